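"""Epoch-level hypnogram model and nightly sleep-parameter derivation.

A contactless bedside monitor scores each night of sleep in fixed 30-second
epochs, each labelled with one of five states: WAKE, LIGHT, DEEP, REM, or
ABSENCE (the sleeper is not in bed).  From one night's ordered epoch
sequence this module derives the standard nightly sleep parameters:

* adjusted sleep latency (SL_adj),
* total sleep time (TST),
* wake after sleep onset (WASO, "intermittent wakefulness"),
* final awakening duration,
* time in bed (TIB, presence-based), and
* sleep efficiency (SE = 100 * TST / TIB).

All derivations operate on an *analysis window* that begins at the first
epoch following the last ABSENCE preceding sleep onset and ends at the
first ABSENCE after the final sleep epoch, or at the end of the recording,
whichever occurs first.  Durations are exact epoch totals in minutes
(0.5-minute granularity); display rounding is a separate concern handled in
:mod:`noctvar.report`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Integer state codes used internally (int8 arrays).
WAKE, LIGHT, DEEP, REM, ABSENCE = 0, 1, 2, 3, 4

STATE_NAMES = ("WAKE", "LIGHT", "DEEP", "REM", "ABSENCE")
STATE_CODES = {name: code for code, name in enumerate(STATE_NAMES)}
SLEEP_STATES = (LIGHT, DEEP, REM)

#: Fixed epoch duration in minutes (30 seconds).
EPOCH_MINUTES = 0.5

NIGHTS_CSV_COLUMNS = [
    "subject_id",
    "night_index",
    "valid",
    "sl_adj_min",
    "tst_min",
    "waso_min",
    "final_awakening_min",
    "tib_min",
    "sleep_efficiency_pct",
]


def encode_states(states: Iterable) -> np.ndarray:
    """Convert state labels (names, case-insensitive, or codes) to an int8 array."""
    arr = np.asarray(list(states) if not isinstance(states, np.ndarray) else states)
    if arr.dtype.kind in "iu":
        codes = arr.astype(np.int8)
    else:
        try:
            codes = np.array(
                [STATE_CODES[str(s).strip().upper()] for s in arr], dtype=np.int8
            )
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise ValueError(f"unknown epoch state label: {exc.args[0]!r}") from exc
    if codes.size and (codes.min() < WAKE or codes.max() > ABSENCE):
        raise ValueError("epoch state codes must be in 0..4")
    return codes


@dataclass(frozen=True)
class EpochSeries:
    """One night's ordered sequence of 30-second epoch states for one subject."""

    subject_id: str
    night_index: int
    states: np.ndarray  # int8 codes, one per epoch

    def __post_init__(self) -> None:
        codes = encode_states(self.states)
        if codes.size == 0:
            raise ValueError("an epoch series must contain at least one epoch")
        object.__setattr__(self, "states", codes)

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def state_names(self) -> list[str]:
        return [STATE_NAMES[c] for c in self.states]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open epoch index span ``[start_index, end_index)`` used for derivation.

    ``has_sleep`` is False when the recording contains no sleep-stage epoch,
    in which case the window is undefined and the night must be flagged
    invalid downstream.
    """

    start_index: int
    end_index: int
    has_sleep: bool


@dataclass(frozen=True)
class NightSummary:
    """Derived nightly sleep parameters (minutes; sleep efficiency in percent).

    Values are unrounded epoch totals.  ``valid`` is False when no sleep
    epoch exists; all parameters are then NaN.
    """

    subject_id: str
    night_index: int
    valid: bool
    sl_adj: float
    tst: float
    waso: float
    final_awakening: float
    tib: float
    sleep_efficiency: float


def _is_sleep(states: np.ndarray) -> np.ndarray:
    return (states == LIGHT) | (states == DEEP) | (states == REM)


def locate_analysis_window(epochs: EpochSeries) -> AnalysisWindow:
    """Locate the analysis window of one night.

    The window starts at the first epoch following the last ABSENCE that
    precedes the first sleep-stage epoch (or at epoch 0 if there is none)
    and ends at the first ABSENCE after the last sleep-stage epoch (or at
    the end of the recording).  Returns ``has_sleep=False`` when no epoch is
    LIGHT, DEEP, or REM.
    """
    states = epochs.states
    sleep_idx = np.flatnonzero(_is_sleep(states))
    if sleep_idx.size == 0:
        return AnalysisWindow(0, 0, False)
    first_sleep = int(sleep_idx[0])
    last_sleep = int(sleep_idx[-1])
    pre_absence = np.flatnonzero(states[:first_sleep] == ABSENCE)
    start = int(pre_absence[-1]) + 1 if pre_absence.size else 0
    post_absence = np.flatnonzero(states[last_sleep + 1 :] == ABSENCE)
    end = last_sleep + 1 + int(post_absence[0]) if post_absence.size else len(epochs)
    return AnalysisWindow(start, end, True)


def _require_sleep(window: AnalysisWindow) -> None:
    if not window.has_sleep:
        raise ValueError("analysis window is undefined: night contains no sleep epoch")


def adjusted_sleep_latency(epochs: EpochSeries, window: AnalysisWindow) -> float:
    """Adjusted sleep latency in minutes.

    When an ABSENCE bout precedes the first sleep epoch, latency runs from
    the end of that bout (the window start); otherwise it runs from the
    start of the recording (which is then also the window start, since the
    recording is user-initiated).  Either way this is
    ``0.5 * (first sleep index - window start)``.
    """
    _require_sleep(window)
    first_sleep = int(np.flatnonzero(_is_sleep(epochs.states))[0])
    return EPOCH_MINUTES * (first_sleep - window.start_index)


def total_sleep_time(epochs: EpochSeries, window: AnalysisWindow) -> float:
    """Total sleep time: summed LIGHT/DEEP/REM epochs within the window, minutes."""
    _require_sleep(window)
    span = epochs.states[window.start_index : window.end_index]
    return EPOCH_MINUTES * int(_is_sleep(span).sum())


def wake_after_sleep_onset(epochs: EpochSeries, window: AnalysisWindow) -> float:
    """WASO: WAKE time strictly between the first and last sleep epochs, minutes.

    ABSENCE epochs within that span are excluded (contribute nothing).
    """
    _require_sleep(window)
    sleep_idx = np.flatnonzero(_is_sleep(epochs.states))
    interior = epochs.states[int(sleep_idx[0]) + 1 : int(sleep_idx[-1])]
    return EPOCH_MINUTES * int((interior == WAKE).sum())


def final_awakening_duration(epochs: EpochSeries, window: AnalysisWindow) -> float:
    """Time from the last sleep epoch to the window end boundary, minutes."""
    _require_sleep(window)
    last_sleep = int(np.flatnonzero(_is_sleep(epochs.states))[-1])
    return EPOCH_MINUTES * (window.end_index - (last_sleep + 1))


def time_in_bed(epochs: EpochSeries, window: AnalysisWindow) -> float:
    """Presence-based time in bed: non-ABSENCE epochs within the window, minutes."""
    _require_sleep(window)
    span = epochs.states[window.start_index : window.end_index]
    return EPOCH_MINUTES * int((span != ABSENCE).sum())


def derive_night(epochs: EpochSeries) -> NightSummary:
    """Derive all nightly sleep parameters for one epoch series.

    Composes the window location and the five duration derivations and adds
    sleep efficiency ``100 * TST / TIB``.  A night with no sleep epoch is
    returned with ``valid=False`` and NaN parameters rather than raising.
    """
    window = locate_analysis_window(epochs)
    if not window.has_sleep:
        nan = float("nan")
        return NightSummary(
            epochs.subject_id, epochs.night_index, False, nan, nan, nan, nan, nan, nan
        )
    tst = total_sleep_time(epochs, window)
    tib = time_in_bed(epochs, window)
    return NightSummary(
        subject_id=epochs.subject_id,
        night_index=epochs.night_index,
        valid=True,
        sl_adj=adjusted_sleep_latency(epochs, window),
        tst=tst,
        waso=wake_after_sleep_onset(epochs, window),
        final_awakening=final_awakening_duration(epochs, window),
        tib=tib,
        sleep_efficiency=100.0 * tst / tib,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def epochs_to_frame(series: Sequence[EpochSeries]) -> pd.DataFrame:
    """Long-format epoch table: subject_id, night_index, epoch_index, state."""
    frames = []
    for es in series:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": es.subject_id,
                    "night_index": es.night_index,
                    "epoch_index": np.arange(len(es), dtype=np.int64),
                    "state": [STATE_NAMES[c] for c in es.states],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_epochs(df: pd.DataFrame) -> list[EpochSeries]:
    """Rebuild :class:`EpochSeries` objects from a long-format epoch table."""
    out: list[EpochSeries] = []
    for (sid, night), grp in df.groupby(["subject_id", "night_index"], sort=True):
        grp = grp.sort_values("epoch_index")
        out.append(EpochSeries(str(sid), int(night), encode_states(grp["state"].to_numpy())))
    return out


def write_epochs_csv(series: Sequence[EpochSeries], path) -> None:
    epochs_to_frame(series).to_csv(path, index=False)


def read_epochs_csv(path) -> list[EpochSeries]:
    return frame_to_epochs(pd.read_csv(path))


def nights_to_frame(nights: Sequence[NightSummary]) -> pd.DataFrame:
    """Nightly-summary table with the canonical column layout."""
    return pd.DataFrame(
        [
            {
                "subject_id": n.subject_id,
                "night_index": n.night_index,
                "valid": n.valid,
                "sl_adj_min": n.sl_adj,
                "tst_min": n.tst,
                "waso_min": n.waso,
                "final_awakening_min": n.final_awakening,
                "tib_min": n.tib,
                "sleep_efficiency_pct": n.sleep_efficiency,
            }
            for n in nights
        ],
        columns=NIGHTS_CSV_COLUMNS,
    )


def write_nights_csv(nights: Sequence[NightSummary], path) -> None:
    nights_to_frame(nights).to_csv(path, index=False)


def read_nights_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
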