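"""End-to-end study pipeline and report rendering.

Orchestrates simulate -> realise epochs -> derive nights -> fit the
location-scale model per outcome -> planned contrasts, and renders the
results as a machine-readable report (JSON) plus a human-readable text
table with one Means row and one SD row per outcome.  Display rounding of
TST and WASO to whole minutes lives here and only here: the statistics path
always consumes unrounded epoch totals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_epoch_cohort
from .hypnogram import NightSummary, derive_night, nights_to_frame, write_epochs_csv
from .model import MixedLocationScaleModel

REPORT_OUTCOMES = ("sleep_efficiency", "tib", "tst", "sl_adj", "waso")


def display_round(night: NightSummary) -> dict:
    """Display view of a night with TST and WASO rounded half-up to whole minutes.

    The underlying analysis values are untouched; only the returned mapping
    is rounded.  Invalid nights display as None.
    """
    if not night.valid:
        return {"subject_id": night.subject_id, "night_index": night.night_index,
                "tst_display_min": None, "waso_display_min": None}
    return {
        "subject_id": night.subject_id,
        "night_index": night.night_index,
        "tst_display_min": int(math.floor(night.tst + 0.5)),
        "waso_display_min": int(math.floor(night.waso + 0.5)),
    }


def grand_mean_age(age_means, ns) -> float:
    """Size-weighted grand mean age from per-group means and counts."""
    age_means = np.asarray(age_means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float((age_means * ns).sum() / ns.sum())


def cohort_descriptives(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, %, age mean/SD and sex split, plus the weighted grand mean age."""
    if subjects.empty:
        raise ValueError("cohort is empty")
    total = len(subjects)
    rows = []
    for group, grp in subjects.groupby("group", sort=False):
        rows.append(
            {
                "group": group,
                "n": len(grp),
                "percent": 100.0 * len(grp) / total,
                "age_mean": float(grp["age_years"].mean()),
                "age_sd": float(grp["age_years"].std(ddof=1)) if len(grp) > 1 else np.nan,
                "female_percent": 100.0 * float((grp["sex"] == "female").mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    table.attrs["grand_mean_age"] = grand_mean_age(
        table["age_mean"].to_numpy(), table["n"].to_numpy()
    )
    return table


def adherence_table(
    nights: pd.DataFrame, subjects: pd.DataFrame, n_nights: int
) -> pd.DataFrame:
    """Observed-night fraction per group and week (missingness diagnostics)."""
    n_weeks = -(-n_nights // 7)
    group_of = subjects.set_index("subject_id")["group"]
    counts = nights.assign(
        week=(nights["night_index"].astype(int) - 1) // 7 + 1,
        group=group_of.loc[nights["subject_id"]].to_numpy(),
    ).groupby(["group", "week"]).size()
    n_subj = subjects.groupby("group").size()
    rows = []
    for group in n_subj.index:
        for week in range(1, n_weeks + 1):
            nights_in_week = min(7, n_nights - 7 * (week - 1))
            possible = n_subj[group] * nights_in_week
            observed = int(counts.get((group, week), 0))
            rows.append(
                {
                    "group": group,
                    "week": week,
                    "observed_fraction": observed / possible,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """Structured study report: contrast table, grand means, adherence,
    cohort descriptives and the configuration that produced them."""

    seed: int
    config: dict
    descriptives: pd.DataFrame
    adherence: pd.DataFrame
    contrasts: pd.DataFrame  # one Means row + one SD row per outcome
    grand_means: dict
    n_invalid_nights: int
    n_observed_nights: int

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "descriptives": self.descriptives.reset_index().to_dict(orient="records"),
            "grand_mean_age": self.descriptives.attrs.get("grand_mean_age"),
            "adherence": self.adherence.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "grand_means": self.grand_means,
            "n_invalid_nights": self.n_invalid_nights,
            "n_observed_nights": self.n_observed_nights,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def read_json(path) -> dict:
        return json.loads(Path(path).read_text())

    def to_text(self) -> str:
        """Two-row (Means / SD) per-outcome contrast table, for visual scanning."""
        lines = [
            f"Study report (seed {self.seed})",
            f"  observed nights: {self.n_observed_nights}  "
            f"invalid nights excluded: {self.n_invalid_nights}",
            "",
            f"  {'outcome':<18} {'row':<6} {'estimate':>10} {'SE':>8} "
            f"{'F':>10} {'df':>10} {'p':>10} {'95% CI':>22}",
        ]
        for rec in self.contrasts.to_dict(orient="records"):
            ci = f"[{rec['ci_low']:.2f}, {rec['ci_high']:.2f}]"
            lines.append(
                f"  {rec['outcome']:<18} {rec['row']:<6} {rec['estimate']:>10.3f} "
                f"{rec['se']:>8.3f} {rec['fvalue']:>10.2f} "
                f"(1, {rec['df_den']:>3d}) {rec['pvalue']:>10.4g} {ci:>22}"
            )
        lines.append("")
        for name, info in self.grand_means.items():
            lines.append(
                f"  grand mean {name}: {info['hours']:.2f} h "
                f"({info['minutes']:.1f} min over {info['n_nights']} nights)"
            )
        return "\n".join(lines)


def run_pipeline(
    config: CohortConfig,
    seed: int | None = None,
    outdir=None,
    outcomes=REPORT_OUTCOMES,
    write_epochs: bool = False,
    ddf_rule: str = "n_minus_5",
) -> StudyReport:
    """Deterministic end-to-end run: simulate, derive, fit, contrast, report.

    When ``outdir`` is given, writes nights CSV, subjects CSV, per-outcome
    fit JSONs and the report (JSON and text); the epoch CSV is written only
    on request since it is large at full scale.
    """
    seed = config.seed if seed is None else int(seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    cohort, epochs = simulate_epoch_cohort(config, seed)
    nights = [derive_night(es) for es in epochs]
    nights_df = nights_to_frame(nights)
    n_invalid = int((~nights_df["valid"]).sum())

    if outdir is not None:
        cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
        nights_df.to_csv(outdir / "nights.csv", index=False)
        if write_epochs:
            write_epochs_csv(epochs, outdir / "epochs.csv")

    rows = []
    for outcome in outcomes:
        model = MixedLocationScaleModel.from_nights(nights_df, cohort.subjects, outcome)
        fit = model.fit(ddf_rule=ddf_rule)
        for row_name, contrast in (
            ("Means", fit.mean_contrast()),
            ("SD", fit.sd_contrast()),
        ):
            lo, hi = contrast.conf_int()
            rows.append(
                {
                    "outcome": outcome,
                    "row": row_name,
                    "estimate": contrast.estimate,
                    "se": contrast.se,
                    "fvalue": contrast.fvalue,
                    "df_num": contrast.df_num,
                    "df_den": contrast.df_den,
                    "pvalue": contrast.pvalue,
                    "ci_low": lo,
                    "ci_high": hi,
                    "converged": fit.converged,
                }
            )
        if outdir is not None:
            fit_payload = {
                "outcome": outcome,
                "params": fit.params.to_dict(),
                "bse": fit.bse.to_dict(),
                "vcov": fit.vcov.to_numpy().tolist(),
                "llf": fit.llf,
                "converged": fit.converged,
                "grad_max_norm": fit.grad_norm,
                "ddf": fit.ddf,
                "ddf_rule": fit.ddf_rule,
                "config": config.to_dict(),
                "seed": seed,
            }
            (outdir / f"fit_{outcome}.json").write_text(
                json.dumps(fit_payload, indent=2, sort_keys=True)
            )

    valid = nights_df.loc[nights_df["valid"].astype(bool)]
    grand_means = {}
    for name, col in (("tib", "tib_min"), ("tst", "tst_min")):
        minutes = float(valid[col].mean())
        grand_means[name] = {
            "minutes": minutes,
            "hours": minutes / 60.0,
            "n_nights": int(len(valid)),
        }

    report = StudyReport(
        seed=seed,
        config=config.to_dict(),
        descriptives=cohort_descriptives(cohort.subjects),
        adherence=adherence_table(nights_df, cohort.subjects, config.n_nights),
        contrasts=pd.DataFrame(rows),
        grand_means=grand_means,
        n_invalid_nights=n_invalid,
        n_observed_nights=int(len(nights_df)),
    )
    if outdir is not None:
        report.to_json(outdir / "report.json")
        (outdir / "report.txt").write_text(report.to_text() + "\n")
    return report
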