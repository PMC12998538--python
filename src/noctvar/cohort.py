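"""Synthetic longitudinal sleep-cohort generator.

Generates epoch-level cohorts with the statistical structure the
location-scale analysis assumes: subject-level random intercepts,
group-specific night-to-night (within-subject) SDs, age/sex covariates, and
weekly adherence decline producing missing nights completely at random.

The generator's night-level primitives are the four additive components of
a night -- sleep latency (SL), wake after sleep onset (WASO), final
awakening (FA) and total sleep time (TST).  Time in bed and sleep
efficiency follow algebraically (TIB = SL + WASO + FA + TST;
SE = 100 * TST / TIB), so a cohort has four free outcome dimensions, not
five.  The configured sleep-efficiency group contrasts (mean difference and
within-subject SD difference) are therefore *calibration targets*:
:func:`derive_group_anchors` solves for the TST group-mean difference and
the TST within-subject SD such that the implied sleep-efficiency contrasts
equal the configured values (first-order delta-method propagation for the
SD; exact ratio-of-means for the mean).

Night values are drawn from normals truncated at zero (exact truncated
normal sampling, conditional on the subject intercept) and quantised to the
0.5-minute epoch grid.  Default anchors keep the analytic truncation mass
below 1% for every outcome and group; a warning is emitted otherwise since
heavier truncation biases parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.stats import norm, truncnorm

from .hypnogram import (
    ABSENCE,
    DEEP,
    EPOCH_MINUTES,
    LIGHT,
    REM,
    WAKE,
    EpochSeries,
)

GROUPS = ("insomnia", "control")
#: Generator primitives, in sampling order.
PRIMITIVES = ("sl", "waso", "fa", "tst")

TARGETS_COLUMNS = [
    "subject_id",
    "night_index",
    "sl_min",
    "waso_min",
    "final_awakening_min",
    "tst_min",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator truth: cohort geometry, outcome anchors, noise and adherence.

    Mean anchors are grand means over the pooled cohort (weighted by group
    size); group means are resolved from each grand anchor ``m`` and the
    insomnia-minus-control difference ``d`` as ``control = m - d * w_ins``,
    ``insomnia = control + d`` with ``w_ins = n_insomnia / n_total``, which
    preserves both the grand mean and the difference.

    All durations are minutes, sleep efficiency is in percentage points and
    ages in years.
    """

    # cohort geometry
    n_insomnia: int = 83
    n_control: int = 29
    n_nights: int = 56

    # grand mean anchors (minutes)
    tib_grand_mean: float = 459.0  # 7.65 h
    tst_grand_mean: float = 395.4  # 6.59 h
    sl_grand_mean: float = 29.5
    waso_grand_mean: float = 25.7
    # final-awakening grand mean is implied: tib - tst - sl - waso

    # insomnia-minus-control mean differences
    se_mean_diff: float = -5.34  # percentage points; calibration target
    sl_mean_diff: float = 10.15
    waso_mean_diff: float = 18.45
    fa_mean_diff: float = 0.0

    # control-group within-subject (night-to-night) SD anchors
    sl_sd_control: float = 1.0
    waso_sd_control: float = 2.0
    fa_sd_control: float = 2.0
    # tst within-subject SD is solved from the SE SD calibration target

    # insomnia-minus-control within-subject SD differences
    se_sd_diff: float = 1.77  # percentage points; calibration target
    sl_sd_diff: float = 8.80
    waso_sd_diff: float = 8.60
    fa_sd_diff: float = 0.0

    # subject random-intercept SDs (shared across groups)
    sl_intercept_sd: float = 4.0
    waso_intercept_sd: float = 4.0
    fa_intercept_sd: float = 2.0
    tst_intercept_sd: float = 25.0

    # covariates
    age_mean_insomnia: float = 38.3
    age_sd_insomnia: float = 12.0
    age_mean_control: float = 29.7
    age_sd_control: float = 8.8
    age_min: float = 18.0
    age_max: float = 65.0
    female_prop_insomnia: float = 0.699
    female_prop_control: float = 0.724

    # weekly adherence (probability a night is recorded), one value per week
    weekly_adherence_insomnia: tuple = (
        0.820, 0.815, 0.838, 0.795, 0.765, 0.725, 0.685, 0.632,
    )
    weekly_adherence_control: tuple = (
        0.808, 0.715, 0.712, 0.710, 0.708, 0.705, 0.700, 0.695,
    )

    # epoch realisation
    pre_sleep_absence_prob: float = 0.5
    absence_bout_epochs: tuple = (2, 20)
    stage_mix: tuple = (0.55, 0.20, 0.25)  # LIGHT, DEEP, REM
    waso_max_bouts: int = 4

    truncation_warn_mass: float = 0.01
    seed: int = 20260324

    def __post_init__(self) -> None:
        if min(self.n_insomnia, self.n_control) < 1 or self.n_nights < 1:
            raise ValueError("group sizes and n_nights must be positive")
        n_weeks = -(-self.n_nights // 7)
        for name in ("weekly_adherence_insomnia", "weekly_adherence_control"):
            probs = getattr(self, name)
            object.__setattr__(self, name, tuple(float(p) for p in probs))
            probs = getattr(self, name)
            if len(probs) != n_weeks:
                raise ValueError(f"{name} must list {n_weeks} weekly probabilities")
            if not all(0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"{name} values must lie in [0, 1]")
        for name in (
            "sl_sd_control", "waso_sd_control", "fa_sd_control",
            "sl_intercept_sd", "waso_intercept_sd", "fa_intercept_sd",
            "tst_intercept_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("female_prop_insomnia", "female_prop_control",
                     "pre_sleep_absence_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not abs(sum(self.stage_mix) - 1.0) < 1e-9:
            raise ValueError("stage_mix must sum to 1")
        object.__setattr__(self, "stage_mix", tuple(float(p) for p in self.stage_mix))
        object.__setattr__(
            self, "absence_bout_epochs", tuple(int(v) for v in self.absence_bout_epochs)
        )

    @property
    def n_total(self) -> int:
        return self.n_insomnia + self.n_control

    @property
    def weight_insomnia(self) -> float:
        return self.n_insomnia / self.n_total

    @property
    def n_weeks(self) -> int:
        return -(-self.n_nights // 7)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def split_grand_mean(m: float, d: float, w_ins: float) -> tuple[float, float]:
    """Resolve a grand anchor and insomnia-minus-control difference into
    (insomnia, control) group values preserving both."""
    control = m - d * w_ins
    return control + d, control


@dataclass(frozen=True)
class GroupTruth:
    """Fully resolved per-group generator truth.

    ``means`` and ``within_sd`` map group -> outcome -> value for the four
    primitives plus the implied ``se`` and ``tib``; ``intercept_sd`` maps
    primitive -> subject random-intercept SD.  ``tst_mean_diff`` and
    ``tst_within_sd`` are the calibrated TST parameters; ``truncation_mass``
    holds the analytic P(night value < 0) per group and primitive.
    """

    means: dict
    within_sd: dict
    intercept_sd: dict
    tst_mean_diff: float
    tst_within_sd: float
    truncation_mass: dict

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for group in GROUPS:
            for outcome in (*PRIMITIVES, "tib", "se"):
                rows.append(
                    {
                        "group": group,
                        "outcome": outcome,
                        "mean": self.means[group][outcome],
                        "within_sd": self.within_sd[group].get(outcome, np.nan),
                    }
                )
        return pd.DataFrame(rows)


def _implied_se_stats(
    means: dict, within: dict, intercept_sd: Mapping | None = None, n_nodes: int = 16
) -> dict:
    """Implied sleep-efficiency moments under the generating process.

    SE = 100 * TST / (TST + R) with R the summed non-sleep components, both
    normal around their group means with subject-intercept and night-noise
    parts.  The mean E[SE] and the within-subject variance E_b[Var(SE | b)]
    are evaluated by tensor-product Gauss-Hermite quadrature (exact for the
    smooth ratio up to quadrature error; the sub-percent truncation mass at
    zero is ignored).
    """
    if intercept_sd is None:
        intercept_sd = {o: 0.0 for o in PRIMITIVES}
    x, wts = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * x
    wn = wts / np.sqrt(np.pi)
    out = {}
    for group in GROUPS:
        m, w = means[group], within[group]
        t_mean = m["tst"]
        r_mean = m["sl"] + m["waso"] + m["fa"]
        t_w = w["tst"]
        r_w = float(np.sqrt(w["sl"] ** 2 + w["waso"] ** 2 + w["fa"] ** 2))
        t_b = float(intercept_sd["tst"])
        r_b = float(
            np.sqrt(
                intercept_sd["sl"] ** 2
                + intercept_sd["waso"] ** 2
                + intercept_sd["fa"] ** 2
            )
        )
        # axes: (bT, bR, eT, eR)
        T = (
            t_mean
            + t_b * z[:, None, None, None]
            + t_w * z[None, None, :, None]
            + np.zeros((1, 1, 1, n_nodes))
        )
        R = (
            r_mean
            + r_b * z[None, :, None, None]
            + r_w * z[None, None, None, :]
            + np.zeros((n_nodes, 1, 1, 1))
        )
        se = 100.0 * np.clip(T, 1e-6, None) / (np.clip(T, 1e-6, None) + np.clip(R, 0.0, None))
        w_night = wn[None, None, :, None] * wn[None, None, None, :]
        mean_b = (se * w_night).sum(axis=(2, 3))          # E[SE | b]
        msq_b = (se**2 * w_night).sum(axis=(2, 3))        # E[SE^2 | b]
        var_b = np.clip(msq_b - mean_b**2, 0.0, None)     # Var(SE | b)
        w_subj = wn[:, None] * wn[None, :]
        out[group] = {
            "mean": float((mean_b * w_subj).sum()),
            "within_sd": float(np.sqrt((var_b * w_subj).sum())),
        }
    return out


def derive_group_anchors(config: CohortConfig) -> GroupTruth:
    """Resolve the configured anchors and differences into per-group truth.

    Group means for SL, WASO and FA come directly from the anchor/difference
    construction.  The TST group difference is solved so the implied
    sleep-efficiency mean contrast equals ``config.se_mean_diff`` exactly
    (ratio of group means), and the TST within-subject SD is solved so the
    delta-method sleep-efficiency within-SD contrast matches
    ``config.se_sd_diff`` as closely as the geometry allows.
    """
    w_ins = config.weight_insomnia
    fa_grand = (
        config.tib_grand_mean
        - config.tst_grand_mean
        - config.sl_grand_mean
        - config.waso_grand_mean
    )
    if fa_grand <= 0:
        raise ValueError(
            "implied final-awakening grand mean is non-positive; "
            "tib anchor must exceed tst + sl + waso anchors"
        )
    base = {
        "sl": split_grand_mean(config.sl_grand_mean, config.sl_mean_diff, w_ins),
        "waso": split_grand_mean(config.waso_grand_mean, config.waso_mean_diff, w_ins),
        "fa": split_grand_mean(fa_grand, config.fa_mean_diff, w_ins),
    }

    def means_for(d_tst: float) -> dict:
        tst_i, tst_c = split_grand_mean(config.tst_grand_mean, d_tst, w_ins)
        means = {}
        for group, tst in zip(GROUPS, (tst_i, tst_c)):
            idx = 0 if group == "insomnia" else 1
            m = {o: base[o][idx] for o in ("sl", "waso", "fa")}
            m["tst"] = tst
            m["tib"] = sum(m.values())
            m["se"] = 100.0 * m["tst"] / m["tib"]
            means[group] = m
        return means

    within = {
        "insomnia": {
            "sl": config.sl_sd_control + config.sl_sd_diff,
            "waso": config.waso_sd_control + config.waso_sd_diff,
            "fa": config.fa_sd_control + config.fa_sd_diff,
        },
        "control": {
            "sl": config.sl_sd_control,
            "waso": config.waso_sd_control,
            "fa": config.fa_sd_control,
        },
    }
    intercept_sd = {
        "sl": config.sl_intercept_sd,
        "waso": config.waso_intercept_sd,
        "fa": config.fa_intercept_sd,
        "tst": config.tst_intercept_sd,
    }

    # Joint calibration of the TST mean difference (-> SE mean contrast) and
    # the TST within-SD (-> SE within-SD contrast): the two one-dimensional
    # solves are alternated to their fixed point (they interact only weakly).
    def se_stats(d_tst: float, sigma_tst: float) -> dict:
        trial = {g: dict(within[g], tst=sigma_tst) for g in GROUPS}
        return _implied_se_stats(means_for(d_tst), trial, intercept_sd)

    d_tst, sigma_tst = 0.0, 60.0
    for _ in range(4):
        d_prev, s_prev = d_tst, sigma_tst
        d_tst = optimize.brentq(
            lambda d: (lambda s: s["insomnia"]["mean"] - s["control"]["mean"])(
                se_stats(d, sigma_tst)
            )
            - config.se_mean_diff,
            -150.0,
            150.0,
            xtol=1e-8,
        )

        def sd_gap(s: float) -> float:
            st = se_stats(d_tst, s)
            return st["insomnia"]["within_sd"] - st["control"]["within_sd"]

        res = optimize.minimize_scalar(
            lambda s: (sd_gap(s) - config.se_sd_diff) ** 2,
            bounds=(1.0, 200.0),
            method="bounded",
            options={"xatol": 1e-7},
        )
        sigma_tst = float(res.x)
        if abs(d_tst - d_prev) < 1e-6 and abs(sigma_tst - s_prev) < 1e-5:
            break
    # final mean re-solve so the SE mean contrast is exact at the solved scale
    d_tst = optimize.brentq(
        lambda d: (lambda s: s["insomnia"]["mean"] - s["control"]["mean"])(
            se_stats(d, sigma_tst)
        )
        - config.se_mean_diff,
        -150.0,
        150.0,
        xtol=1e-10,
    )
    means = means_for(d_tst)
    achieved = sd_gap(sigma_tst)
    if abs(achieved - config.se_sd_diff) > max(0.05 * abs(config.se_sd_diff), 0.02):
        warnings.warn(
            "sleep-efficiency within-SD contrast calibration is off target "
            f"({achieved:.3f} vs {config.se_sd_diff:.3f}); the configured SL/WASO "
            "SD anchors may be geometrically incompatible",
            stacklevel=2,
        )
    for group in GROUPS:
        within[group]["tst"] = sigma_tst

    implied = _implied_se_stats(means, within, intercept_sd)
    for group in GROUPS:
        within[group]["se"] = implied[group]["within_sd"]
        means[group]["se"] = implied[group]["mean"]  # E[SE], not ratio of means

    for group in GROUPS:
        for outcome in PRIMITIVES:
            if means[group][outcome] <= 0:
                raise ValueError(
                    f"resolved mean for {outcome} in {group} group is non-positive"
                )
            if within[group][outcome] <= 0:
                raise ValueError(
                    f"resolved within-subject SD for {outcome} in {group} group "
                    "is non-positive"
                )

    truncation = {
        group: {
            o: float(
                norm.cdf(
                    0.0,
                    loc=means[group][o],
                    scale=np.hypot(within[group][o], intercept_sd[o]),
                )
            )
            for o in PRIMITIVES
        }
        for group in GROUPS
    }
    worst = max(v for d in truncation.values() for v in d.values())
    if worst > config.truncation_warn_mass:
        warnings.warn(
            f"maximum analytic truncation mass {worst:.3%} exceeds "
            f"{config.truncation_warn_mass:.1%}; truncation will bias parameter "
            "recovery",
            stacklevel=2,
        )

    return GroupTruth(
        means=means,
        within_sd=within,
        intercept_sd=intercept_sd,
        tst_mean_diff=float(d_tst),
        tst_within_sd=sigma_tst,
        truncation_mass=truncation,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_QUANT_VAR = EPOCH_MINUTES**2 / 12.0  # Sheppard correction for the 0.5-min grid


def _truncated_moments(mu_raw, sigma_raw, b_nodes, b_weights):
    """Mean and within-variance of max(N(mu_raw + b, sigma_raw^2), truncated
    at 0), averaged over the subject-intercept distribution."""
    alpha = (mu_raw + b_nodes) / sigma_raw
    lam = norm.pdf(alpha) / np.clip(norm.cdf(alpha), 1e-300, None)
    mean_i = mu_raw + b_nodes + sigma_raw * lam
    var_i = sigma_raw**2 * np.clip(1.0 - alpha * lam - lam**2, 0.0, None)
    return float(b_weights @ mean_i), float(b_weights @ var_i)


def _raw_sampling_params(truth: GroupTruth, n_nodes: int = 24) -> dict:
    """Invert truncation and quantisation: per group and primitive, the raw
    normal (mean, SD) whose truncated-at-zero, 0.5-min-quantised night values
    reproduce the target mean and within-subject SD of the truth table.

    Where the truncation mass is negligible the targets are returned as-is.
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    raw: dict = {g: {} for g in GROUPS}
    for group in GROUPS:
        for outcome in PRIMITIVES:
            mu_t = truth.means[group][outcome]
            sd_t = truth.within_sd[group][outcome]
            u = truth.intercept_sd[outcome]
            b_nodes = np.sqrt(2.0) * u * x
            b_weights = w / np.sqrt(np.pi)
            # variance target before quantisation (Sheppard)
            var_t = sd_t**2 - _QUANT_VAR if sd_t**2 > 2.0 * _QUANT_VAR else sd_t**2
            sd_pre = float(np.sqrt(var_t))
            mass = norm.cdf(0.0, loc=mu_t, scale=float(np.hypot(sd_pre, u)))
            if mass < 1e-10:
                raw[group][outcome] = (mu_t, sd_pre)
                continue

            def gap(params):
                mu_r, log_sd_r = params
                m, v = _truncated_moments(mu_r, np.exp(log_sd_r), b_nodes, b_weights)
                return [m - mu_t, v - var_t]

            sol = optimize.root(gap, x0=[mu_t, np.log(sd_pre)], method="hybr")
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"could not invert truncation for {outcome} in {group} group"
                )
            raw[group][outcome] = (float(sol.x[0]), float(np.exp(sol.x[1])))
    return raw

def sample_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the subject table: ids, group labels, truncated-normal ages, sex."""
    rows = []
    specs = [
        ("insomnia", "I", config.n_insomnia, config.age_mean_insomnia,
         config.age_sd_insomnia, config.female_prop_insomnia),
        ("control", "C", config.n_control, config.age_mean_control,
         config.age_sd_control, config.female_prop_control),
    ]
    for group, prefix, n, age_mean, age_sd, p_female in specs:
        a = (config.age_min - age_mean) / age_sd
        b = (config.age_max - age_mean) / age_sd
        ages = truncnorm.rvs(a, b, loc=age_mean, scale=age_sd, size=n, random_state=rng)
        female = rng.random(n) < p_female
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}{k + 1:03d}",
                    "group": group,
                    "age_years": float(ages[k]),
                    "sex": "female" if female[k] else "male",
                }
            )
    return pd.DataFrame(rows)


def draw_subject_intercepts(
    subjects: pd.DataFrame, truth: GroupTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """One random intercept per subject and primitive outcome."""
    n = len(subjects)
    data = {"subject_id": subjects["subject_id"].to_numpy()}
    for outcome in PRIMITIVES:
        data[outcome] = rng.normal(0.0, truth.intercept_sd[outcome], size=n)
    return pd.DataFrame(data)


def sample_night_targets(
    truth: GroupTruth,
    subjects: pd.DataFrame,
    n_nights: int,
    rng: np.random.Generator,
    intercepts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw quantised nightly (SL, WASO, FA, TST) targets for every night.

    Night value = group mean + subject intercept + night noise with the
    group's within-subject SD, sampled from a normal truncated at zero and
    rounded to the 0.5-minute epoch grid.  The raw normal parameters are
    pre-adjusted (:func:`_raw_sampling_params`) so that the truncated,
    quantised values reproduce the truth-table moments exactly.
    """
    if intercepts is None:
        intercepts = draw_subject_intercepts(subjects, truth, rng)
    intercepts = intercepts.set_index("subject_id")
    raw = _raw_sampling_params(truth)
    n_sub = len(subjects)
    groups = subjects["group"].to_numpy()
    sids = subjects["subject_id"].to_numpy()

    out = {
        "subject_id": np.repeat(sids, n_nights),
        "night_index": np.tile(np.arange(1, n_nights + 1), n_sub),
    }
    colname = {"sl": "sl_min", "waso": "waso_min",
               "fa": "final_awakening_min", "tst": "tst_min"}
    for outcome in PRIMITIVES:
        mu_subj = np.array(
            [raw[g][outcome][0] for g in groups]
        ) + intercepts.loc[sids, outcome].to_numpy()
        sigma = np.array([raw[g][outcome][1] for g in groups])
        loc = np.repeat(mu_subj, n_nights)
        scale = np.repeat(sigma, n_nights)
        a = (0.0 - loc) / scale
        values = truncnorm.rvs(a, np.inf, loc=loc, scale=scale, random_state=rng)
        out[colname[outcome]] = np.round(values * 2.0) / 2.0
    return pd.DataFrame(out)


def apply_adherence(
    targets: pd.DataFrame,
    subjects: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Drop unrecorded nights: each night kept independently with its group's
    weekly probability (missing completely at random)."""
    weekly = {
        "insomnia": np.asarray(config.weekly_adherence_insomnia),
        "control": np.asarray(config.weekly_adherence_control),
    }
    group_of = subjects.set_index("subject_id")["group"]
    week = (targets["night_index"].to_numpy() - 1) // 7
    groups = group_of.loc[targets["subject_id"]].to_numpy()
    probs = np.where(
        groups == "insomnia", weekly["insomnia"][week], weekly["control"][week]
    )
    keep = rng.random(len(targets)) < probs
    return targets.loc[keep].reset_index(drop=True)


def targets_to_nights_frame(targets: pd.DataFrame) -> pd.DataFrame:
    """Nightly-summary frame implied directly by the targets.

    By the realisation/derivation round-trip identity this equals what
    :func:`noctvar.hypnogram.derive_night` returns on realised epochs.
    """
    tib = (
        targets["sl_min"]
        + targets["waso_min"]
        + targets["final_awakening_min"]
        + targets["tst_min"]
    )
    return pd.DataFrame(
        {
            "subject_id": targets["subject_id"],
            "night_index": targets["night_index"],
            "valid": True,
            "sl_adj_min": targets["sl_min"],
            "tst_min": targets["tst_min"],
            "waso_min": targets["waso_min"],
            "final_awakening_min": targets["final_awakening_min"],
            "tib_min": tib,
            "sleep_efficiency_pct": 100.0 * targets["tst_min"] / tib,
        }
    )


# ---------------------------------------------------------------------------
# Epoch realisation
# ---------------------------------------------------------------------------

def realize_epochs(
    subject_id: str,
    night_index: int,
    sl: float,
    waso: float,
    final_awakening: float,
    tst: float,
    rng: np.random.Generator,
    config: CohortConfig,
) -> EpochSeries:
    """Emit an epoch sequence whose derived summary reproduces the targets.

    Layout: optional pre-sleep ABSENCE bout, SL wake epochs, a sleep span
    with the WASO wake epochs distributed over 1-4 bouts strictly interior
    to the first/last sleep epochs, then the final-awakening wake epochs.
    Raises when the targets are not realisable (WASO > 0 needs at least two
    sleep epochs to enclose a wake bout).
    """
    counts = {}
    for name, minutes in (("sl", sl), ("waso", waso), ("fa", final_awakening),
                          ("tst", tst)):
        n = minutes / EPOCH_MINUTES
        if minutes < 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"{name} target {minutes} is not a non-negative multiple of "
                f"{EPOCH_MINUTES} min"
            )
        counts[name] = int(round(n))
    n_sleep, n_waso = counts["tst"], counts["waso"]
    if n_sleep == 0:
        raise ValueError("cannot realise a night with zero total sleep time")
    if n_waso > 0 and n_sleep < 2:
        raise ValueError("WASO > 0 requires at least two sleep epochs")

    parts: list[np.ndarray] = []
    if rng.random() < config.pre_sleep_absence_prob:
        lo, hi = config.absence_bout_epochs
        parts.append(np.full(rng.integers(lo, hi + 1), ABSENCE, dtype=np.int8))
    parts.append(np.full(counts["sl"], WAKE, dtype=np.int8))

    stages = rng.choice(
        np.array([LIGHT, DEEP, REM], dtype=np.int8), size=n_sleep, p=config.stage_mix
    )
    if n_waso == 0:
        parts.append(stages)
    else:
        n_bouts = int(rng.integers(1, min(config.waso_max_bouts, n_waso, n_sleep - 1) + 1))
        # split the wake epochs into n_bouts positive runs
        if n_bouts == 1:
            bout_sizes = np.array([n_waso])
        else:
            bout_sizes = np.bincount(
                rng.integers(0, n_bouts, n_waso - n_bouts), minlength=n_bouts
            ) + 1
        gaps = np.sort(rng.choice(np.arange(1, n_sleep), size=n_bouts, replace=False))
        prev = 0
        for gap, size in zip(gaps, bout_sizes):
            parts.append(stages[prev:gap])
            parts.append(np.full(size, WAKE, dtype=np.int8))
            prev = gap
        parts.append(stages[prev:])

    parts.append(np.full(counts["fa"], WAKE, dtype=np.int8))
    return EpochSeries(subject_id, night_index, np.concatenate(parts))


def realize_cohort(
    targets: pd.DataFrame, rng: np.random.Generator, config: CohortConfig
) -> list[EpochSeries]:
    """Realise an epoch series for every target row."""
    out = []
    for row in targets.itertuples(index=False):
        out.append(
            realize_epochs(
                row.subject_id,
                int(row.night_index),
                row.sl_min,
                row.waso_min,
                row.final_awakening_min,
                row.tst_min,
                rng,
                config,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort: subjects, observed night targets and resolved truth."""

    config: CohortConfig
    truth: GroupTruth
    subjects: pd.DataFrame
    targets: pd.DataFrame  # observed nights only (after adherence)


def simulate_cohort(
    config: CohortConfig, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Simulate subjects and observed nightly targets (no epoch realisation)."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = derive_group_anchors(config)
    subjects = sample_subjects(config, rng)
    targets = sample_night_targets(truth, subjects, config.n_nights, rng)
    observed = apply_adherence(targets, subjects, config, rng)
    return SimulatedCohort(config, truth, subjects, observed)


def simulate_epoch_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[SimulatedCohort, list[EpochSeries]]:
    """Simulate a cohort and realise the epoch sequences of observed nights."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort = simulate_cohort(config, rng=rng)
    epochs = realize_cohort(cohort.targets, rng, config)
    return cohort, epochs
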