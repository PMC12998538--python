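"""Mixed-effects location-scale model for night-to-night sleep variability.

The model for a nightly sleep parameter :math:`y_{ij}` (subject *i*, night
*j*) is

.. math::

    y_{ij} = \\beta_0 + \\beta_g \\, g_i + \\beta_a \\, (a_i - \\bar a)
             + \\beta_s \\, s_i + b_i + e_{ij},

with :math:`g_i` the insomnia indicator, :math:`a_i` age, :math:`s_i` a
male indicator, a subject random intercept :math:`b_i \\sim N(0,
\\sigma_b^2)` and night-level noise :math:`e_{ij} \\sim N(0,
\\sigma_w^2(g_i))`.  The *location* part estimates group means (adjusted
for age and sex); the *scale* part gives each group its own within-subject
SD :math:`\\sigma_w(g)`, the index of night-to-night variability.

Because the random effect enters linearly, the marginal distribution of a
subject's nights is multivariate normal with compound-symmetric covariance
:math:`\\sigma_w^2 I + \\sigma_b^2 J`, and the likelihood is evaluated in
closed form in :math:`O(n_i)` per subject via the rank-one structure.
Variance parameters are optimised on the log scale; standard errors on the
natural scale follow by the delta method from the observed information.

Planned Wald contrasts compare the groups on means (:math:`\\beta_g`) and
on within-subject SDs (:math:`\\sigma_w(\\text{ins}) -
\\sigma_w(\\text{ctl})`), each reported as F = (estimate/SE)^2 on
(1, ddf) degrees of freedom with a t-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "OUTCOME_COLUMNS",
    "ContrastResult",
    "MixedLocationScaleModel",
    "MixedLocationScaleResults",
    "weekly_summaries",
]

#: Model outcome names mapped to nightly-summary table columns.
OUTCOME_COLUMNS = {
    "sleep_efficiency": "sleep_efficiency_pct",
    "tib": "tib_min",
    "tst": "tst_min",
    "sl_adj": "sl_adj_min",
    "waso": "waso_min",
}

PARAM_NAMES = [
    "beta_intercept",
    "beta_group",
    "beta_age",
    "beta_sex_male",
    "sigma_b",
    "sigma_w_insomnia",
    "sigma_w_control",
]

_LOG_SIGMA_B_FLOOR = -10.0


@dataclass(frozen=True)
class ContrastResult:
    """A planned insomnia-minus-control Wald contrast."""

    name: str
    estimate: float
    se: float
    df_num: int
    df_den: int

    @property
    def fvalue(self) -> float:
        return (self.estimate / self.se) ** 2

    @property
    def pvalue(self) -> float:
        return float(stats.f.sf(self.fvalue, self.df_num, self.df_den))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df_den)
        return self.estimate - tcrit * self.se, self.estimate + tcrit * self.se

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.conf_int()
        return (
            f"{self.name}: {self.estimate:.3f} (SE {self.se:.3f}), "
            f"F(1, {self.df_den}) = {self.fvalue:.2f}, p = {self.pvalue:.4g}, "
            f"95% CI [{lo:.3f}, {hi:.3f}]"
        )


class MixedLocationScaleModel:
    """Location-scale mixed model with a subject random intercept.

    Parameters
    ----------
    endog:
        Nightly outcome values.
    subject:
        Subject identifier per observation.
    group_insomnia:
        Insomnia-group indicator per observation (1 = insomnia).
    age, sex_male:
        Subject covariates per observation; age is centred at the mean age
        of the distinct subjects unless ``age_center`` is given.
    """

    def __init__(
        self,
        endog,
        subject,
        group_insomnia,
        age,
        sex_male,
        outcome: str = "outcome",
        age_center: float | None = None,
    ):
        df = pd.DataFrame(
            {
                "y": np.asarray(endog, dtype=float),
                "subject": np.asarray(subject),
                "group": np.asarray(group_insomnia, dtype=float),
                "age": np.asarray(age, dtype=float),
                "male": np.asarray(sex_male, dtype=float),
            }
        ).sort_values(["subject"], kind="mergesort").reset_index(drop=True)
        self.outcome = outcome

        subj_first = df.drop_duplicates("subject")
        if age_center is None:
            age_center = float(subj_first["age"].mean())
        self.age_center = age_center

        counts = df.groupby("subject", sort=True).size()
        self.subject_ids = counts.index.to_numpy()
        self.n_i = counts.to_numpy()
        self.n_subjects = len(self.n_i)
        self.n_obs = len(df)
        self.starts = np.concatenate([[0], np.cumsum(self.n_i)[:-1]])

        self.y = df["y"].to_numpy()
        self.X = np.column_stack(
            [
                np.ones(self.n_obs),
                df["group"].to_numpy(),
                df["age"].to_numpy() - age_center,
                df["male"].to_numpy(),
            ]
        )
        # subject-level group indicator (constant within subject)
        self.subj_group = df.groupby("subject", sort=True)["group"].first().to_numpy()
        self.ins_rows = df["group"].to_numpy() == 1.0
        self.ins_subj = self.subj_group == 1.0

        # per-subject and per-group sufficient statistics
        self.U = np.add.reduceat(self.X, self.starts, axis=0)  # X_i' 1
        self._XtX = {}
        self._Xty = {}
        self._yty = {}
        for label, mask in (("ins", self.ins_rows), ("ctl", ~self.ins_rows)):
            Xg, yg = self.X[mask], self.y[mask]
            self._XtX[label] = Xg.T @ Xg
            self._Xty[label] = Xg.T @ yg
            self._yty[label] = float(yg @ yg)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_nights(
        cls,
        nights: pd.DataFrame,
        subjects: pd.DataFrame,
        outcome: str,
        age_center: float | None = None,
    ) -> "MixedLocationScaleModel":
        """Build the model from nightly-summary and subject tables.

        Invalid nights (``valid == False``) are excluded; the model fits
        exactly the observed valid nights (no imputation).
        """
        if outcome not in OUTCOME_COLUMNS:
            raise ValueError(
                f"unknown outcome {outcome!r}; choose from {sorted(OUTCOME_COLUMNS)}"
            )
        col = OUTCOME_COLUMNS[outcome]
        data = nights.loc[nights["valid"].astype(bool), ["subject_id", col]]
        merged = data.merge(
            subjects[["subject_id", "group", "age_years", "sex"]],
            on="subject_id",
            validate="many_to_one",
        )
        return cls(
            endog=merged[col],
            subject=merged["subject_id"],
            group_insomnia=(merged["group"] == "insomnia").astype(float),
            age=merged["age_years"],
            sex_male=(merged["sex"] == "male").astype(float),
            outcome=outcome,
            age_center=age_center,
        )

    def _validate(self) -> None:
        for label, mask in (("insomnia", self.ins_subj), ("control", ~self.ins_subj)):
            ok = (self.n_i[mask] >= 2).sum()
            if mask.sum() < 2 or ok < 2:
                raise ValueError(
                    f"need at least two {label} subjects with two or more "
                    "observed nights"
                )
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            raise ValueError("mean-model design matrix is rank deficient")

    # -- likelihood -------------------------------------------------------

    def _variances(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        b2 = np.exp(2.0 * params[4])
        s2_subj = np.where(
            self.ins_subj, np.exp(2.0 * params[5]), np.exp(2.0 * params[6])
        )
        return b2, s2_subj

    def neg_loglike(self, params: Sequence[float]) -> float:
        """Closed-form negative marginal log-likelihood.

        ``params`` is the internal vector ``[beta_0, beta_group, beta_age,
        beta_sex, log sigma_b, log sigma_w_ins, log sigma_w_ctl]``.  Each
        subject contributes a multivariate-normal density with
        compound-symmetric covariance, evaluated through the rank-one
        (Sherman-Morrison) structure.
        """
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            return float("inf")
        beta = params[:4]
        b2, s2 = self._variances(params)
        r = self.y - self.X @ beta
        S = np.add.reduceat(r, self.starts)
        D = s2 + self.n_i * b2
        Q_ins = float(r[self.ins_rows] @ r[self.ins_rows])
        Q_ctl = float(r[~self.ins_rows] @ r[~self.ins_rows])
        s2_ins, s2_ctl = np.exp(2.0 * params[5]), np.exp(2.0 * params[6])
        nll = 0.5 * (
            self.n_obs * np.log(2.0 * np.pi)
            + float(((self.n_i - 1) * np.log(s2)).sum())
            + float(np.log(D).sum())
            + Q_ins / s2_ins
            + Q_ctl / s2_ctl
            - float((b2 * S**2 / (s2 * D)).sum())
        )
        return float(nll) if np.isfinite(nll) else float("inf")

    def score(self, params: Sequence[float]) -> np.ndarray:
        """Analytic gradient of :meth:`neg_loglike` (internal scale)."""
        params = np.asarray(params, dtype=float)
        beta = params[:4]
        b2, s2 = self._variances(params)
        r = self.y - self.X @ beta
        S = np.add.reduceat(r, self.starts)
        D = s2 + self.n_i * b2
        c = b2 * S / (s2 * D)  # per-subject weight on X_i'1

        s2_ins, s2_ctl = np.exp(2.0 * params[5]), np.exp(2.0 * params[6])
        Xtr_ins = self.X[self.ins_rows].T @ r[self.ins_rows]
        Xtr_ctl = self.X[~self.ins_rows].T @ r[~self.ins_rows]
        g_beta = -(Xtr_ins / s2_ins + Xtr_ctl / s2_ctl - self.U.T @ c)

        # d/d(sigma_w^2) per group
        g_s2 = np.empty(2)
        for k, (mask, s2g, Q) in enumerate(
            (
                (self.ins_subj, s2_ins, float(r[self.ins_rows] @ r[self.ins_rows])),
                (~self.ins_subj, s2_ctl, float(r[~self.ins_rows] @ r[~self.ins_rows])),
            )
        ):
            n_g, D_g, S_g = self.n_i[mask], D[mask], S[mask]
            g_s2[k] = 0.5 * (
                float(((n_g - 1) / s2g).sum())
                + float((1.0 / D_g).sum())
                - Q / s2g**2
                + float((b2 * S_g**2 * (D_g + s2g) / (s2g**2 * D_g**2)).sum())
            )
        g_b2 = 0.5 * float((self.n_i / D - S**2 / D**2).sum())

        grad = np.empty(7)
        grad[:4] = g_beta
        grad[4] = g_b2 * 2.0 * b2
        grad[5] = g_s2[0] * 2.0 * s2_ins
        grad[6] = g_s2[1] * 2.0 * s2_ctl
        return grad

    # -- profiled fitting -------------------------------------------------

    def _gls_beta(self, theta: np.ndarray) -> np.ndarray:
        """Closed-form GLS mean coefficients given the variance parameters."""
        b2 = np.exp(2.0 * theta[0])
        s2_ins, s2_ctl = np.exp(2.0 * theta[1]), np.exp(2.0 * theta[2])
        s2 = np.where(self.ins_subj, s2_ins, s2_ctl)
        D = s2 + self.n_i * b2
        c = b2 / (s2 * D)
        A = self._XtX["ins"] / s2_ins + self._XtX["ctl"] / s2_ctl
        A = A - (self.U * c[:, None]).T @ self.U
        Sy = np.add.reduceat(self.y, self.starts)
        rhs = self._Xty["ins"] / s2_ins + self._Xty["ctl"] / s2_ctl
        rhs = rhs - self.U.T @ (c * Sy)
        return np.linalg.solve(A, rhs)

    def _profiled(self, theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        beta = self._gls_beta(theta)
        full = np.concatenate([beta, theta])
        nll = self.neg_loglike(full)
        grad = self.score(full)[4:]  # envelope: d(profiled)/d(theta)
        return nll, grad, beta

    def _start_values(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        r = self.y - self.X @ beta
        rbar = np.add.reduceat(r, self.starts) / self.n_i
        within_ss = np.add.reduceat(r**2, self.starts) - self.n_i * rbar**2
        s2w = np.empty(2)
        for k, mask in enumerate((self.ins_subj, ~self.ins_subj)):
            dof = float((self.n_i[mask] - 1).sum())
            s2w[k] = max(within_ss[mask].sum() / max(dof, 1.0), 1e-6)
        s2_subj = np.where(self.ins_subj, s2w[0], s2w[1])
        b2 = max(float(np.var(rbar)) - float(np.mean(s2_subj / self.n_i)), 1e-4 * s2w.mean())
        return np.array([0.5 * np.log(b2), 0.5 * np.log(s2w[0]), 0.5 * np.log(s2w[1])])

    def fit(
        self,
        ddf_rule: str = "n_minus_5",
        start: Sequence[float] | None = None,
        gtol: float = 1e-9,
        max_newton: int = 40,
    ) -> "MixedLocationScaleResults":
        """Maximise the marginal likelihood.

        The mean coefficients are profiled out in closed form (GLS), so the
        optimiser works on the three log-scale variance parameters only:
        quasi-Newton (L-BFGS-B, with the log sigma_b floor) followed by
        Newton polishing with a finite-difference Hessian of the analytic
        gradient.  ``ddf_rule`` sets the Wald denominator df:
        ``n_minus_5`` (number of subjects minus 5) or ``n_minus_rank``
        (subjects minus the mean-design rank, 4).
        """
        self._validate()
        if ddf_rule == "n_minus_5":
            ddf = self.n_subjects - 5
        elif ddf_rule == "n_minus_rank":
            ddf = self.n_subjects - self.X.shape[1]
        else:
            raise ValueError("ddf_rule must be 'n_minus_5' or 'n_minus_rank'")
        if ddf < 1:
            raise ValueError("too few subjects for the requested ddf rule")

        theta0 = np.asarray(start, dtype=float) if start is not None else self._start_values()
        bounds = [(_LOG_SIGMA_B_FLOOR, 12.0), (-12.0, 12.0), (-12.0, 12.0)]
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

        res = minimize(
            lambda t: self._profiled(t)[:2],
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = np.asarray(res.x, dtype=float)

        # Newton polish on the profiled objective
        nll, grad, _ = self._profiled(theta)
        for _ in range(max_newton):
            at_floor = theta[0] <= _LOG_SIGMA_B_FLOOR + 1e-9
            active = grad.copy()
            if at_floor and grad[0] > 0:
                active[0] = 0.0
            if np.max(np.abs(active)) < gtol:
                break
            H = self._numeric_hessian_profiled(theta)
            try:
                step = np.linalg.solve(H, active)
            except np.linalg.LinAlgError:
                break
            # near the optimum the NLL is flat to machine precision, so accept
            # a step when either the NLL or the gradient norm improves
            scale = 1.0
            gnorm = np.max(np.abs(active))
            for _bt in range(30):
                cand = theta - scale * step
                cand[0] = max(cand[0], _LOG_SIGMA_B_FLOOR)
                nll_c, grad_c, _ = self._profiled(cand)
                if nll_c < nll - 1e-12 or np.max(np.abs(grad_c)) < gnorm:
                    theta, nll, grad = cand, nll_c, grad_c
                    break
                scale *= 0.5
            else:
                break

        beta = self._gls_beta(theta)
        full = np.concatenate([beta, theta])
        full_grad = self.score(full)
        at_floor = theta[0] <= _LOG_SIGMA_B_FLOOR + 1e-9
        check = full_grad.copy()
        if at_floor and check[4] > 0:
            check[4] = 0.0
        grad_norm = float(np.max(np.abs(check)))

        hess = self._numeric_hessian_full(full)
        singular_hessian = False
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(hess)
            singular_hessian = True
        vcov = 0.5 * (vcov + vcov.T)

        converged = bool(np.isfinite(nll)) and grad_norm < 1e-6 and not singular_hessian
        return MixedLocationScaleResults(
            model=self,
            params_internal=full,
            vcov_internal=vcov,
            llf=-nll,
            converged=converged,
            grad_norm=grad_norm,
            singular_hessian=singular_hessian,
            sigma_b_at_floor=bool(at_floor),
            ddf=int(ddf),
            ddf_rule=ddf_rule,
            optimizer_message=str(res.message),
        )

    # -- numerical Hessians ----------------------------------------------

    def _numeric_hessian_profiled(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        H = np.empty((3, 3))
        for k in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            H[k] = (self._profiled(tp)[1] - self._profiled(tm)[1]) / (2.0 * h)
        return 0.5 * (H + H.T)

    def _numeric_hessian_full(self, params: np.ndarray, h: float = 1e-6) -> np.ndarray:
        n = len(params)
        H = np.empty((n, n))
        for k in range(n):
            step = h * max(1.0, abs(params[k]))
            pp, pm = params.copy(), params.copy()
            pp[k] += step
            pm[k] -= step
            H[k] = (self.score(pp) - self.score(pm)) / (2.0 * step)
        return 0.5 * (H + H.T)


class MixedLocationScaleResults:
    """Fitted location-scale model: estimates, uncertainty and contrasts."""

    def __init__(
        self,
        model: MixedLocationScaleModel,
        params_internal: np.ndarray,
        vcov_internal: np.ndarray,
        llf: float,
        converged: bool,
        grad_norm: float,
        singular_hessian: bool,
        sigma_b_at_floor: bool,
        ddf: int,
        ddf_rule: str,
        optimizer_message: str = "",
    ):
        self.model = model
        self.params_internal = params_internal
        self.vcov_internal = vcov_internal
        self.llf = llf
        self.converged = converged
        self.grad_norm = grad_norm
        self.singular_hessian = singular_hessian
        self.sigma_b_at_floor = sigma_b_at_floor
        self.ddf = ddf
        self.ddf_rule = ddf_rule
        self.optimizer_message = optimizer_message

    # -- natural-scale parameters -----------------------------------------

    @property
    def params(self) -> pd.Series:
        """Point estimates on the natural scale.

        ``sigma_b`` is reported as 0 when the optimiser pinned it at the
        log-scale floor (boundary solution).
        """
        p = self.params_internal
        sigma_b = 0.0 if self.sigma_b_at_floor else float(np.exp(p[4]))
        values = [*p[:4], sigma_b, float(np.exp(p[5])), float(np.exp(p[6]))]
        return pd.Series(values, index=PARAM_NAMES, name=self.model.outcome)

    @property
    def bse(self) -> pd.Series:
        """Delta-method standard errors on the natural scale."""
        se_int = np.sqrt(np.clip(np.diag(self.vcov_internal), 0.0, None))
        sigmas = np.exp(self.params_internal[4:])
        values = [*se_int[:4], *(sigmas * se_int[4:])]
        return pd.Series(values, index=PARAM_NAMES, name="se")

    @property
    def vcov(self) -> pd.DataFrame:
        """Natural-scale variance-covariance of the estimates (delta method)."""
        jac = np.ones(7)
        jac[4:] = np.exp(self.params_internal[4:])
        V = self.vcov_internal * np.outer(jac, jac)
        return pd.DataFrame(V, index=PARAM_NAMES, columns=PARAM_NAMES)

    # -- contrasts ---------------------------------------------------------

    def _require_convergence(self) -> None:
        if not self.converged:
            raise RuntimeError(
                "model did not converge; contrasts are unavailable "
                f"(gradient max-norm {self.grad_norm:.2e})"
            )

    def mean_contrast(self) -> ContrastResult:
        """Insomnia-minus-control difference in adjusted group means."""
        self._require_convergence()
        est = float(self.params_internal[1])
        se = float(np.sqrt(self.vcov_internal[1, 1]))
        return ContrastResult(f"{self.model.outcome} mean", est, se, 1, self.ddf)

    def sd_contrast(self) -> ContrastResult:
        """Insomnia-minus-control difference in within-subject SDs.

        The SE follows by the delta method from the log-scale covariance of
        the two scale parameters.
        """
        self._require_convergence()
        s_ins = float(np.exp(self.params_internal[5]))
        s_ctl = float(np.exp(self.params_internal[6]))
        V = self.vcov_internal[5:7, 5:7]
        grad = np.array([s_ins, -s_ctl])
        var = float(grad @ V @ grad)
        return ContrastResult(
            f"{self.model.outcome} within-subject SD",
            s_ins - s_ctl,
            float(np.sqrt(var)),
            1,
            self.ddf,
        )

    # -- prediction --------------------------------------------------------

    def predict_at(self, sex: str | float = "female", age: float = 36.1) -> pd.DataFrame:
        """Model-predicted group means at fixed covariates.

        ``sex`` may be "female", "male" or a male fraction in [0, 1]; age is
        in years on the original (uncentred) scale.
        """
        self._require_convergence()
        male = {"female": 0.0, "male": 1.0}.get(sex, sex)
        rows = []
        beta = self.params_internal[:4]
        Vb = self.vcov_internal[:4, :4]
        for group, g in (("insomnia", 1.0), ("control", 0.0)):
            x = np.array([1.0, g, age - self.model.age_center, float(male)])
            rows.append(
                {
                    "group": group,
                    "mean": float(x @ beta),
                    "se": float(np.sqrt(x @ Vb @ x)),
                }
            )
        return pd.DataFrame(rows).set_index("group")

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table."""
        p, se = self.params, self.bse
        lines = [
            f"Mixed location-scale model: {self.model.outcome}",
            f"  subjects: {self.model.n_subjects}   nights: {self.model.n_obs}   "
            f"log-likelihood: {self.llf:.3f}",
            f"  converged: {self.converged} (grad max-norm {self.grad_norm:.1e}, "
            f"ddf rule {self.ddf_rule} -> {self.ddf})",
            "",
            f"  {'parameter':<20} {'estimate':>12} {'SE':>10}",
        ]
        for name in PARAM_NAMES:
            lines.append(f"  {name:<20} {p[name]:>12.4f} {se[name]:>10.4f}")
        lines.append("")
        for contrast in (self.mean_contrast(), self.sd_contrast()):
            lines.append("  " + str(contrast))
        return "\n".join(lines)


def weekly_summaries(
    nights: pd.DataFrame,
    outcomes: Sequence[str] = tuple(OUTCOME_COLUMNS),
    n_weeks: int | None = None,
) -> pd.DataFrame:
    """Per-subject weekly means and SDs of the nightly parameters.

    Week *w* covers nights ``7(w-1)+1 .. 7w``.  SDs use the n-1 denominator
    and are left null (NaN) for weeks with fewer than two observed nights;
    weeks with no observed nights are omitted entirely.
    """
    valid = nights.loc[nights["valid"].astype(bool)].copy()
    valid["week"] = (valid["night_index"].astype(int) - 1) // 7 + 1
    if n_weeks is not None:
        valid = valid.loc[valid["week"] <= n_weeks]
    records = []
    for (sid, week), grp in valid.groupby(["subject_id", "week"], sort=True):
        for outcome in outcomes:
            col = OUTCOME_COLUMNS[outcome]
            vals = grp[col].to_numpy(dtype=float)
            records.append(
                {
                    "subject_id": sid,
                    "week": int(week),
                    "outcome": outcome,
                    "n_nights": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(
        records, columns=["subject_id", "week", "outcome", "n_nights", "mean", "sd"]
    )
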