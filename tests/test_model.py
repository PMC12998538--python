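"""Location-scale mixed model: likelihood oracles, invariances, contrasts."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp, roots_hermite
from scipy.stats import norm

from noctvar import (
    MixedLocationScaleModel,
    simulate_cohort,
    targets_to_nights_frame,
    weekly_summaries,
)


def make_model(n_subjects=10, n_nights=6, seed=3, sigma_b=3.0,
               sigma_ins=8.0, sigma_ctl=4.0, beta=(50.0, 10.0, 0.2, -1.5)):
    """Small location-scale dataset with known generating parameters."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        group = 1.0 if i < n_subjects // 2 else 0.0
        age = float(rng.uniform(20, 60))
        male = float(rng.integers(0, 2))
        b_i = rng.normal(0, sigma_b)
        sw = sigma_ins if group else sigma_ctl
        for j in range(n_nights):
            mu = beta[0] + beta[1] * group + beta[2] * (age - 40.0) + beta[3] * male
            rows.append(
                {"y": mu + b_i + rng.normal(0, sw), "subject": f"s{i:02d}",
                 "group": group, "age": age, "male": male}
            )
    df = pd.DataFrame(rows)
    return MixedLocationScaleModel(
        df["y"], df["subject"], df["group"], df["age"], df["male"],
        age_center=40.0,
    )


# ---------------------------------------------------------------------------
# likelihood oracles
# ---------------------------------------------------------------------------

def gauss_hermite_nll(model, params, n_nodes=64):
    """Adaptive Gauss-Hermite evaluation of the marginal likelihood.

    Integrates each subject's random intercept numerically, centring and
    scaling the nodes at the (closed-form) Gaussian posterior of b_i.
    Written directly from the integral definition as an independent oracle.
    """
    params = np.asarray(params, dtype=float)
    beta = params[:4]
    sigma_b = np.exp(params[4])
    nodes, weights = roots_hermite(n_nodes)
    r = model.y - model.X @ beta
    nll = 0.0
    for i in range(model.n_subjects):
        lo = model.starts[i]
        hi = lo + model.n_i[i]
        ri = r[lo:hi]
        sw = np.exp(params[5]) if model.ins_subj[i] else np.exp(params[6])
        prec = model.n_i[i] / sw**2 + 1.0 / sigma_b**2
        v = 1.0 / prec
        mode = v * ri.sum() / sw**2
        b = mode + np.sqrt(2.0 * v) * nodes
        logf = (
            norm.logpdf(ri[None, :], loc=b[:, None], scale=sw).sum(axis=1)
            + norm.logpdf(b, loc=0.0, scale=sigma_b)
        )
        log_li = 0.5 * np.log(2.0 * v) + logsumexp(np.log(weights) + nodes**2 + logf)
        nll -= log_li
    return nll


def test_nll_single_observation_is_standard_normal_density():
    """One subject, one night, zero residual, unit scale: NLL = ln(2*pi)/2."""
    model = MixedLocationScaleModel([5.0], ["a"], [1.0], [30.0], [0.0],
                                    age_center=30.0)
    params = [5.0, 0.0, 0.0, 0.0, -10.0, 0.0, 0.0]
    assert model.neg_loglike(params) == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-8)


def test_closed_form_matches_gauss_hermite_quadrature():
    """Rank-one closed form equals 64-node adaptive quadrature to 1e-8."""
    rng = np.random.default_rng(8)
    for seed in range(5):
        model = make_model(n_subjects=5, n_nights=4, seed=seed)
        for _ in range(3):
            params = np.array([
                rng.normal(50, 5), rng.normal(8, 3), rng.normal(0, 0.3),
                rng.normal(0, 2), rng.normal(1.0, 0.5), rng.normal(2.0, 0.3),
                rng.normal(1.5, 0.3),
            ])
            assert model.neg_loglike(params) == pytest.approx(
                gauss_hermite_nll(model, params), abs=1e-8
            )


def test_duplicating_every_subject_doubles_the_nll():
    model = make_model(n_subjects=6, n_nights=5, seed=1)
    y = np.concatenate([model.y, model.y])
    subj = np.concatenate(
        [[f"a{s}" for s in model.subject_ids[np.searchsorted(
            np.cumsum(model.n_i), np.arange(model.n_obs), side="right")]],
         [f"b{s}" for s in model.subject_ids[np.searchsorted(
            np.cumsum(model.n_i), np.arange(model.n_obs), side="right")]]]
    )
    grp = np.concatenate([model.X[:, 1], model.X[:, 1]])
    age = np.concatenate([model.X[:, 2] + 40.0, model.X[:, 2] + 40.0])
    male = np.concatenate([model.X[:, 3], model.X[:, 3]])
    doubled = MixedLocationScaleModel(y, subj, grp, age, male, age_center=40.0)
    params = [50.0, 8.0, 0.1, -1.0, 1.0, 2.0, 1.5]
    assert doubled.neg_loglike(params) == pytest.approx(
        2.0 * model.neg_loglike(params), rel=1e-12
    )


def test_analytic_score_matches_finite_differences():
    model = make_model(n_subjects=8, n_nights=5, seed=5)
    params = np.array([48.0, 9.0, 0.15, -2.0, 1.2, 2.1, 1.4])
    grad = model.score(params)
    h = 1e-6
    for k in range(7):
        pp, pm = params.copy(), params.copy()
        pp[k] += h
        pm[k] -= h
        numeric = (model.neg_loglike(pp) - model.neg_loglike(pm)) / (2 * h)
        assert grad[k] == pytest.approx(numeric, rel=1e-5, abs=1e-5)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_generating_parameters():
    model = make_model(n_subjects=60, n_nights=20, seed=11)
    fit = model.fit()
    assert fit.converged and fit.grad_norm < 1e-6
    p, se = fit.params, fit.bse
    for name, truth in (("beta_group", 10.0), ("sigma_w_insomnia", 8.0),
                        ("sigma_w_control", 4.0), ("sigma_b", 3.0)):
        assert abs(p[name] - truth) < 4.0 * se[name] + 1e-9


def test_row_permutation_and_relabel_invariance():
    base = make_model(n_subjects=12, n_nights=6, seed=2)
    fit0 = base.fit()
    rng = np.random.default_rng(0)
    order = rng.permutation(base.n_obs)
    subj_of_row = np.repeat(np.arange(base.n_subjects), base.n_i)
    relabel = {i: f"z{(7 * i + 3) % base.n_subjects:02d}" for i in range(base.n_subjects)}
    permuted = MixedLocationScaleModel(
        base.y[order],
        [relabel[subj_of_row[k]] for k in order],
        base.X[order, 1],
        base.X[order, 2] + 40.0,
        base.X[order, 3],
        age_center=40.0,
    )
    fit1 = permuted.fit()
    np.testing.assert_allclose(
        fit1.params.to_numpy(), fit0.params.to_numpy(), rtol=1e-8, atol=1e-8
    )
    assert fit1.llf == pytest.approx(fit0.llf, abs=1e-8)


def test_age_centering_changes_only_the_intercept():
    base = make_model(n_subjects=12, n_nights=6, seed=6)
    fit0 = base.fit()
    recentred = MixedLocationScaleModel(
        base.y, np.repeat(base.subject_ids, base.n_i), base.X[:, 1],
        base.X[:, 2] + 40.0, base.X[:, 3], age_center=30.0,
    )
    fit1 = recentred.fit()
    p0, p1 = fit0.params, fit1.params
    # x'beta invariance: b0_new + b_age*(a - 30) == b0_old + b_age*(a - 40)
    assert p1["beta_intercept"] == pytest.approx(
        p0["beta_intercept"] - 10.0 * p0["beta_age"], rel=1e-6
    )
    for name in ("beta_group", "beta_age", "beta_sex_male", "sigma_w_insomnia",
                 "sigma_w_control"):
        assert p1[name] == pytest.approx(p0[name], rel=1e-6, abs=1e-8)


def test_zero_between_subject_variance_is_handled_at_the_boundary():
    """Data with no subject effect: sigma_b collapses toward 0 without crashing."""
    model = make_model(n_subjects=40, n_nights=20, seed=9, sigma_b=0.0,
                       sigma_ins=5.0, sigma_ctl=5.0)
    fit = model.fit()
    assert np.isfinite(fit.llf)
    assert fit.params["sigma_b"] < 1.0
    assert fit.params["sigma_w_insomnia"] == pytest.approx(5.0, rel=0.15)


def test_contrasts_on_null_truth_are_unremarkable():
    model = make_model(n_subjects=40, n_nights=12, seed=14, beta=(50, 0.0, 0, 0),
                       sigma_ins=6.0, sigma_ctl=6.0)
    fit = model.fit()
    for contrast in (fit.mean_contrast(), fit.sd_contrast()):
        assert abs(contrast.estimate) < 4.0 * contrast.se
        lo, hi = contrast.conf_int()
        assert lo < 0.0 < hi or abs(contrast.estimate) < 4.0 * contrast.se
        assert 0.0 < contrast.pvalue <= 1.0


def test_contrasts_unavailable_before_convergence():
    model = make_model(n_subjects=8, n_nights=4, seed=4)
    fit = model.fit()
    fit.converged = False
    with pytest.raises(RuntimeError, match="did not converge"):
        fit.mean_contrast()


def test_ddf_rules():
    model = make_model(n_subjects=20, n_nights=5, seed=7)
    assert model.fit(ddf_rule="n_minus_5").ddf == 15
    assert model.fit(ddf_rule="n_minus_rank").ddf == 16
    with pytest.raises(ValueError):
        model.fit(ddf_rule="bogus")


def test_predictions_respect_design_algebra():
    model = make_model(n_subjects=16, n_nights=8, seed=12)
    fit = model.fit()
    pred = fit.predict_at(sex="female", age=36.1)
    assert pred.loc["insomnia", "mean"] - pred.loc["control", "mean"] == pytest.approx(
        fit.params["beta_group"], rel=1e-10
    )
    # at each group's own observation-mean covariates, the prediction equals
    # the group's mean fitted value (regression identity)
    beta = fit.params_internal[:4]
    fitted = model.X @ beta
    for g, mask in (("insomnia", model.ins_rows), ("control", ~model.ins_rows)):
        mean_age = model.X[mask, 2].mean() + 40.0
        male_frac = model.X[mask, 3].mean()
        pred_g = fit.predict_at(sex=male_frac, age=mean_age).loc[g, "mean"]
        assert pred_g == pytest.approx(fitted[mask].mean(), rel=1e-10)


# ---------------------------------------------------------------------------
# independent cross-check: R nlme (lme + varIdent), ML
# ---------------------------------------------------------------------------

R_SCRIPT = """
suppressMessages({library(nlme); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$group <- factor(d$group_label, levels = c("control", "insomnia"))
m <- lme(y ~ group + age_c + male, random = ~ 1 | subject,
         weights = varIdent(form = ~ 1 | group), data = d, method = "ML",
         control = lmeControl(maxIter = 500, msMaxIter = 500,
                              tolerance = 1e-12, msTol = 1e-12))
vw <- coef(m$modelStruct$varStruct, unconstrained = FALSE, allCoef = TRUE)
sds <- m$sigma * vw
out <- list(beta = as.numeric(fixef(m)),
            sigma_b = as.numeric(VarCorr(m)["(Intercept)", "StdDev"]),
            sigma_w = as.list(sds),
            loglik = as.numeric(logLik(m)))
cat(toJSON(out, auto_unbox = TRUE, digits = 12))
"""


def test_matches_r_nlme_maximum_likelihood(tmp_path, small_config):
    """Estimates and log-likelihood agree with nlme::lme + varIdent (ML)."""
    assert shutil.which("Rscript"), "Rscript is required for the nlme cross-check"
    cohort = simulate_cohort(small_config, seed=5)
    nights = targets_to_nights_frame(cohort.targets)
    model = MixedLocationScaleModel.from_nights(nights, cohort.subjects, "waso")
    fit = model.fit()

    data = pd.DataFrame(
        {
            "y": model.y,
            "subject": np.repeat(model.subject_ids, model.n_i),
            "group_label": np.where(model.ins_rows, "insomnia", "control"),
            "age_c": model.X[:, 2],
            "male": model.X[:, 3],
        }
    )
    csv = tmp_path / "nights.csv"
    data.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(R_SCRIPT)
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv)],
        capture_output=True, text=True, timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    ref = json.loads(proc.stdout)

    np.testing.assert_allclose(
        fit.params_internal[:4], np.asarray(ref["beta"]), rtol=2e-3, atol=1e-3
    )
    assert fit.params["sigma_b"] == pytest.approx(ref["sigma_b"], rel=5e-3)
    assert fit.params["sigma_w_insomnia"] == pytest.approx(
        ref["sigma_w"]["insomnia"], rel=5e-3
    )
    assert fit.params["sigma_w_control"] == pytest.approx(
        ref["sigma_w"]["control"], rel=5e-3
    )
    assert fit.llf == pytest.approx(ref["loglik"], abs=1e-3)
    assert fit.llf >= ref["loglik"] - 1e-4  # ours is a true maximum


# ---------------------------------------------------------------------------
# weekly summaries
# ---------------------------------------------------------------------------

def weekly_frame(values_by_night, sid="s1"):
    rows = []
    for night, value in values_by_night.items():
        rows.append({"subject_id": sid, "night_index": night, "valid": True,
                     "sl_adj_min": 0.0, "tst_min": value, "waso_min": 0.0,
                     "final_awakening_min": 0.0, "tib_min": value,
                     "sleep_efficiency_pct": 100.0})
    return pd.DataFrame(rows)


def test_weekly_summaries_hand_computed():
    nights = weekly_frame({n: float(n) for n in range(1, 8)})
    out = weekly_summaries(nights, outcomes=("tst",))
    row = out[(out["week"] == 1) & (out["outcome"] == "tst")].iloc[0]
    assert row["mean"] == 4.0
    assert row["sd"] == pytest.approx(np.sqrt(28.0 / 6.0))  # 2.1602...


def test_weekly_summaries_degenerate_weeks():
    nights = weekly_frame({**{n: 7.0 for n in range(1, 8)}, 9: 5.0})
    out = weekly_summaries(nights, outcomes=("tst",)).set_index("week")
    assert out.loc[1, "sd"] == 0.0  # identical nights
    assert out.loc[2, "mean"] == 5.0  # single night: mean defined ...
    assert np.isnan(out.loc[2, "sd"])  # ... SD explicitly null
    assert set(out.index) == {1, 2}  # empty weeks omitted, not zero-filled
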