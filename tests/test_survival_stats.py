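"""Kaplan-Meier, log-rank, Cox, PH diagnostics, RMST, interaction LRT, power."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import proportional_hazard_test
from scipy import stats as sps

from irskit.stats import (
    PowerSpec,
    benjamini_hochberg,
    check_ph,
    fit_coxph,
    km_estimate,
    logrank_test,
    lrt_interaction,
    power_cox,
    rmst,
    rmst_difference,
    spearman_corr,
)


# -------------------------------------------------------------- Kaplan-Meier

def test_km_no_events_survival_one_median_unbounded():
    km = km_estimate([5, 6, 7], [False, False, False])
    assert np.all(km.survival == 1.0)
    assert np.isinf(km.median)


def test_km_three_events_hand_product_limit():
    km = km_estimate([1, 2, 3], [True, True, True])
    assert km.survival == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])
    assert km.median == 2.0


def test_km_exponential_median_closed_form(rng):
    lam = 0.2
    t = rng.exponential(1 / lam, size=10_000)
    km = km_estimate(t, np.ones_like(t, bool))
    assert km.median == pytest.approx(np.log(2) / lam, rel=0.05)


def test_km_equals_empirical_survival_without_censoring(rng):
    t = rng.exponential(1.0, size=500)
    km = km_estimate(t, np.ones_like(t, bool))
    ecdf_surv = 1.0 - np.searchsorted(np.sort(t), km.times, side="right") / len(t)
    assert np.allclose(km.survival, ecdf_surv, atol=1e-12)


# ------------------------------------------------------------------- log-rank

def test_logrank_identical_groups_null():
    d = [1, 2, 3, 4]
    e = [True] * 4
    stat, p = logrank_test(d + d, e + e, [0] * 4 + [1] * 4)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_hand_observed_minus_expected():
    """Two groups, A events at 1,2 and B at 3,4: textbook O-E computation."""
    durations = [1, 2, 3, 4]
    events = [True] * 4
    groups = ["A", "A", "B", "B"]
    # hand trace: per event time, O-E for A and hypergeometric variance
    o_minus_e, var = 0.0, 0.0
    at_risk = [("A", 1), ("A", 2), ("B", 3), ("B", 4)]
    for t in [1, 2, 3, 4]:
        risk = [(g, tt) for g, tt in at_risk if tt >= t]
        n = len(risk)
        n_a = sum(1 for g, _ in risk if g == "A")
        d = 1
        obs_a = 1 if ("A", t) in risk else 0
        exp_a = d * n_a / n
        o_minus_e += obs_a - exp_a
        if n > 1:
            var += d * n_a * (n - n_a) * (n - d) / (n**2 * (n - 1))
    expected_chi2 = o_minus_e**2 / var
    stat, p = logrank_test(durations, events, groups)
    assert stat == pytest.approx(expected_chi2, rel=1e-9)


# ------------------------------------------------------------------ Cox model

def test_cox_null_covariate_hr_near_one(rng):
    n = 3000
    x = rng.normal(size=n)
    t = rng.exponential(1.0, size=n)
    df = pd.DataFrame({"duration_months": t, "event": True, "x": x})
    fit = fit_coxph(df, covariates=["x"])
    assert fit.hazard_ratios["x"] == pytest.approx(1.0, abs=0.1)
    assert fit.tie_method == "Efron"


def test_cox_recovers_rate_ratio_two(rng):
    n = 5000
    g = rng.binomial(1, 0.5, n)
    t = rng.exponential(1.0 / np.where(g == 1, 2.0, 1.0))
    df = pd.DataFrame({"duration_months": t, "event": True, "g": g.astype(float)})
    fit = fit_coxph(df, covariates=["g"])
    se = fit.standard_errors["g"]
    assert abs(fit.coefficients["g"] - np.log(2.0)) < 3 * se
    assert fit.hazard_ratios["g"] == pytest.approx(
        np.exp(fit.coefficients["g"]), rel=1e-9
    )


def test_cox_cluster_robust_se_reported(rng):
    n = 400
    pid = np.repeat(np.arange(n // 2), 2)
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.3 * x))
    df = pd.DataFrame({"duration_months": t, "event": True, "x": x, "pid": pid})
    fit = fit_coxph(df, covariates=["x"], cluster_col="pid")
    assert fit.robust_standard_errors is not None
    assert fit.robust_standard_errors["x"] > 0
    assert fit.robust_standard_errors["x"] != fit.standard_errors["x"]


def test_cox_time_rescaling_invariance(rng):
    n = 500
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.5 * x))
    df = pd.DataFrame({"duration_months": t, "event": True, "x": x})
    a = fit_coxph(df, covariates=["x"])
    df2 = df.assign(duration_months=df["duration_months"] * 7.3)
    b = fit_coxph(df2, covariates=["x"])
    assert a.coefficients["x"] == pytest.approx(b.coefficients["x"], rel=1e-8)


# -------------------------------------------------------------- PH diagnostics

def test_ph_single_covariate_global_df_one(rng):
    n = 300
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.4 * x))
    df = pd.DataFrame({"duration_months": t, "event": True, "x": x})
    res = check_ph(fit_coxph(df, covariates=["x"]))
    assert res.loc["GLOBAL", "df"] == 1
    assert res.loc["x", "df"] == 1


def test_ph_per_covariate_matches_lifelines(rng):
    n = 400
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    t = rng.exponential(np.exp(-0.5 * x1 + 0.3 * x2))
    c = rng.uniform(0, 3, n)
    df = pd.DataFrame(
        {"duration_months": np.minimum(t, c), "event": t <= c, "x1": x1, "x2": x2}
    )
    fit = fit_coxph(df, covariates=["x1", "x2"])
    mine = check_ph(fit, transform="rank")
    ll = proportional_hazard_test(fit._fitter, fit._data, time_transform="rank")
    for cov in ["x1", "x2"]:
        assert mine.loc[cov, "chi2"] == pytest.approx(
            float(ll.summary.loc[cov, "test_statistic"]), rel=1e-6
        )


def test_ph_detects_sign_reversal(rng):
    """An effect that reverses halfway through follow-up violates PH."""
    n = 1200
    g = rng.binomial(1, 0.5, n).astype(float)
    # piecewise hazard: protective early, harmful late
    t1 = rng.exponential(np.exp(-1.2 * g))
    t = np.where(t1 < 0.7, t1, 0.7 + rng.exponential(np.exp(1.2 * g)))
    df = pd.DataFrame({"duration_months": t, "event": True, "g": g})
    res = check_ph(fit_coxph(df, covariates=["g"]))
    assert res.loc["GLOBAL", "p"] < 0.01


# ------------------------------------------------------------------------ RMST

def test_rmst_no_events_equals_tau():
    r = rmst([30, 40, 50], [False, False, False], tau=24)
    assert r["rmst"] == pytest.approx(24.0)


def test_rmst_exponential_closed_form(rng):
    lam, tau = 0.1, 12.0
    t = rng.exponential(1 / lam, size=8000)
    r = rmst(t, np.ones_like(t, bool), tau)
    assert r["rmst"] == pytest.approx((1 - np.exp(-lam * tau)) / lam, rel=0.02)


def test_rmst_tau_beyond_followup_names_group():
    with pytest.raises(ValueError, match="late"):
        rmst([1, 2, 3], [True, True, True], tau=10, label="late")


def test_rmst_difference_recovers_group_gap(rng):
    n = 1500
    g = np.repeat(["A", "B"], n)
    t = np.concatenate([rng.exponential(5, n), rng.exponential(10, n)])
    res = rmst_difference(t, np.ones(2 * n, bool), g, tau=12)
    expect = (1 - np.exp(-1.2)) * 10 - (1 - np.exp(-12 / 5)) * 5
    assert res["difference"] == pytest.approx(expect, rel=0.1)
    lo, hi = res["difference_ci"]
    assert lo < res["difference"] < hi


def test_rmst_adjusted_close_to_unadjusted_when_balanced(rng):
    n = 800
    g = rng.binomial(1, 0.5, n)
    x = rng.normal(size=n)  # independent of group
    t = rng.exponential(np.exp(0.7 * g + 0.2 * x))
    res = rmst_difference(
        t, np.ones(n, bool), np.where(g == 1, "B", "A"), tau=3,
        covariates=pd.DataFrame({"x": x}),
    )
    assert res["adjusted_difference"] == pytest.approx(res["difference"], abs=0.3)


# ----------------------------------------------------------- interaction LRT

def test_lrt_equal_models_statistic_zero(rng):
    n = 200
    df = pd.DataFrame(
        {
            "duration_months": rng.exponential(1, n),
            "event": True,
            "a": rng.normal(size=n),
        }
    )
    stat, dof, p = lrt_interaction(df, "duration_months", "event", ["a"], ["a"])
    assert (stat, dof, p) == (0.0, 0, 1.0)


def test_lrt_binary_interaction_df_one(rng):
    n = 400
    g = rng.binomial(1, 0.5, n).astype(float)
    b = rng.binomial(1, 0.5, n).astype(float)
    df = pd.DataFrame(
        {
            "duration_months": rng.exponential(np.exp(0.5 * g * b), n),
            "event": True,
            "g": g,
            "b": b,
            "gb": g * b,
        }
    )
    stat, dof, p = lrt_interaction(
        df, "duration_months", "event", ["g", "b", "gb"], ["g", "b"]
    )
    assert dof == 1
    assert stat >= 0
    with pytest.raises(ValueError, match="nested"):
        lrt_interaction(df, "duration_months", "event", ["g"], ["b"])


# ----------------------------------------------------------------------- power

def test_power_at_validation_design():
    power = power_cox(PowerSpec(hazard_ratio=0.5, event_rate=0.5, n=180))
    assert power == pytest.approx(0.90, abs=0.01)


def test_power_hr_one_degenerates_to_alpha():
    with pytest.warns(UserWarning):
        assert power_cox(PowerSpec(hazard_ratio=1.0, event_rate=0.5, n=100)) == 0.05


def test_power_monotone_in_n_and_effect():
    base = power_cox(PowerSpec(hazard_ratio=0.6, event_rate=0.5, n=150))
    more_n = power_cox(PowerSpec(hazard_ratio=0.6, event_rate=0.5, n=300))
    stronger = power_cox(PowerSpec(hazard_ratio=0.4, event_rate=0.5, n=150))
    assert more_n > base and stronger > base


def test_required_n_inverts_power():
    n = power_cox(PowerSpec(hazard_ratio=0.5, event_rate=0.5, power=0.9))
    achieved = power_cox(PowerSpec(hazard_ratio=0.5, event_rate=0.5, n=n))
    assert achieved == pytest.approx(0.9, abs=1e-6)


# ------------------------------------------------------------------- utilities

def test_spearman_perfect_and_hand_example():
    x = [1, 2, 3, 4, 5]
    assert spearman_corr(x, x) == pytest.approx(1.0)
    assert spearman_corr(x, [-v for v in x]) == pytest.approx(-1.0)
    y = [3, 1, 4, 1.5, 5]
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    brute = np.corrcoef(rx, ry)[0, 1]
    assert spearman_corr(x, y) == pytest.approx(brute, abs=1e-12)
    with pytest.raises(ValueError):
        spearman_corr([1, 1, 1], [1, 2, 3])


def test_benjamini_hochberg_monotone_and_order_preserving(rng):
    p = rng.uniform(size=30)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
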