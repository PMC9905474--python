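"""Survival statistics for biomarker validation.

Kaplan–Meier estimation, log-rank tests, covariate-adjusted Cox
proportional-hazards fits (Efron ties; cluster-robust variance for repeated
measures), Schoenfeld-residual proportional-hazards diagnostics, restricted
mean survival time (unadjusted, and covariate-adjusted via pseudo-value
regression), the likelihood-ratio test for biomarker-by-treatment
interaction, the Schoenfeld power/sample-size formula for the log-rank /
Cox setting, Spearman correlation, and Benjamini–Hochberg adjustment.

Built on lifelines for estimation; the Grambsch–Therneau global
proportional-hazards test is computed here from Schoenfeld residuals (the
per-covariate version is cross-checked against lifelines in the tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times, restricted_mean_survival_time
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- Kaplan–Meier

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with at-risk counts and median (95% CI)."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median: float            # inf if the curve never reaches 0.5
    median_ci: tuple[float, float]
    label: str = ""
    n: int = 0
    n_events: int = 0


def km_estimate(
    durations: Sequence[float], events: Sequence[bool], label: str = ""
) -> KMCurve:
    """Kaplan–Meier curve; median CI by the log-log (Brookmeyer–Crowley) method."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(durations) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events, label=label or "KM")
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    tab = kmf.event_table
    return KMCurve(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        n_at_risk=tab["at_risk"].to_numpy(),
        median=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
        label=label,
        n=len(durations),
        n_events=int(events.sum()),
    )


def logrank_test(
    durations: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> tuple[float, float]:
    """Two-sided log-rank test across two or more groups."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(labels) == 2:
        a, b = (groups == labels[0]), (groups == labels[1])
        res = _ll_logrank(durations[a], durations[b], events[a], events[b])
    else:
        res = multivariate_logrank_test(durations, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ------------------------------------------------------------------- Cox model

@dataclass(frozen=True)
class CoxFit:
    """Adjusted Cox PH fit summary (Efron ties)."""

    coefficients: Mapping[str, float]
    hazard_ratios: Mapping[str, float]
    ci_lower: Mapping[str, float]
    ci_upper: Mapping[str, float]
    standard_errors: Mapping[str, float]
    robust_standard_errors: Mapping[str, float] | None
    p_values: Mapping[str, float]
    partial_log_likelihood: float
    concordance: float
    n: int
    n_events: int
    tie_method: str
    _fitter: CoxPHFitter | None = None
    _data: pd.DataFrame | None = None


def fit_coxph(
    df: pd.DataFrame,
    duration_col: str = "duration_months",
    event_col: str = "event",
    covariates: Sequence[str] | None = None,
    cluster_col: str | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit with optional cluster-robust variance.

    Categorical covariates are dummy-coded (first level reference). With
    ``cluster_col``, sandwich standard errors grouped by cluster are
    reported alongside the model-based ones; p-values and CIs then use the
    robust variance.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in df.columns
        if c not in {duration_col, event_col, cluster_col}
    ]
    work = df[[duration_col, event_col] + covariates
              + ([cluster_col] if cluster_col else [])].copy()
    work[event_col] = work[event_col].astype(int)
    cat = [c for c in covariates
           if work[c].dtype == object or str(work[c].dtype) == "category"]
    if cat:
        work = pd.get_dummies(work, columns=cat, drop_first=True, dtype=float)
    if int(work[event_col].sum()) == 0:
        raise RuntimeError("no events: cannot fit a Cox model")

    base = CoxPHFitter()
    base.fit(work.drop(columns=[cluster_col] if cluster_col else []),
             duration_col=duration_col, event_col=event_col)
    robust_se = None
    rep = base
    if cluster_col:
        rep = CoxPHFitter()
        rep.fit(work, duration_col=duration_col, event_col=event_col,
                cluster_col=cluster_col)
        robust_se = {k: float(v) for k, v in rep.standard_errors_.items()}
    summ = rep.summary
    return CoxFit(
        coefficients={k: float(v) for k, v in rep.params_.items()},
        hazard_ratios={k: float(np.exp(v)) for k, v in rep.params_.items()},
        ci_lower={k: float(np.exp(v))
                  for k, v in summ["coef lower 95%"].items()},
        ci_upper={k: float(np.exp(v))
                  for k, v in summ["coef upper 95%"].items()},
        standard_errors={k: float(v) for k, v in base.standard_errors_.items()},
        robust_standard_errors=robust_se,
        p_values={k: float(v) for k, v in summ["p"].items()},
        partial_log_likelihood=float(base.log_likelihood_),
        concordance=float(base.concordance_index_),
        n=len(work),
        n_events=int(work[event_col].sum()),
        tie_method="Efron",
        _fitter=base,
        _data=work.drop(columns=[cluster_col] if cluster_col else []),
    )


def check_ph(
    fit: CoxFit, transform: str = "rank"
) -> pd.DataFrame:
    """Grambsch–Therneau test on scaled Schoenfeld residuals.

    Correlation of the scaled Schoenfeld residuals with (transformed) event
    time, per covariate (df = 1 each) and globally (df = number of
    covariates). ``transform`` is ``"rank"``, ``"km"`` or ``"identity"``.
    Returns a frame indexed by covariate plus a ``GLOBAL`` row, with columns
    ``chi2``, ``df``, ``p``.
    """
    if fit._fitter is None or fit._data is None:
        raise ValueError("CoxFit must come from fit_coxph to run diagnostics")
    cph, data = fit._fitter, fit._data
    dur, ev = cph.duration_col, cph.event_col
    sch = cph.compute_residuals(data, kind="schoenfeld")
    event_times = data.loc[sch.index, dur].to_numpy(dtype=float)
    order = np.argsort(event_times, kind="stable")
    S = sch.to_numpy(dtype=float)[order]
    t = event_times[order]
    d = len(t)
    if transform == "rank":
        g = sps.rankdata(t, method="average")
    elif transform == "identity":
        g = t.copy()
    elif transform == "km":
        kmf = KaplanMeierFitter().fit(
            data[dur].to_numpy(float), data[ev].to_numpy(bool))
        g = 1.0 - kmf.survival_function_at_times(t).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    gg = float(gc @ gc)
    V = cph.variance_matrix_.to_numpy(dtype=float)  # Var(beta_hat)
    u = S.T @ gc
    rows = {}
    vu = V @ u
    for j, name in enumerate(sch.columns):
        chi2 = d * vu[j] ** 2 / (V[j, j] * gg)
        rows[name] = {"chi2": chi2, "df": 1, "p": sps.chi2.sf(chi2, 1)}
    gstat = d * float(u @ vu) / gg
    p = len(sch.columns)
    rows["GLOBAL"] = {"chi2": gstat, "df": p, "p": sps.chi2.sf(gstat, p)}
    return pd.DataFrame(rows).T


# ------------------------------------------------------------------------ RMST

def _km_rmst(durations: np.ndarray, events: np.ndarray, tau: float) -> float:
    """Area under the Kaplan–Meier curve up to tau (fast path for jackknife)."""
    order = np.lexsort((1 - events.astype(int), durations))  # events first in ties
    t = durations[order]
    e = events[order]
    n = len(t)
    at_risk = n - np.arange(n)
    surv = np.cumprod(1.0 - e / at_risk)
    # step function: S = 1 on [0, t_1), surv[i] on [t_i, t_{i+1})
    knots = np.concatenate(([0.0], t))
    s_vals = np.concatenate(([1.0], surv))
    knots_c = np.minimum(knots, tau)
    widths = np.diff(np.append(knots_c, tau))
    return float(np.sum(s_vals * widths))


def rmst(
    durations: Sequence[float],
    events: Sequence[bool],
    tau: float,
    alpha: float = 0.05,
    label: str = "",
) -> dict:
    """Restricted mean survival time to horizon ``tau`` with 95% CI."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if tau > durations.max():
        raise ValueError(
            f"tau={tau} exceeds the longest observed time"
            + (f" in group {label!r}" if label else "")
        )
    kmf = KaplanMeierFitter().fit(durations, events)
    with warnings.catch_warnings():
        # lifelines integrates the variance numerically; quadrature chatter
        # on long step functions is harmless here
        warnings.simplefilter("ignore")
        point, var = restricted_mean_survival_time(kmf, t=tau,
                                                   return_variance=True)
    z = sps.norm.ppf(1 - alpha / 2)
    se = float(np.sqrt(var))
    return {"rmst": float(point), "se": se,
            "ci": (float(point - z * se), float(point + z * se)),
            "tau": tau, "label": label}


def rmst_difference(
    durations: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
    tau: float,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Between-group RMST difference at ``tau``; adjusted when covariates given.

    Two groups are required; the difference is group[max label] minus
    group[min label] in sorted label order (for a "High"/"Low" factor this
    is Low minus High alphabetically, so pass an ordered categorical or
    relabel if the other direction is wanted). Unadjusted difference uses
    independent Greenwood variances; covariate adjustment regresses
    jackknife pseudo-values on group plus covariates with robust (HC1)
    standard errors, reporting the group coefficient.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = sorted(np.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError("rmst_difference requires exactly two groups")
    per = {
        lab: rmst(durations[groups == lab], events[groups == lab], tau,
                  alpha, label=str(lab))
        for lab in labels
    }
    a, b = labels  # difference = b - a
    diff = per[b]["rmst"] - per[a]["rmst"]
    se = float(np.hypot(per[a]["se"], per[b]["se"]))
    z = sps.norm.ppf(1 - alpha / 2)
    out = {
        "per_group": per,
        "difference": diff,
        "difference_ci": (diff - z * se, diff + z * se),
        "comparison": f"{b} - {a}",
    }
    if covariates is not None:
        pseudo = rmst_pseudovalues(durations, events, tau)
        Xd = pd.DataFrame({"group": (groups == b).astype(float)})
        cov = covariates.reset_index(drop=True)
        cat = [c for c in cov.columns if cov[c].dtype == object]
        if cat:
            cov = pd.get_dummies(cov, columns=cat, drop_first=True, dtype=float)
        Xd = pd.concat([Xd, cov], axis=1)
        ols = sm.OLS(pseudo, sm.add_constant(Xd)).fit(cov_type="HC1")
        ci = ols.conf_int(alpha).loc["group"]
        out["adjusted_difference"] = float(ols.params["group"])
        out["adjusted_ci"] = (float(ci[0]), float(ci[1]))
        out["adjusted_p"] = float(ols.pvalues["group"])
    return out


def rmst_pseudovalues(
    durations: np.ndarray, events: np.ndarray, tau: float
) -> np.ndarray:
    """Leave-one-out jackknife pseudo-values of the RMST at ``tau``."""
    n = len(durations)
    full = _km_rmst(durations, events, tau)
    mask = np.ones(n, dtype=bool)
    out = np.empty(n)
    for i in range(n):
        mask[i] = False
        out[i] = n * full - (n - 1) * _km_rmst(durations[mask], events[mask], tau)
        mask[i] = True
    return out


# ----------------------------------------------------- interaction and power

def lrt_interaction(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    full_covariates: Sequence[str],
    reduced_covariates: Sequence[str],
) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested Cox models.

    Typically the full model adds biomarker-by-treatment interaction terms
    to the reduced model (two rows per patient: prior-therapy line and
    checkpoint-inhibitor line). Returns (chi-square, df, p).
    """
    if not set(reduced_covariates) <= set(full_covariates):
        raise ValueError("models are not nested")
    fits = {}
    for name, covs in (("full", full_covariates), ("reduced", reduced_covariates)):
        cph = CoxPHFitter()
        cph.fit(df[[duration_col, event_col] + list(covs)],
                duration_col=duration_col, event_col=event_col)
        fits[name] = cph
    stat = 2.0 * (fits["full"].log_likelihood_ - fits["reduced"].log_likelihood_)
    stat = max(stat, 0.0)
    dof = len(full_covariates) - len(reduced_covariates)
    if dof == 0:
        return 0.0, 0, 1.0
    return float(stat), dof, float(sps.chi2.sf(stat, dof))


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-group survival comparison for the Schoenfeld formula."""

    hazard_ratio: float
    event_rate: float
    allocation: float = 0.5
    alpha: float = 0.05
    n: int | None = None
    power: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha in (0,1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio > 0")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation in (0,1)")
        if not 0 < self.event_rate <= 1:
            raise ValueError("event_rate in (0,1]")


def power_cox(spec: PowerSpec) -> float:
    """Power (given n) or required n (given power) by the Schoenfeld formula.

    Required events d = (z_{1-a/2} + z_{1-b})^2 / (p(1-p) ln^2 HR); total
    sample size n = d / event_rate. With ``spec.n`` set, returns achieved
    power; with ``spec.power`` set, returns required n.
    """
    p, hr = spec.allocation, spec.hazard_ratio
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    if hr == 1.0:
        warnings.warn("HR = 1: power degenerates to the type-I error rate",
                      stacklevel=2)
        if spec.n is not None:
            return spec.alpha
        raise ValueError("cannot size a study for HR = 1")
    if (spec.n is None) == (spec.power is None):
        raise ValueError("exactly one of n and power must be given")
    if spec.n is not None:
        d = spec.n * spec.event_rate
        return float(sps.norm.cdf(
            np.sqrt(d * p * (1 - p)) * abs(np.log(hr)) - z_a
        ))
    z_b = sps.norm.ppf(spec.power)
    d = (z_a + z_b) ** 2 / (p * (1 - p) * np.log(hr) ** 2)
    return float(d / spec.event_rate)


# ------------------------------------------------------------------ utilities

def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone, never smaller than the input)."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]
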