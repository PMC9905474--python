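"""Nearest-neighbor propensity-score matching with a caliper.

Used to compare first-line checkpoint-inhibitor monotherapy vs combination
therapy when the treatment decision is confounded: a logistic model of
treatment on confounders yields the propensity score; treated subjects are
greedily matched 1:1 without replacement to the nearest control on the
logit-propensity scale, subject to a caliper of 0.25 standard deviations
(of the logit scores, the Rosenbaum–Rubin convention; the raw-probability
scale is available by flag). Treated subjects with no control inside the
caliper are dropped — and reported. Post-match covariate balance is
verified with two-tailed t-tests (continuous) and Fisher's exact test
(categorical), flagged at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class SeparationError(RuntimeError):
    """The propensity model separates treatment perfectly."""


class MatchingError(RuntimeError):
    """No valid matched pairs could be formed."""


@dataclass(frozen=True)
class MatchResult:
    """Matched pair set with caliper bookkeeping and balance report."""

    pairs: tuple[tuple[str, str, float], ...]  # (treated_id, control_id, distance)
    dropped_treated: tuple[str, ...]
    propensity: Mapping[str, float]
    caliper_width: float
    scale: str  # "logit" | "probability"
    balance: Mapping[str, tuple[str, float]] | None = None

    @property
    def matched_ids(self) -> list[str]:
        out: list[str] = []
        for t, c, _ in self.pairs:
            out.extend((t, c))
        return out


def fit_propensity(
    cohort: pd.DataFrame,
    treatment_col: str,
    covariates: Sequence[str],
    id_col: str = "patient_id",
) -> pd.Series:
    """Logistic propensity model; returns fitted P(treated) indexed by id.

    Categorical covariates are dummy-coded; constant covariates are dropped
    with a warning. Perfect separation raises.
    """
    y = cohort[treatment_col].astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError(f"{treatment_col!r} must be binary 0/1")
    X = cohort[list(covariates)].copy()
    cat = [c for c in X.columns if X[c].dtype == object
           or str(X[c].dtype) == "category"]
    if cat:
        X = pd.get_dummies(X, columns=cat, drop_first=True, dtype=float)
    X = X.astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn("dropping constant covariate(s): " + ", ".join(const),
                      stacklevel=2)
        X = X.drop(columns=const)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy())).fit(disp=0)
    except Exception as exc:
        raise SeparationError(f"propensity model failed: {exc}") from exc
    scores = pd.Series(res.predict(), index=cohort[id_col].astype(str))
    if scores.min() <= 0 or scores.max() >= 1:
        raise SeparationError("fitted propensities at the 0/1 boundary")
    return scores


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def nn_match(
    scores: pd.Series,
    treatment: pd.Series,
    caliper_sd: float = 0.25,
    seed: int = 0,
    scale: str = "logit",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    ``scores`` and ``treatment`` (0/1) are aligned by id index. Treated
    subjects are processed in descending propensity order (ties shuffled by
    ``seed``); each takes the nearest available control within
    ``caliper_sd`` standard deviations of the (logit) score, computed over
    all subjects. Unmatched treated subjects are dropped and listed.
    """
    scores = scores.astype(float)
    treatment = treatment.reindex(scores.index).astype(int)
    work = _logit(scores.to_numpy()) if scale == "logit" else scores.to_numpy()
    if scale not in {"logit", "probability"}:
        raise ValueError(f"unknown scale {scale!r}")
    caliper = caliper_sd * float(np.std(work, ddof=1))
    ids = scores.index.to_numpy()
    tmask = treatment.to_numpy() == 1
    if not tmask.any() or tmask.all():
        raise MatchingError("both arms must be non-empty")

    rng = np.random.default_rng(seed)
    t_idx = np.flatnonzero(tmask)
    t_idx = t_idx[rng.permutation(len(t_idx))]
    t_idx = t_idx[np.argsort(-work[t_idx], kind="stable")]

    control = {i: work[i] for i in np.flatnonzero(~tmask)}
    pairs: list[tuple[str, str, float]] = []
    dropped: list[str] = []
    for ti in t_idx:
        if not control:
            dropped.append(str(ids[ti]))
            continue
        cix = np.fromiter(control.keys(), dtype=int)
        dist = np.abs(np.fromiter(control.values(), dtype=float) - work[ti])
        j = int(np.argmin(dist))
        if dist[j] <= caliper:
            pairs.append((str(ids[ti]), str(ids[cix[j]]), float(dist[j])))
            del control[int(cix[j])]
        else:
            dropped.append(str(ids[ti]))
    if not pairs:
        raise MatchingError("no treated subject matched within the caliper")
    return MatchResult(
        pairs=tuple(pairs),
        dropped_treated=tuple(dropped),
        propensity={str(i): float(s) for i, s in scores.items()},
        caliper_width=float(caliper),
        scale=scale,
    )


def balance_table(
    cohort: pd.DataFrame,
    result: MatchResult,
    covariates: Sequence[str],
    treatment_col: str,
    id_col: str = "patient_id",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Post-match balance: t-test (continuous) / Fisher exact (categorical).

    Returns a frame indexed by covariate with ``test``, ``p`` and a
    ``flagged`` boolean (p < alpha). Categorical covariates with more than
    two levels fall back to the chi-square test (noted in ``test``).
    """
    matched = cohort[cohort[id_col].astype(str).isin(result.matched_ids)]
    arm = matched[treatment_col].astype(int)
    rows = {}
    for cov in covariates:
        col = matched[cov]
        if col.dtype == object or str(col.dtype) == "category" or col.nunique() <= 2:
            tab = pd.crosstab(col, arm)
            if tab.shape[0] == 1:
                test, p = "fisher_exact", 1.0
            elif tab.shape == (2, 2):
                test, p = "fisher_exact", float(sps.fisher_exact(tab.to_numpy())[1])
            else:
                test, p = "chi2", float(sps.chi2_contingency(tab.to_numpy())[1])
        else:
            a = col[arm == 1].astype(float)
            b = col[arm == 0].astype(float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                test, p = "t_test", 1.0
            else:
                test, p = "t_test", float(sps.ttest_ind(a, b).pvalue)
        rows[cov] = {"test": test, "p": p, "flagged": p < alpha}
    return pd.DataFrame(rows).T


def standardized_mean_differences(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    treatment_col: str,
) -> pd.Series:
    """Absolute standardized mean differences between arms (pooled SD)."""
    arm = cohort[treatment_col].astype(int)
    out = {}
    for cov in covariates:
        col = cohort[cov]
        if col.dtype == object or str(col.dtype) == "category":
            col = (col == col.mode().iloc[0]).astype(float)
        col = col.astype(float)
        a, b = col[arm == 1], col[arm == 0]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        out[cov] = 0.0 if pooled == 0 else abs(a.mean() - b.mean()) / pooled
    return pd.Series(out)
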