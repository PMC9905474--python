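"""The Immunotherapy Response Score: locked scoring and re-derivation.

The locked model is a linear score over five transformed biomarkers,

    IRS = 0.273758*TMB + 0.112641*PD-1 + 0.061904*PD-L1
          - 0.077011*TOP2A - 0.057991*ADAM12

with TMB entering as log2(Muts/Mb) and each gene as centered log2 nRPM
(:mod:`irskit.biomarkers`). Patients at or above the locked threshold
0.873569 are IRS-High (predicted checkpoint-inhibitor benefit); below it,
IRS-Low. Because higher IRS means *longer* survival, the score is the
negative of a Cox model's log-hazard linear predictor; this module keeps
both conventions explicit.

Re-derivation follows the original procedure: Lasso-penalized Cox
proportional-hazards regression over candidate features, the penalty chosen
to maximize the 5-fold cross-validated concordance index, then an
unpenalized Cox refit on the features with non-zero penalized coefficients.
Features are standardized internally for the penalized fit and coefficients
reported back on the transformed-feature scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .io import ModelSpec

logger = logging.getLogger("irskit")


class ScoringError(ValueError):
    """A profile is missing features required by the model."""


class FittingError(RuntimeError):
    """Model re-derivation could not proceed (e.g. no events)."""


@dataclass(frozen=True)
class IRSResult:
    """Score and dichotomized group for one patient."""

    patient_id: str
    score: float
    group: str  # "High" | "Low"
    feature_values: Mapping[str, float]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a cross-validated Lasso-Cox re-derivation."""

    selected_features: tuple[str, ...]
    penalized_coefficients: Mapping[str, float]  # hazard scale, unstandardized
    refit_coefficients: Mapping[str, float]      # hazard scale, unpenalized
    score_coefficients: Mapping[str, float]      # -refit: higher = better
    refit_standard_errors: Mapping[str, float]
    lambda_path: tuple[tuple[float, float], ...]  # (penalty, mean CV concordance)
    chosen_penalty: float
    cv_seed: int


def compute_irs(
    profile: Mapping[str, float], spec: ModelSpec, patient_id: str = ""
) -> IRSResult:
    """Evaluate the locked equation on one patient's transformed features.

    ``profile`` maps the five feature names (log2 TMB and centered log2
    expression) to values; a group of "High" requires score >= threshold.
    """
    missing = [f for f in spec.coefficients if f not in profile]
    if missing:
        raise ScoringError("missing feature(s): " + ", ".join(missing))
    score = float(sum(spec.coefficients[f] * profile[f] for f in spec.coefficients))
    group = "High" if score >= spec.threshold else "Low"
    used = {f: float(profile[f]) for f in spec.coefficients}
    return IRSResult(patient_id=patient_id, score=score, group=group,
                     feature_values=used)


def score_cohort(features: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Vectorized locked-model scoring of a transformed-feature table.

    Returns ``patient_id``, ``irs_score`` and ``irs_group`` ("High"/"Low").
    """
    missing = [f for f in spec.coefficients if f not in features.columns]
    if missing:
        raise ScoringError("missing feature column(s): " + ", ".join(missing))
    score = sum(
        spec.coefficients[f] * features[f].astype(float)
        for f in spec.coefficients
    )
    return pd.DataFrame(
        {
            "patient_id": features["patient_id"].astype(str)
            if "patient_id" in features
            else np.arange(len(features)).astype(str),
            "irs_score": score,
            "irs_group": np.where(score >= spec.threshold, "High", "Low"),
        }
    )


def fit_lasso_cox(
    durations: Sequence[float],
    events: Sequence[bool],
    features: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
) -> FitResult:
    """Cross-validated Lasso-Cox feature selection with unpenalized refit.

    The penalty path runs from the smallest penalty that zeroes every
    coefficient down to ``alpha_min_ratio`` of it (log-spaced). Folds are
    stratified by event status; the penalty maximizing mean cross-validated
    concordance wins, ties broken toward the sparser (larger-penalty) model.
    Features are standardized internally; reported coefficients are on the
    input feature scale.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    n_events = int(events.sum())
    if n_events == 0:
        raise FittingError("no events: cannot fit a Cox model")
    if n_events < 2 * n_folds:
        raise FittingError(
            f"only {n_events} events for {n_folds}-fold CV (need >= 2 per fold)"
        )
    X = features.astype(float).copy()
    if not np.isfinite(X.to_numpy()).all():
        raise FittingError("non-finite feature values")
    sd = X.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(
            "dropping constant feature(s): " + ", ".join(map(str, constant)),
            stacklevel=2,
        )
        X = X.drop(columns=constant)
        sd = sd.drop(index=constant)
    mean = X.mean()
    Xs = (X - mean) / sd
    cols = list(X.columns)
    y = Surv.from_arrays(event=events, time=durations)

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    path_model.fit(Xs.to_numpy(), y)
    alphas = np.asarray(path_model.alphas_)

    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_scores = np.full((n_folds, len(alphas)), np.nan)
    for k, (tr, te) in enumerate(folds.split(Xs, events.astype(int))):
        est = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, fit_baseline_model=False,
        )
        est.fit(Xs.iloc[tr].to_numpy(), y[tr])
        fitted = np.asarray(est.alphas_)
        for j, a in enumerate(alphas):
            if not np.any(np.isclose(fitted, a)):
                continue
            risk = est.predict(Xs.iloc[te].to_numpy(), alpha=a)
            if np.ptp(risk) == 0:
                cv_scores[k, j] = 0.5
            else:
                cv_scores[k, j] = concordance_index_censored(
                    events[te], durations[te], risk
                )[0]
    mean_cv = np.nanmean(cv_scores, axis=0)
    # ties toward the sparser model: alphas_ is decreasing, so take the
    # first (largest-penalty) argmax
    best = int(np.argmax(np.round(mean_cv, 12)))
    chosen = float(alphas[best])

    coef_std = path_model.coef_[:, best]
    penalized = {c: float(b / sd[c]) for c, b in zip(cols, coef_std)}
    selected = tuple(c for c, b in zip(cols, coef_std) if b != 0)
    if not selected:
        raise FittingError("penalty path selected the empty model")

    refit_df = X[list(selected)].copy()
    refit_df["duration"] = durations
    refit_df["event"] = events.astype(int)
    cph = CoxPHFitter()
    cph.fit(refit_df, duration_col="duration", event_col="event")
    refit = {c: float(cph.params_[c]) for c in selected}
    ses = {c: float(cph.standard_errors_[c]) for c in selected}
    logger.debug("lasso-cox: selected %s at penalty %.5g", selected, chosen)
    return FitResult(
        selected_features=selected,
        penalized_coefficients=penalized,
        refit_coefficients=refit,
        score_coefficients={c: -v for c, v in refit.items()},
        refit_standard_errors=ses,
        lambda_path=tuple((float(a), float(s)) for a, s in zip(alphas, mean_cv)),
        chosen_penalty=chosen,
        cv_seed=seed,
    )


class ThresholdError(ValueError):
    """No valid dichotomization cut exists for the given scores."""


def select_threshold(
    scores: Sequence[float],
    durations: Sequence[float],
    events: Sequence[bool],
    hr_target: float,
    min_group: int = 10,
) -> tuple[float | None, pd.DataFrame]:
    """Scan score percentiles for a High/Low dichotomization threshold.

    Candidate thresholds are the 1..99 score percentiles. For each, the
    unadjusted hazard ratio of High (score >= cut) vs Low is fitted; cuts
    leaving fewer than ``min_group`` patients on either side are skipped.
    Returns the full (threshold, HR, High fraction) curve and the threshold
    with the **largest High fraction** among those with HR <= ``hr_target``
    (None if no cut qualifies).
    """
    scores = np.asarray(scores, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    grid = np.unique(np.percentile(scores, np.arange(1, 100)))
    rows = []
    for cut in grid:
        high = scores >= cut
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        df = pd.DataFrame(
            {"duration": durations, "event": events.astype(int),
             "high": high.astype(int)}
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                # degenerate cuts (separation, monotone likelihood) are skipped
                warnings.simplefilter("error")
                cph.fit(df, duration_col="duration", event_col="event")
        except Exception:
            continue
        rows.append(
            {"threshold": float(cut),
             "hazard_ratio": float(np.exp(cph.params_["high"])),
             "high_fraction": float(high.mean())}
        )
    if not rows:
        raise ThresholdError(
            "no candidate threshold leaves both groups adequately populated"
        )
    curve = pd.DataFrame(rows)
    ok = curve[curve["hazard_ratio"] <= hr_target]
    if ok.empty:
        return None, curve
    best = ok.sort_values(["high_fraction", "threshold"],
                          ascending=[False, True]).iloc[0]
    return float(best["threshold"]), curve
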