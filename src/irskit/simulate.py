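"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real patient-level data behind checkpoint-inhibitor response scoring are
held under data-sharing agreements, so every pipeline stage here is
exercised on generated cohorts that emulate the published structure:

* **Biomarkers** — a Gaussian copula with log-normal marginals. Rank
  (Spearman) correlation targets are taken from the published pan-cohort
  correlation table (e.g. 0.571 for PD-1 vs PD-L1, 0.211 for TMB vs TOP2A)
  and converted to copula (Pearson) parameters by
  ``rho_P = 2 sin(pi rho_S / 6)``, which is exact for the Gaussian copula.
* **Outcomes** — Weibull proportional-hazards event times whose log-hazard
  is minus the centered true score (higher score, longer survival), plus
  staggered administrative censoring and independent exponential dropout.
* **Treatment histories** — per-dose medication records drawn from scripted
  archetypes (monotherapy, overlapping combination, gapped re-treatment,
  adjuvant-then-advanced) with the ground-truth line structure attached in
  ``truth_*`` columns that the pipeline ignores.

Defaults are calibrated to the published discovery-cohort anchors: a TMB
marginal with roughly a third of patients at >= 10 Muts/Mb, a High-score
fraction near 46%, an event rate near one half, and a median time-to-event
around a year. ``SimConfig.with_high_fraction`` re-solves the TMB location
so a target High fraction is hit under a normal approximation to the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .biomarkers import transform_features
from .io import ModelSpec, default_model_spec
from .model import score_cohort

BIOMARKER_ORDER = ("TMB", "PD-1", "PD-L1", "TOP2A", "ADAM12")

#: Published pan-cohort Spearman rank correlations; pairs the table does not
#: print are set to plausible values inside the printed range.
DEFAULT_SPEARMAN = {
    ("TMB", "PD-1"): 0.12,
    ("TMB", "PD-L1"): 0.15,
    ("TMB", "TOP2A"): 0.211,
    ("TMB", "ADAM12"): 0.032,
    ("PD-1", "PD-L1"): 0.571,
    ("PD-1", "TOP2A"): 0.033,
    ("PD-1", "ADAM12"): 0.15,
    ("PD-L1", "TOP2A"): 0.10,
    ("PD-L1", "ADAM12"): 0.20,
    ("TOP2A", "ADAM12"): 0.25,
}

ARCHETYPES = ("monotherapy", "combination", "gapped_retreat",
              "adjuvant_then_advanced")


class ConfigError(ValueError):
    """Simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the package's study conditions."""

    n_patients: int = 2000
    seed: int = 0
    # log-normal marginals: (median, sigma of log)
    tmb_marginal: tuple[float, float] = (6.5, 1.15)
    gene_marginals: dict = field(default_factory=lambda: {
        "PD-1": (40.5, 1.0),
        "PD-L1": (81.0, 1.0),
        "TOP2A": (200.0, 1.0),
        "ADAM12": (100.0, 1.0),
    })
    spearman: dict = field(default_factory=lambda: dict(DEFAULT_SPEARMAN))
    # outcome model
    weibull_shape: float = 1.2
    weibull_scale_months: float = 18.0
    lp_center: float | None = None  # None: analytic mean score under defaults
    extra_covariate_effects: dict = field(default_factory=dict)
    # censoring
    admin_horizon_months: tuple[float, float] = (3.0, 30.0)
    dropout_rate_per_month: float = 0.01
    # treatment histories
    dose_interval_days: int = 21
    archetype_weights: dict = field(default_factory=lambda: {
        "monotherapy": 0.4, "combination": 0.3,
        "gapped_retreat": 0.15, "adjuvant_then_advanced": 0.15,
    })

    def spearman_matrix(self) -> np.ndarray:
        k = len(BIOMARKER_ORDER)
        m = np.eye(k)
        for (a, b), rho in self.spearman.items():
            i, j = BIOMARKER_ORDER.index(a), BIOMARKER_ORDER.index(b)
            m[i, j] = m[j, i] = rho
        return m

    def pearson_matrix(self) -> np.ndarray:
        """Copula correlation: rho_P = 2 sin(pi rho_S / 6); must be PSD."""
        m = 2.0 * np.sin(np.pi * self.spearman_matrix() / 6.0)
        np.fill_diagonal(m, 1.0)
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ConfigError("correlation matrix is not positive semidefinite")
        return m

    def with_high_fraction(
        self, target: float, spec: ModelSpec | None = None
    ) -> "SimConfig":
        """Re-solve the TMB median so P(score >= threshold) ~= target."""
        spec = spec or default_model_spec()
        sigma = self.tmb_marginal[1]

        def frac(log2_median: float) -> float:
            cfg = replace(self, tmb_marginal=(2.0 ** log2_median, sigma))
            mu, sd = irs_normal_approx(cfg, spec)
            return float(sps.norm.sf(spec.threshold, mu, sd)) - target

        sol = optimize.brentq(frac, -2.0, 7.0)
        return replace(self, tmb_marginal=(2.0 ** sol, sigma))


def _feature_moments(
    median: float, sigma: float, kind: str, spec: ModelSpec, ref_median: float = 0.0
) -> tuple[float, float]:
    """Mean and SD of a transformed feature by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)
    x = np.exp(np.log(median) + sigma * z)
    if kind == "tmb":
        f = np.log2(np.maximum(x, spec.tmb_floor))
    else:
        f = np.log2(x + 1.0) - np.log2(ref_median + 1.0)
    mean = float(w @ f)
    var = float(w @ (f - mean) ** 2)
    return mean, np.sqrt(var)


def irs_normal_approx(config: SimConfig, spec: ModelSpec) -> tuple[float, float]:
    """Approximate mean and SD of the true score under a config.

    Marginal moments of each transformed feature are exact (quadrature);
    cross-covariances use the copula correlation as a linear approximation,
    which is accurate because each transform is nearly affine in the latent
    Gaussian over the bulk of its range.
    """
    moments = {"TMB": _feature_moments(*config.tmb_marginal, "tmb", spec)}
    for g, (med, sig) in config.gene_marginals.items():
        moments[g] = _feature_moments(med, sig, "gene", spec,
                                      ref_median=spec.gene_medians[g])
    coefs = np.array([spec.coefficients[b] for b in BIOMARKER_ORDER])
    means = np.array([moments[b][0] for b in BIOMARKER_ORDER])
    sds = np.array([moments[b][1] for b in BIOMARKER_ORDER])
    cov = config.pearson_matrix() * np.outer(sds, sds)
    mean = float(coefs @ means)
    sd = float(np.sqrt(coefs @ cov @ coefs))
    return mean, sd


# ------------------------------------------------------------------ biomarkers

def gen_biomarkers(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a biomarker table from the Gaussian copula.

    Columns: ``patient_id``, ``tmb`` (Muts/Mb) and one nRPM column per
    model gene. Marginals are log-normal; rank correlations match the
    configured Spearman targets up to Monte-Carlo error.
    """
    corr = config.pearson_matrix()
    z = rng.multivariate_normal(np.zeros(len(BIOMARKER_ORDER)), corr,
                                size=config.n_patients,
                                method="cholesky")
    cols = {}
    for j, name in enumerate(BIOMARKER_ORDER):
        med, sig = (config.tmb_marginal if name == "TMB"
                    else config.gene_marginals[name])
        cols["tmb" if name == "TMB" else name] = np.exp(np.log(med) + sig * z[:, j])
    df = pd.DataFrame(cols)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(config.n_patients)])
    return df


# -------------------------------------------------------------------- outcomes

def gen_outcomes(
    biomarkers: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    spec: ModelSpec | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Weibull proportional-hazards outcomes driven by the true score.

    The log relative hazard is ``-(score - center)`` so that higher scores
    mean longer survival; ``center`` defaults to the analytic mean score so
    the baseline scale is interpretable. Censoring combines a staggered
    administrative horizon with exponential dropout. The returned frame
    carries ``duration_months``, ``event`` and the ground truth
    (``truth_lp``, ``truth_event_time``) for oracle tests.
    """
    spec = spec or default_model_spec()
    feats = transform_features(biomarkers, spec)
    scored = score_cohort(feats, spec)
    center = (config.lp_center if config.lp_center is not None
              else irs_normal_approx(config, spec)[0])
    lp = -(scored["irs_score"].to_numpy() - center)
    if covariates is not None:
        for colname, beta in config.extra_covariate_effects.items():
            lp = lp + beta * covariates[colname].to_numpy(dtype=float)
    n = len(lp)
    u = rng.exponential(1.0, size=n)
    t_event = config.weibull_scale_months * (
        u / np.exp(lp)
    ) ** (1.0 / config.weibull_shape)
    lo, hi = config.admin_horizon_months
    admin = rng.uniform(lo, hi, size=n)
    if config.dropout_rate_per_month > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate_per_month, size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(admin, dropout)
    return pd.DataFrame({
        "patient_id": biomarkers["patient_id"].astype(str),
        "duration_months": np.minimum(t_event, censor),
        "event": t_event <= censor,
        "irs_score": scored["irs_score"],
        "irs_group": scored["irs_group"],
        "truth_lp": lp,
        "truth_event_time": t_event,
    })


# ---------------------------------------------------------- treatment history

def _doses(agent, cls, start_day, n, interval, index, pid, rows):
    for k in range(n):
        d = index + timedelta(days=start_day + k * interval)
        rows.append({"patient_id": pid, "agent": agent, "class": cls,
                     "start_date": d, "end_date": d})


def gen_treatment_history(
    config: SimConfig,
    rng: np.random.Generator,
    patient_ids: list[str] | None = None,
    index_dates: list[date] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dose medication records from scripted archetypes.

    Returns (medications, truth): medications in the cohort table schema;
    truth one row per patient with the archetype and its known line
    structure (``truth_n_lines``, ``truth_n_systemic_lines``,
    ``truth_first_line_combination``, ``truth_has_adjuvant``).
    """
    if patient_ids is None:
        patient_ids = [f"P{i:05d}" for i in range(config.n_patients)]
    if index_dates is None:
        index_dates = [date(2019, 1, 1)] * len(patient_ids)
    names = list(config.archetype_weights)
    probs = np.array([config.archetype_weights[a] for a in names], dtype=float)
    probs /= probs.sum()
    iv = config.dose_interval_days
    rows: list[dict] = []
    truth: list[dict] = []
    for pid, index in zip(patient_ids, index_dates):
        arch = names[rng.choice(len(names), p=probs)]
        n_doses = int(rng.integers(4, 11))
        if arch == "monotherapy":
            _doses("pembrolizumab", "PD-1", 0, n_doses, iv, index, pid, rows)
            t = dict(n_lines=1, n_systemic=1, combo=False, adjuvant=False)
        elif arch == "combination":
            _doses("pembrolizumab", "PD-1", 0, n_doses, iv, index, pid, rows)
            _doses("carboplatin", "chemotherapy", 0, min(n_doses, 4), iv,
                   index, pid, rows)
            t = dict(n_lines=1, n_systemic=1, combo=True, adjuvant=False)
        elif arch == "gapped_retreat":
            _doses("pembrolizumab", "PD-1", 0, 3, iv, index, pid, rows)
            gap = int(rng.integers(100, 200))  # > merge window
            _doses("pembrolizumab", "PD-1", 2 * iv + gap, 3, iv, index, pid, rows)
            t = dict(n_lines=2, n_systemic=2, combo=False, adjuvant=False)
        else:  # adjuvant_then_advanced
            _doses("carboplatin", "chemotherapy", 0, 2, iv, index, pid, rows)
            restart = iv + int(rng.integers(190, 260))  # >= adjuvant gap
            _doses("pembrolizumab", "PD-1", restart, n_doses, iv, index, pid, rows)
            t = dict(n_lines=2, n_systemic=1, combo=False, adjuvant=True)
        truth.append({
            "patient_id": pid, "truth_archetype": arch,
            "truth_n_lines": t["n_lines"],
            "truth_n_systemic_lines": t["n_systemic"],
            "truth_first_line_combination": t["combo"],
            "truth_has_adjuvant": t["adjuvant"],
        })
    med = pd.DataFrame(rows)
    med[["start_date", "end_date"]] = med[["start_date", "end_date"]].apply(
        pd.to_datetime)
    return med, pd.DataFrame(truth)


# ------------------------------------------------------------------ full cohort

def gen_cohort(
    config: SimConfig,
    spec: ModelSpec | None = None,
    tumor_types: tuple[str, ...] = ("NSCLC", "melanoma", "bladder", "breast",
                                    "colorectal", "other"),
    tumor_probs: tuple[float, ...] = (0.40, 0.12, 0.08, 0.10, 0.10, 0.20),
) -> dict[str, pd.DataFrame]:
    """Generate a self-consistent cohort file set (patients, medications,
    biomarkers) runnable end-to-end through the pipeline.

    An index (line-start) date is drawn per patient; checkpoint-inhibitor
    doses run from it until progression or censoring; a progression event
    manifests as either a subsequent therapy line (a new agent starting at
    the event time) or death. Ground-truth score columns are embedded in the
    patients table under ``truth_`` names the pipeline ignores.
    """
    spec = spec or default_model_spec()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    bio = gen_biomarkers(config, rng)
    out = gen_outcomes(bio, config, rng, spec)

    index = [date(2019, 1, 1) + timedelta(days=int(d))
             for d in rng.integers(0, 365, size=n)]
    age = np.clip(rng.normal(65, 10, size=n), 20, 92).round(1)
    gender = np.where(rng.random(n) < 0.45, "F", "M")
    ttype = rng.choice(tumor_types, size=n, p=tumor_probs)

    iv = config.dose_interval_days
    med_rows: list[dict] = []
    death_dates: list[date | None] = []
    last_records: list[date] = []
    for i in range(n):
        pid = bio.at[i, "patient_id"]
        dur_days = max(int(round(out.at[i, "duration_months"] * 30.4375)), 1)
        event = bool(out.at[i, "event"])
        n_doses = max(dur_days // iv, 1)
        first_row = len(med_rows)
        _doses("pembrolizumab", "PD-1", 0, n_doses, iv, index[i], pid, med_rows)
        end_day = dur_days
        death: date | None = None
        if event:
            if rng.random() < 0.5:
                # progression -> next therapy line, later death for some
                n_next = int(rng.integers(2, 6))
                _doses("docetaxel", "chemotherapy", end_day, n_next, iv,
                       index[i], pid, med_rows)
                if rng.random() < 0.5:
                    death = index[i] + timedelta(
                        days=end_day + (n_next - 1) * iv + 1
                        + int(rng.exponential(8 * 30.4375)))
            else:
                death = index[i] + timedelta(days=end_day)
        pat_dates = [r["start_date"] for r in med_rows[first_row:]]
        last = index[i] + timedelta(days=end_day + int(rng.integers(0, 60)))
        last = max([last] + pat_dates)
        if death is not None:
            last = max(last, death)
        death_dates.append(death)
        last_records.append(last)

    patients = pd.DataFrame({
        "patient_id": bio["patient_id"],
        "age": age,
        "gender": gender,
        "tumor_type": ttype,
        "death_date": pd.to_datetime(death_dates),
        "last_record_date": pd.to_datetime(last_records),
        "truth_irs_score": out["irs_score"],
        "truth_irs_group": out["irs_group"],
        "truth_duration_months": out["duration_months"],
        "truth_event": out["event"],
    })
    med = pd.DataFrame(med_rows)
    med[["start_date", "end_date"]] = med[["start_date", "end_date"]].apply(
        pd.to_datetime)
    bio = bio.copy()
    bio.insert(1, "sample_collection_date", pd.to_datetime(
        [d - timedelta(days=int(g)) for d, g in
         zip(index, rng.integers(10, 60, size=n))]))
    return {"patients": patients, "medications": med, "biomarkers": bio}
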