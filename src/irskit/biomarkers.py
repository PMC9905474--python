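"""Biomarker normalization and transformation.

Expression from the targeted RNA panel is reported in **nRPM** (normalized
reads per million): per-sample reads-per-million rescaled by a factor that
makes the median housekeeping target match its reads-per-million in a
reference sample run alongside. Downstream, the scoring model consumes
log2-transformed TMB (mutations per megabase, floored to keep the log
finite) and log2-transformed, median-centered expression, with a +1
pseudocount so zero reads stay finite:

    expr_feature = log2(nRPM + 1) - log2(median_nRPM + 1)
    tmb_feature  = log2(max(TMB, floor))

Centering medians are frozen constants carried by the model spec, never
re-estimated per scored batch. TMB-High is the categorical call TMB >= 10
Muts/Mb (cutoff configurable).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import MODEL_GENES, ModelSpec


class NormalizationError(ValueError):
    """Housekeeping signal insufficient to scale the sample."""


class ConfigurationError(ValueError):
    """Required centering or reference constants are missing."""


def normalize_nrpm(
    raw_counts: Mapping[str, float],
    housekeeping_counts: Mapping[str, float],
    reference_rpm: Mapping[str, float],
) -> dict[str, float]:
    """Scale raw target counts to nRPM via housekeeping genes.

    Per-sample RPM is computed over all reads (targets + housekeeping); the
    scale factor is the median over housekeeping targets of
    ``reference_rpm / sample_rpm``, so multiplying every raw count by a
    constant leaves nRPM unchanged.
    """
    total = float(sum(raw_counts.values()) + sum(housekeeping_counts.values()))
    if total <= 0:
        raise NormalizationError("no reads in sample")
    hk_rpm = {g: c / total * 1e6 for g, c in housekeeping_counts.items()}
    ratios = [
        reference_rpm[g] / rpm
        for g, rpm in hk_rpm.items()
        if rpm > 0 and g in reference_rpm
    ]
    if not ratios:
        raise NormalizationError(
            "all housekeeping targets have zero reads (or no reference RPM)"
        )
    factor = float(np.median(ratios))
    return {g: c / total * 1e6 * factor for g, c in raw_counts.items()}


def center_log2(
    nrpm: Mapping[str, float], gene_medians: Mapping[str, float]
) -> dict[str, float]:
    """log2(nRPM + 1) minus log2(median + 1), per gene."""
    missing = [g for g in nrpm if g not in gene_medians]
    if missing:
        raise ConfigurationError(
            "no centering median for gene(s): " + ", ".join(sorted(missing))
        )
    return {
        g: float(np.log2(v + 1.0) - np.log2(gene_medians[g] + 1.0))
        for g, v in nrpm.items()
    }


def transform_tmb(tmb: float, floor: float = 0.5) -> float:
    """log2 of TMB floored at ``floor`` Muts/Mb (not median-centered)."""
    if tmb < 0:
        raise ValueError("TMB must be non-negative")
    return float(np.log2(max(tmb, floor)))


def call_tmb_high(tmb: float, cutoff: float = 10.0) -> bool:
    """Categorical TMB-High call: TMB >= cutoff Muts/Mb."""
    if tmb < 0:
        raise ValueError("TMB must be non-negative")
    return tmb >= cutoff


def transform_features(biomarkers: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Model-ready feature table from a biomarkers cohort table.

    Input columns: ``patient_id``, ``tmb`` and one nRPM column per model
    gene. Output columns: ``patient_id``, the transformed features named as
    in the locked equation (``TMB`` = log2 TMB; gene names = centered log2
    nRPM) and the boolean ``tmb_high`` call.
    """
    missing = [g for g in MODEL_GENES if g not in biomarkers.columns]
    if missing:
        raise ConfigurationError(
            "biomarkers table missing expression column(s): " + ", ".join(missing)
        )
    out = pd.DataFrame({"patient_id": biomarkers["patient_id"].astype(str)})
    tmb = biomarkers["tmb"].astype(float)
    if (tmb < 0).any():
        raise ValueError("TMB must be non-negative")
    out["TMB"] = np.log2(np.maximum(tmb, spec.tmb_floor))
    for gene in MODEL_GENES:
        med = spec.gene_medians.get(gene)
        if med is None:
            raise ConfigurationError(f"no centering median for gene {gene!r}")
        vals = biomarkers[gene].astype(float)
        if (vals < 0).any():
            raise ValueError(f"negative nRPM for gene {gene!r}")
        out[gene] = np.log2(vals + 1.0) - np.log2(med + 1.0)
    out["tmb_high"] = tmb >= spec.tmb_high_cutoff
    return out
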