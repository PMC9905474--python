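"""Cohort table I/O, model-specification loading, configuration and logging.

Three tabular schemas are understood, all plain CSV/TSV with ISO-8601 dates:

``patients``
    one row per patient: ``patient_id, age, gender, tumor_type, death_date,
    last_record_date`` (``death_date`` may be empty).
``medications``
    one row per dose or administration interval: ``patient_id, agent, class,
    start_date, end_date`` (``end_date`` may equal ``start_date``).
``biomarkers``
    one row per profiled sample: ``patient_id, sample_collection_date, tmb``
    plus one column per expression target (nRPM), housekeeping columns
    optional.

The locked scoring model (coefficients, dichotomization threshold, centering
medians, TMB handling constants) travels as a JSON document; a packaged
default carries the published constants.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger("irskit")

#: Transformed-feature names of the locked model, in equation order.
MODEL_FEATURES = ("TMB", "PD-1", "PD-L1", "TOP2A", "ADAM12")

#: Expression targets used by the locked model (everything except TMB).
MODEL_GENES = ("PD-1", "PD-L1", "TOP2A", "ADAM12")

_DATE_COLUMNS = {
    "patients": ["death_date", "last_record_date"],
    "medications": ["start_date", "end_date"],
    "biomarkers": ["sample_collection_date"],
}

_REQUIRED_COLUMNS = {
    "patients": ["patient_id", "age", "gender", "tumor_type",
                 "death_date", "last_record_date"],
    "medications": ["patient_id", "agent", "class", "start_date", "end_date"],
    "biomarkers": ["patient_id", "sample_collection_date", "tmb"],
}

#: Columns that may be empty for a given row.
_OPTIONAL_VALUE_COLUMNS = {"patients": {"death_date"}}


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates an invariant."""


class DateParseError(ValueError):
    """A date cell could not be parsed as an ISO-8601 calendar date."""


class ModelSpecError(ValueError):
    """A model-spec document is missing required keys or is inconsistent."""


def setup_logging(verbose: bool = False) -> None:
    """Route package log messages to standard error with timestamps."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _parse_dates(df: pd.DataFrame, schema: str, path: Path) -> pd.DataFrame:
    optional = _OPTIONAL_VALUE_COLUMNS.get(schema, set())
    for col in _DATE_COLUMNS[schema]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = parsed.isna() & ~blank
        if bad.any():
            row = int(bad.idxmax())
            raise DateParseError(
                f"{path}: column {col!r}, row {row}: "
                f"{raw[bad].iloc[0]!r} is not an ISO-8601 date (YYYY-MM-DD)"
            )
        if blank.any() and col not in optional:
            row = int(blank.idxmax())
            raise SchemaError(f"{path}: column {col!r} empty at row {row}")
        df[col] = parsed
    return df


def read_cohort(path: str | Path, schema: str) -> pd.DataFrame:
    """Read one cohort table, validating columns and parsing dates.

    Parameters
    ----------
    path
        CSV (comma) or TSV/TXT (tab) file.
    schema
        One of ``"patients"``, ``"medications"``, ``"biomarkers"``.

    Returns
    -------
    pandas.DataFrame
        Typed records in file order; date columns are ``datetime64``.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the error names it) or a
        per-table invariant fails (duplicate patient ids, dose after
        death, end before start).
    DateParseError
        If a date cell is malformed; the message carries the row index.
    """
    if schema not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={"patient_id": str})
    missing = [c for c in _REQUIRED_COLUMNS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: {schema} table missing column(s) "
            + ", ".join(repr(c) for c in missing)
        )
    df = _parse_dates(df, schema, path)
    if schema == "patients":
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if not dup.empty:
            raise SchemaError(f"{path}: duplicate patient_id {dup.iloc[0]!r}")
    if schema == "medications":
        bad = df["end_date"] < df["start_date"]
        if bad.any():
            raise SchemaError(
                f"{path}: end_date before start_date at row {int(bad.idxmax())}"
            )
    logger.debug("read %d %s rows from %s", len(df), schema, path)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a cohort table; absent values become empty cells."""
    path = Path(path)
    out = df.copy()
    for col in _DATE_COLUMNS.get(schema, []):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=_delimiter_for(path), index=False)


def validate_patient_medication_dates(
    patients: pd.DataFrame, medications: pd.DataFrame
) -> None:
    """Fail if any dose is recorded after the patient's death date."""
    merged = medications.merge(
        patients[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    bad = merged["death_date"].notna() & (merged["start_date"] > merged["death_date"])
    if bad.any():
        pid = merged.loc[bad.idxmax(), "patient_id"]
        raise SchemaError(f"post-mortem dose recorded for patient {pid!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Locked scoring model: coefficients, threshold and transform constants.

    ``gene_medians`` are the frozen nRPM centering constants (estimated once
    on a reference cohort, never re-estimated per scored batch);
    ``tmb_floor`` keeps log2(TMB) finite at zero mutations; ``tmb_high_cutoff``
    is the categorical TMB-High boundary in Muts/Mb.
    """

    coefficients: Mapping[str, float]
    threshold: float
    gene_medians: Mapping[str, float]
    tmb_floor: float = 0.5
    tmb_high_cutoff: float = 10.0
    reference_rpm: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in MODEL_FEATURES if f not in self.coefficients]
        if missing:
            raise ModelSpecError(
                "model spec missing coefficient(s): " + ", ".join(missing)
            )
        if not (self.tmb_floor > 0 and self.tmb_high_cutoff > 0):
            raise ModelSpecError("tmb_floor and tmb_high_cutoff must be > 0")
        import math

        if not math.isfinite(self.threshold):
            raise ModelSpecError("threshold must be finite")


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load a model specification from a JSON document."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        return ModelSpec(
            coefficients=doc["coefficients"],
            threshold=float(doc["threshold"]),
            gene_medians={k: float(v) for k, v in doc["gene_medians"].items()},
            tmb_floor=float(doc.get("tmb_floor", 0.5)),
            tmb_high_cutoff=float(doc.get("tmb_high_cutoff", 10.0)),
            reference_rpm=doc.get("reference_rpm", {}),
        )
    except KeyError as exc:
        raise ModelSpecError(f"model spec missing key {exc.args[0]!r}") from exc


def save_model_spec(spec: ModelSpec, path: str | Path) -> None:
    doc = {
        "coefficients": dict(spec.coefficients),
        "threshold": spec.threshold,
        "gene_medians": dict(spec.gene_medians),
        "tmb_floor": spec.tmb_floor,
        "tmb_high_cutoff": spec.tmb_high_cutoff,
        "reference_rpm": dict(spec.reference_rpm),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def default_model_spec() -> ModelSpec:
    """The packaged locked model: published coefficients and threshold."""
    with resources.files("irskit.data").joinpath("model_spec.json").open() as fh:
        doc = json.load(fh)
    return ModelSpec(
        coefficients=doc["coefficients"],
        threshold=float(doc["threshold"]),
        gene_medians=doc["gene_medians"],
        tmb_floor=float(doc["tmb_floor"]),
        tmb_high_cutoff=float(doc["tmb_high_cutoff"]),
        reference_rpm=doc.get("reference_rpm", {}),
    )


def default_agent_classes() -> dict[str, str]:
    """Packaged agent -> class map (chemotherapy, PD-1, PD-L1, CTLA4, ...).

    The full dictionary used in routine care is institution-specific; this
    default covers the synthetic agents emitted by :mod:`irskit.simulate`
    plus common real agents, and is meant to be replaced by a user-supplied
    YAML mapping for real cohorts.
    """
    with resources.files("irskit.data").joinpath("agent_classes.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return doc
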