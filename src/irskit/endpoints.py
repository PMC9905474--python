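"""Real-world survival endpoints per therapy line.

rwPFS (real-world progression-free survival, proxied by time to next
therapy) runs from a line's start date to an *effective end date*, which is
the earliest applicable of:

(b) date of death — event;
(c) start of the subsequent therapy line — event;
(a) date of last record if treatment is ongoing — censored;
(d) the latest available member-course end date — censored.

OS runs from the line's start date to death (event) or the date of last
record (censored). Durations are reported in months, defined throughout as
days / 30.4375 (the mean Gregorian month).

When death and a next line fall on the same date, death takes precedence
(it is the harder event); "ongoing" is operationalized as: no death, no
subsequent line, and the latest member-course end within one merge window
(90 days by default) of the date of last record.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .lines import LineRules, TherapyLine

DAYS_PER_MONTH = 30.4375

CENSORED_REASONS = frozenset({"ongoing", "latest_end"})


class OrderingError(ValueError):
    """Dates violate required ordering (e.g. death before line start)."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One endpoint observation for one therapy line."""

    patient_id: str
    line_number: int
    endpoint: str  # "rwPFS" | "OS"
    duration_months: float
    event: bool
    effective_end_reason: str  # ongoing | death | next_line | latest_end

    def __post_init__(self) -> None:
        if self.duration_months < 0:
            raise ValueError("negative duration")
        if self.event and self.effective_end_reason in CENSORED_REASONS:
            raise ValueError(
                f"reason {self.effective_end_reason!r} cannot be an event"
            )


def months_between(start: date, end: date) -> float:
    return (end - start).days / DAYS_PER_MONTH


def effective_end(
    line: TherapyLine,
    next_line_start: date | None,
    death_date: date | None,
    last_record_date: date,
    rules: LineRules = LineRules(),
) -> tuple[date, bool, str]:
    """Effective end date of a line with its event flag and rule label.

    The earliest qualifying event date (death or next-line start) wins; on a
    tie death takes precedence. With no event, the line is censored at the
    last record date if treatment is ongoing, otherwise at the latest
    member-course end date.
    """
    if last_record_date < line.start_date:
        raise OrderingError(
            f"{line.patient_id}: last_record_date precedes line start"
        )
    if next_line_start is not None and next_line_start < line.start_date:
        raise OrderingError(
            f"{line.patient_id}: next line starts before line {line.line_number}"
        )
    candidates: list[tuple[date, int, str]] = []
    if death_date is not None:
        candidates.append((death_date, 0, "death"))
    if next_line_start is not None:
        candidates.append((next_line_start, 1, "next_line"))
    if candidates:
        end, _, reason = min(candidates)
        return end, True, reason
    gap = (last_record_date - line.latest_member_end).days
    if gap <= rules.merge_gap_days:
        return last_record_date, False, "ongoing"
    return line.latest_member_end, False, "latest_end"


def compute_rwpfs(
    lines: list[TherapyLine],
    death_date: date | None,
    last_record_date: date,
    rules: LineRules = LineRules(),
) -> list[SurvivalRecord]:
    """rwPFS record for every non-adjuvant line of one patient.

    The "next line" for each analyzed line is the chronologically next
    non-adjuvant line (adjuvant lines are upstream by construction).
    """
    systemic = [ln for ln in lines if not ln.is_adjuvant]
    records = []
    for i, line in enumerate(systemic):
        nxt = systemic[i + 1].start_date if i + 1 < len(systemic) else None
        end, event, reason = effective_end(
            line, nxt, death_date, last_record_date, rules
        )
        records.append(
            SurvivalRecord(
                patient_id=line.patient_id,
                line_number=line.line_number,
                endpoint="rwPFS",
                duration_months=months_between(line.start_date, end),
                event=event,
                effective_end_reason=reason,
            )
        )
    return records


def compute_os(
    line: TherapyLine,
    death_date: date | None,
    last_record_date: date,
) -> SurvivalRecord:
    """OS from line start to death (event) or last record (censored)."""
    if death_date is not None:
        if death_date < line.start_date:
            raise OrderingError(
                f"{line.patient_id}: death precedes line {line.line_number} start"
            )
        end, event, reason = death_date, True, "death"
    else:
        if last_record_date < line.start_date:
            raise OrderingError(
                f"{line.patient_id}: last_record_date precedes line start"
            )
        end, event, reason = last_record_date, False, "ongoing"
    return SurvivalRecord(
        patient_id=line.patient_id,
        line_number=line.line_number,
        endpoint="OS",
        duration_months=months_between(line.start_date, end),
        event=event,
        effective_end_reason=reason,
    )


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Tabulate survival records for the statistics layer."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "line_number": [r.line_number for r in records],
            "endpoint": [r.endpoint for r in records],
            "duration_months": [r.duration_months for r in records],
            "event": [r.event for r in records],
            "effective_end_reason": [r.effective_end_reason for r in records],
        }
    )


def derive_endpoints(
    lines_by_patient: dict[str, list[TherapyLine]],
    patients: pd.DataFrame,
    rules: LineRules = LineRules(),
) -> pd.DataFrame:
    """rwPFS and OS for every non-adjuvant line across a cohort table."""
    meta = patients.set_index("patient_id")
    out: list[SurvivalRecord] = []
    for pid, lines in lines_by_patient.items():
        row = meta.loc[pid]
        death = None if pd.isna(row["death_date"]) else row["death_date"].date()
        last = row["last_record_date"].date()
        out.extend(compute_rwpfs(lines, death, last, rules))
        for line in lines:
            if not line.is_adjuvant:
                out.append(compute_os(line, death, last))
    return records_to_frame(out)
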