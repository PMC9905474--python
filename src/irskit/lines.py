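"""Line-of-therapy inference from per-dose medication records.

Real-world oncology treatment histories arrive as individual dose events or
short administration intervals. Reconstructing clinically meaningful "lines
of therapy" is a two-stage procedure:

1. **Course merging** — per patient and agent, consecutive records whose
   start dates fall within a merge window (default 90 days) are combined
   into a single course spanning the earliest start to the latest end.
2. **Line assignment** — courses are considered sequentially by start date.
   A course joins the currently open line unless it begins more than a
   delay window (default 30 days) after the line's start, or its duration
   of overlap with the line span is below a minimum fraction (default 50%),
   in which case it opens a new line.

Lines are then classified: more than one distinct agent makes a
*combination* line; any member agent of checkpoint-inhibitor class sets the
line's immuno-oncology class; and a first line consisting solely of
chemotherapy and/or hormonal agents that ended at least 180 days before the
next line's start is flagged *adjuvant* (retained, but skipped by systemic
line numbering).

Interval conventions (the published wording leaves these open; they are
fixed here and exercised by the tests): "within 90 days" is inclusive,
"more than 30 days" and "less than 50%" are strict; the overlap fraction's
denominator is the candidate course's own duration (a short course fully
nested in a line always joins it), with a shared single day counting as one
day of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

IO_CLASSES = ("PD-1", "PD-L1", "CTLA4")
ADJUVANT_CLASSES = frozenset({"chemotherapy", "hormonal"})


@dataclass(frozen=True)
class LineRules:
    """Windows (days) and thresholds controlling line inference."""

    merge_gap_days: int = 90
    new_line_delay_days: int = 30
    overlap_fraction_min: float = 0.50
    adjuvant_gap_days: int = 180

    def __post_init__(self) -> None:
        if min(self.merge_gap_days, self.new_line_delay_days,
               self.adjuvant_gap_days) <= 0:
            raise ValueError("all day windows must be strictly positive")
        if not 0 < self.overlap_fraction_min <= 1:
            raise ValueError("overlap_fraction_min must be in (0, 1]")


@dataclass(frozen=True)
class MedicationRecord:
    """One dose event or administration interval."""

    patient_id: str
    agent: str
    agent_class: str
    start_date: date
    end_date: date
    record_id: int | None = None

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(
                f"{self.patient_id}/{self.agent}: end_date before start_date"
            )


@dataclass(frozen=True)
class TreatmentCourse:
    """Merged run of same-agent records with a single start and end date."""

    patient_id: str
    agent: str
    agent_class: str
    start_date: date
    end_date: date
    source_record_ids: tuple[int, ...] = ()

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass
class TherapyLine:
    """A non-overlapping line of therapy with classification flags."""

    patient_id: str
    line_number: int
    member_courses: list[TreatmentCourse]
    start_date: date
    latest_member_end: date
    is_combination: bool = False
    is_adjuvant: bool = False
    io_class: str = "none"
    systemic_line_number: int | None = None

    @property
    def agents(self) -> set[str]:
        return {c.agent for c in self.member_courses}

    @property
    def agent_classes(self) -> set[str]:
        return {c.agent_class for c in self.member_courses}


@dataclass(frozen=True)
class AuditEntry:
    """Which rule placed a course into (or out of) a line."""

    patient_id: str
    agent: str
    course_start: date
    line_number: int
    rule: str  # first_course | joined | new_line_late_start | new_line_low_overlap


def _course_sort_key(c: TreatmentCourse):
    # same-day ties: longer course first, then agent name, for determinism
    return (c.start_date, -c.duration_days, c.agent)


def merge_courses(
    records: list[MedicationRecord], rules: LineRules = LineRules()
) -> list[TreatmentCourse]:
    """Merge per-agent dose records into treatment courses.

    Records sharing a patient and agent are sorted by start date; a record
    whose start falls within ``merge_gap_days`` (inclusive) of the previous
    record's start continues the current course. Merging never crosses
    agents.
    """
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValueError(f"records span multiple patients: {sorted(patients)}")
    by_agent: dict[tuple[str, str], list[MedicationRecord]] = {}
    for r in records:
        by_agent.setdefault((r.agent, r.agent_class), []).append(r)

    courses: list[TreatmentCourse] = []
    for (agent, agent_class), recs in by_agent.items():
        recs = sorted(recs, key=lambda r: (r.start_date, r.end_date))
        run: list[MedicationRecord] = [recs[0]]
        for rec in recs[1:]:
            if (rec.start_date - run[-1].start_date).days <= rules.merge_gap_days:
                run.append(rec)
            else:
                courses.append(_close_course(run))
                run = [rec]
        courses.append(_close_course(run))
    return sorted(courses, key=_course_sort_key)


def _close_course(run: list[MedicationRecord]) -> TreatmentCourse:
    ids = tuple(r.record_id for r in run if r.record_id is not None)
    return TreatmentCourse(
        patient_id=run[0].patient_id,
        agent=run[0].agent,
        agent_class=run[0].agent_class,
        start_date=min(r.start_date for r in run),
        end_date=max(r.end_date for r in run),
        source_record_ids=ids,
    )


def overlap_days(a_start: date, a_end: date, b_start: date, b_end: date) -> int:
    """Days of intersection of two closed date intervals; a shared day is 1."""
    lo = max(a_start, b_start)
    hi = min(a_end, b_end)
    return (hi - lo).days + 1 if hi >= lo else 0


def assign_lines(
    courses: list[TreatmentCourse],
    rules: LineRules = LineRules(),
    audit: list[AuditEntry] | None = None,
) -> list[TherapyLine]:
    """Group one patient's courses into non-overlapping lines of therapy.

    Courses are processed in start-date order (ties: longer first, then
    agent name). Each course joins the currently open line unless it starts
    strictly more than ``new_line_delay_days`` after the line's start, or
    the fraction of its own duration overlapping the line span is strictly
    below ``overlap_fraction_min``; either condition opens a new line. The
    line span grows to cover its members. When ``audit`` is supplied, one
    entry per course records the rule that fired.
    """
    if not courses:
        return []
    patients = {c.patient_id for c in courses}
    if len(patients) > 1:
        raise ValueError(f"courses span multiple patients: {sorted(patients)}")

    lines: list[TherapyLine] = []
    current: TherapyLine | None = None
    for course in sorted(courses, key=_course_sort_key):
        if current is None:
            rule = "first_course"
        else:
            delay = (course.start_date - current.start_date).days
            inter = overlap_days(
                course.start_date, course.end_date,
                current.start_date, current.latest_member_end,
            )
            frac = inter / max(course.duration_days, 1)
            if delay > rules.new_line_delay_days:
                rule = "new_line_late_start"
            elif frac < rules.overlap_fraction_min:
                rule = "new_line_low_overlap"
            else:
                rule = "joined"
        if rule == "joined":
            assert current is not None
            current.member_courses.append(course)
            current.latest_member_end = max(current.latest_member_end,
                                            course.end_date)
        else:
            current = TherapyLine(
                patient_id=course.patient_id,
                line_number=len(lines) + 1,
                member_courses=[course],
                start_date=course.start_date,
                latest_member_end=course.end_date,
            )
            lines.append(current)
        if audit is not None:
            audit.append(AuditEntry(course.patient_id, course.agent,
                                    course.start_date, current.line_number, rule))
    return lines


def classify_lines(
    lines: list[TherapyLine], rules: LineRules = LineRules()
) -> list[TherapyLine]:
    """Set combination, immuno-oncology class, and adjuvant flags in place.

    A first line of only chemotherapy/hormonal agents that ended at least
    ``adjuvant_gap_days`` before the next line's start is adjuvant; adjuvant
    lines keep their chronological ``line_number`` but receive no
    ``systemic_line_number``, which numbers the remaining lines 1, 2, ...
    """
    systemic = 0
    for i, line in enumerate(lines):
        line.is_combination = len(line.agents) > 1
        io = {c for c in line.agent_classes if c in IO_CLASSES}
        line.io_class = "none" if not io else (io.pop() if len(io) == 1 else "mixed")

        line.is_adjuvant = False
        if (
            line.line_number == 1
            and line.agent_classes <= ADJUVANT_CLASSES
            and i + 1 < len(lines)
        ):
            gap = (lines[i + 1].start_date - line.latest_member_end).days
            if gap >= rules.adjuvant_gap_days:
                line.is_adjuvant = True
        if line.is_adjuvant:
            line.systemic_line_number = None
        else:
            systemic += 1
            line.systemic_line_number = systemic
    return lines


def infer_lines(
    records: list[MedicationRecord],
    rules: LineRules = LineRules(),
    audit: list[AuditEntry] | None = None,
) -> list[TherapyLine]:
    """Full two-stage pipeline for one patient: merge, assign, classify."""
    courses = merge_courses(records, rules)
    return classify_lines(assign_lines(courses, rules, audit), rules)


def records_from_frame(df) -> dict[str, list[MedicationRecord]]:
    """Split a medications table (see :mod:`irskit.io`) into per-patient records."""
    out: dict[str, list[MedicationRecord]] = {}
    for i, row in enumerate(df.to_dict("records")):
        rec = MedicationRecord(
            patient_id=str(row["patient_id"]),
            agent=row["agent"],
            agent_class=row["class"],
            start_date=row["start_date"].date(),
            end_date=row["end_date"].date(),
            record_id=i,
        )
        out.setdefault(rec.patient_id, []).append(rec)
    return out
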