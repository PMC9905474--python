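"""Treatment-course merging and line assignment, against hand traces and a
brute-force reference implementation."""

import itertools
from datetime import timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irskit.lines import (
    LineRules,
    MedicationRecord,
    TreatmentCourse,
    assign_lines,
    classify_lines,
    infer_lines,
    merge_courses,
    overlap_days,
)

from conftest import day, dose


def course(pid, agent, cls, start, end):
    return TreatmentCourse(pid, agent, cls, day(start), day(end))


# ------------------------------------------------------------- course merging

@pytest.mark.parametrize(
    "days, expected",
    [
        ([0], [(0, 0)]),                      # single dose
        ([0, 60, 200], [(0, 60), (200, 200)]),  # 140-day gap splits
        ([0, 90], [(0, 90)]),                 # 90 days is within the window
        ([0, 91], [(0, 0), (91, 91)]),        # 91 days is not
        ([0, 80, 160, 240], [(0, 240)]),      # chained merging
    ],
)
def test_merge_window_on_same_agent(days, expected):
    got = [
        (c.start_date, c.end_date) for c in merge_courses(dose(days))
    ]
    assert got == [(day(a), day(b)) for a, b in expected]


def test_merging_is_per_agent():
    recs = dose([0, 60]) + dose([30], agent="carboplatin", cls="chemotherapy")
    courses = merge_courses(recs)
    assert sorted(c.agent for c in courses) == ["carboplatin", "pembrolizumab"]


# ------------------------------------------------------------ line assignment

def test_single_course_single_line():
    lines = assign_lines([course("p", "a", "chemotherapy", 0, 0)])
    assert [ln.line_number for ln in lines] == [1]


def test_nested_course_joins_line():
    # B starts 20 days in (<= 30) and overlaps its own span fully
    lines = assign_lines([
        course("p", "a", "chemotherapy", 0, 180),
        course("p", "b", "chemotherapy", 20, 150),
    ])
    assert len(lines) == 1
    assert lines[0].agents == {"a", "b"}


def test_late_start_opens_new_line():
    lines = assign_lines([
        course("p", "a", "chemotherapy", 0, 100),
        course("p", "b", "chemotherapy", 40, 300),
    ])
    assert [ln.line_number for ln in lines] == [1, 2]


def test_low_overlap_opens_new_line():
    # B starts day 25 (within delay) but the line span [0, 30] covers only
    # 6 of its 171 days: overlap fraction < 0.5
    lines = assign_lines([
        course("p", "a", "chemotherapy", 0, 30),
        course("p", "b", "chemotherapy", 25, 195),
    ])
    assert len(lines) == 2


def test_audit_trail_records_rules():
    from irskit.lines import AuditEntry

    audit: list[AuditEntry] = []
    assign_lines(
        [course("p", "a", "chemotherapy", 0, 100),
         course("p", "b", "chemotherapy", 40, 300)],
        audit=audit,
    )
    assert [a.rule for a in audit] == ["first_course", "new_line_late_start"]


# ------------------------------------------------------------- classification

def test_monotherapy_io_class():
    lines = classify_lines(assign_lines([course("p", "pembrolizumab", "PD-1", 0, 63)]))
    assert not lines[0].is_combination
    assert lines[0].io_class == "PD-1"


def test_combination_flag():
    lines = classify_lines(assign_lines([
        course("p", "pembrolizumab", "PD-1", 0, 63),
        course("p", "carboplatin", "chemotherapy", 0, 42),
    ]))
    assert lines[0].is_combination
    assert lines[0].io_class == "PD-1"


def test_adjuvant_first_line_chemo():
    # chemo line ends day 100; next line starts day 290: gap 190 >= 180
    lines = classify_lines(assign_lines([
        course("p", "carboplatin", "chemotherapy", 0, 100),
        course("p", "pembrolizumab", "PD-1", 290, 350),
    ]))
    assert lines[0].is_adjuvant
    assert lines[0].systemic_line_number is None
    assert lines[1].systemic_line_number == 1


def test_adjuvant_gap_below_threshold_not_flagged():
    lines = classify_lines(assign_lines([
        course("p", "carboplatin", "chemotherapy", 0, 100),
        course("p", "pembrolizumab", "PD-1", 279, 350),  # gap 179 < 180
    ]))
    assert not lines[0].is_adjuvant
    assert lines[0].systemic_line_number == 1


# ----------------------------------------------------------------- properties

@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c"]),
            st.integers(min_value=0, max_value=400),
            st.integers(min_value=0, max_value=60),
        ),
        min_size=1,
        max_size=8,
    ),
    st.randoms(use_true_random=False),
)
def test_record_order_invariance(raw, rnd):
    """Line inference is invariant to input record order."""
    recs = [
        MedicationRecord("p", agent, "chemotherapy", day(s), day(s + d))
        for agent, s, d in raw
    ]
    shuffled = list(recs)
    rnd.shuffle(shuffled)

    def fingerprint(lines):
        return [
            (ln.line_number, ln.start_date, ln.latest_member_end,
             tuple(sorted(ln.agents)), ln.is_combination, ln.is_adjuvant)
            for ln in lines
        ]

    assert fingerprint(infer_lines(recs)) == fingerprint(infer_lines(shuffled))


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c"]),
            st.integers(min_value=0, max_value=400),
            st.integers(min_value=0, max_value=120),
        ),
        min_size=1,
        max_size=6,
    )
)
def test_every_course_in_exactly_one_line(raw):
    courses = merge_courses(
        [MedicationRecord("p", a, "chemotherapy", day(s), day(s + d))
         for a, s, d in raw]
    )
    lines = assign_lines(courses)
    members = [id(c) for ln in lines for c in ln.member_courses]
    assert sorted(members) == sorted(id(c) for c in courses)
    assert len(set(members)) == len(members)


def test_assign_lines_idempotent_on_own_output():
    courses = [
        course("p", "a", "chemotherapy", 0, 30),
        course("p", "b", "chemotherapy", 10, 40),
        course("p", "a", "chemotherapy", 200, 260),
        course("p", "c", "chemotherapy", 215, 255),
    ]
    first = assign_lines(courses)
    again = assign_lines([c for ln in first for c in ln.member_courses])
    assert [ln.start_date for ln in first] == [ln.start_date for ln in again]
    assert [sorted(ln.agents) for ln in first] == [sorted(ln.agents) for ln in again]


# ------------------------------------------------------- brute-force oracle

def brute_force_lines(courses, rules=LineRules()):
    """Literal day-by-day restatement of the assignment rules.

    Independently tracks the open line as (start, end, members) and decides
    membership by explicitly enumerating each candidate course's days to
    measure overlap, rather than via interval arithmetic.
    """
    ordered = sorted(courses,
                     key=lambda c: (c.start_date, -(c.end_date - c.start_date).days,
                                    c.agent))
    lines = []
    cur = None
    for c in ordered:
        if cur is not None:
            start, end, members = cur
            days_in_line = 0
            total = 0
            d = c.start_date
            while d <= c.end_date:
                total += 1
                if start <= d <= end:
                    days_in_line += 1
                d += timedelta(days=1)
            if (c.end_date - c.start_date).days == 0:
                total = 1  # a single shared day counts fully
            frac = days_in_line / max((c.end_date - c.start_date).days, 1)
            new_line = ((c.start_date - start).days > rules.new_line_delay_days
                        or frac < rules.overlap_fraction_min)
        else:
            new_line = True
        if new_line:
            cur = [c.start_date, c.end_date, [c]]
            lines.append(cur)
        else:
            cur[1] = max(cur[1], c.end_date)
            cur[2].append(c)
    return [(s, e, tuple(sorted(m.agent for m in mem))) for s, e, mem in lines]


def test_brute_force_oracle_two_courses_exhaustive():
    """Production line assignment equals the brute-force reference over an
    exhaustive two-course grid."""
    grid = range(0, 201, 25)
    durs = [0, 20, 50, 120]
    for s1, d1, s2, d2 in itertools.product(grid, durs, grid, durs):
        courses = [course("p", "a", "chemotherapy", s1, s1 + d1),
                   course("p", "b", "chemotherapy", s2, s2 + d2)]
        got = [(ln.start_date, ln.latest_member_end,
                tuple(sorted(ln.agents)))
               for ln in assign_lines(courses)]
        assert got == brute_force_lines(courses), (s1, d1, s2, d2)
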