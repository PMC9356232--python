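"""Engagement-indicator computations: entropy, access rate, counts, GPA,
and the course/student inclusion filters."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmswell.features import (
    SemesterCalendar,
    SchemaError,
    access_rate,
    aggregate_student_semester,
    daily_activity,
    filter_courses,
    filter_students,
    gpa,
    log_count,
    shannon_entropy,
)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([7, 0, 0, 0], 0.0),
            ([2, 1, 1], 1.0397207708399179),  # −Σ p ln p with p = (.5, .25, .25)
        ],
    )
    def test_examples(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected, abs=1e-10)

    def test_base_option(self):
        assert shannon_entropy([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            shannon_entropy([0, 0, 0])

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            shannon_entropy([1, -1, 2])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=5))
    @settings(derandomize=True, max_examples=200)
    def test_brute_force_oracle_and_bounds(self, counts):
        """For ≤5 days the vectorized entropy equals naive summation, and
        0 ≤ S ≤ ln(n_days)."""
        total = sum(counts)
        if total == 0:
            return
        expected = -sum(
            (c / total) * math.log(c / total) for c in counts if c > 0
        )
        s = shannon_entropy(counts)
        assert s == pytest.approx(expected, abs=1e-12)
        assert -1e-12 <= s <= math.log(len(counts)) + 1e-12

    @given(
        st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=20),
        st.randoms(use_true_random=False),
    )
    @settings(derandomize=True, max_examples=100)
    def test_permutation_and_scaling_invariance(self, counts, rnd):
        if sum(counts) == 0:
            return
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        assert shannon_entropy(shuffled) == pytest.approx(shannon_entropy(counts), abs=1e-12)
        doubled = [2 * c for c in counts]
        assert shannon_entropy(doubled) == pytest.approx(shannon_entropy(counts), abs=1e-12)

    def test_uniform_attains_maximum(self):
        assert shannon_entropy([3] * 10) == pytest.approx(math.log(10), abs=1e-12)


class TestAccessRate:
    def test_eighty_percent_active(self):
        counts = np.zeros(100)
        counts[:80] = 1
        assert access_rate(counts, 100) == pytest.approx(0.8)

    def test_zero_vector_and_all_active(self):
        assert access_rate(np.zeros(10), 10) == 0.0
        assert access_rate(np.ones(10), 10) == 1.0

    def test_invariances(self):
        counts = np.array([0, 3, 1, 0, 5])
        assert access_rate(counts * 2, 5) == access_rate(counts, 5)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            access_rate([1, 2], 0)
        with pytest.raises(ValueError):
            access_rate([1, 2], 5)


class TestLogCount:
    def test_examples(self):
        assert log_count(100, 2)[0] == pytest.approx(50.0)
        assert log_count(0, 3) == (0.0, 0.0)
        raw, transformed = log_count(412, 1)
        assert raw == 412
        assert transformed == pytest.approx(math.log(413), abs=1e-12)

    def test_doubling_counts_doubles_raw(self):
        assert log_count(84, 3)[0] == 2 * log_count(42, 3)[0]

    def test_zero_courses(self):
        with pytest.raises(ValueError):
            log_count(10, 0)


class TestGpa:
    @pytest.mark.parametrize(
        "grades, expected",
        [(["A+"], 4.5), (["A+", "B"], 3.75), (["F", "F"], 0.0)],
    )
    def test_examples(self, grades, expected):
        assert gpa(grades) == pytest.approx(expected)

    def test_unknown_symbol_named(self):
        with pytest.raises(ValueError, match="E"):
            gpa(["A", "E"])

    def test_empty(self):
        with pytest.raises(ValueError):
            gpa([])


def _enrollments(rows):
    return pd.DataFrame(
        rows, columns=["student_id", "semester", "course_id", "credits", "grading_basis", "grade"]
    )


class TestFilters:
    def test_course_rule(self):
        enr = _enrollments(
            [
                ("s1", "f20", "A", 3, "letter", "A"),
                ("s1", "f20", "B", 3, "pass_fail", "P"),
                ("s1", "f20", "C", 1, "letter", "A+"),
            ]
        )
        assert list(filter_courses(enr)["course_id"]) == ["A"]

    def test_empty_and_noop(self):
        assert filter_courses(_enrollments([])).empty
        enr = _enrollments([("s1", "f20", f"C{i}", 3, "letter", "A") for i in range(5)])
        assert len(filter_courses(enr)) == 5

    def test_missing_columns(self):
        with pytest.raises(SchemaError):
            filter_courses(pd.DataFrame({"student_id": ["s1"]}))

    def test_student_rule(self):
        enr = _enrollments(
            [
                ("s1", "f20", "A", 3, "pass_fail", "P"),
                ("s2", "f20", "B", 2, "letter", "B"),
            ]
        )
        included = filter_students(filter_courses(enr))
        assert list(included) == ["s2"]


class TestDailyActivity:
    CAL = SemesterCalendar(date(2020, 9, 1), date(2020, 12, 9))  # 100 days

    def _events(self, stamps):
        return pd.DataFrame({"timestamp": pd.to_datetime(stamps)})

    def test_day_placement(self):
        ev = self._events(["2020-09-01 10:00"] * 3 + ["2020-09-05 23:00"])
        counts = daily_activity(ev, self.CAL)
        assert counts[0] == 3 and counts[4] == 1 and counts.sum() == 4

    def test_empty(self):
        assert daily_activity(self._events([]), self.CAL).sum() == 0

    def test_midnight_boundary(self):
        ev = self._events(["2020-09-02 23:59:00", "2020-09-03 00:01:00"])
        counts = daily_activity(ev, self.CAL)
        assert counts[1] == 1 and counts[2] == 1

    def test_outside_calendar_dropped(self):
        ev = self._events(["2020-08-31 10:00", "2020-09-01 10:00"])
        assert daily_activity(ev, self.CAL).sum() == 1


class TestAggregate:
    CAL = SemesterCalendar(date(2020, 9, 1), date(2020, 12, 21))  # 112 days

    def _fixture(self, stamps, student="s1"):
        events = pd.DataFrame(
            {
                "student_id": student,
                "course_id": "A",
                "event_type": "course-access",
                "timestamp": pd.to_datetime(stamps),
                "semester": "f20",
            }
        )
        enr = _enrollments([(student, "f20", "A", 3, "letter", "B+")])
        return events, enr

    def test_uniform_beats_crammed(self):
        uniform = [f"2020-09-{d:02d} 12:00" for d in range(1, 29)]
        crammed = ["2020-09-03 12:00"] * 28
        ev_u, enr = self._fixture(uniform)
        ev_c, _ = self._fixture(crammed)
        row_u = aggregate_student_semester(ev_u, enr, self.CAL).iloc[0]
        row_c = aggregate_student_semester(ev_c, enr, self.CAL).iloc[0]
        assert row_u["log_count"] == row_c["log_count"]
        assert row_u["log_entropy"] > row_c["log_entropy"]
        assert row_u["access_rate"] > row_c["access_rate"]

    def test_empty_event_stream(self):
        ev, enr = self._fixture([])
        row = aggregate_student_semester(ev, enr, self.CAL).iloc[0]
        assert row["log_count"] == 0
        assert row["access_rate"] == 0
        assert pd.isna(row["log_entropy"])

    def test_login_counts_but_has_no_course(self):
        ev, enr = self._fixture(["2020-09-01 10:00"])
        login = ev.copy()
        login.loc[:, "event_type"] = "login-attempt"
        login.loc[:, "course_id"] = ""
        both = pd.concat([ev, login])
        row = aggregate_student_semester(both, enr, self.CAL).iloc[0]
        assert row["n_events"] == 2

    def test_row_conservation(self, small_cohort):
        table = aggregate_student_semester(
            small_cohort.events, small_cohort.enrollments, small_cohort.calendars
        )
        expected = (
            small_cohort.enrollments.groupby(["student_id", "semester"]).ngroups
        )
        assert len(table) == expected
        assert table["log_entropy"].between(0, math.log(112)).all()
        assert table["access_rate"].between(0, 1).all()
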