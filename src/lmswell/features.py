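"""Engagement indicators from LMS event logs.

Two Blackboard log types are retained as learning activities: ``login-attempt``
(a student entered the LMS; carries no course id) and ``course-access`` (any
in-course activity: opening material, watching content, quizzes, uploads,
forum posts).  From the filtered stream three per-student-semester indicators
are computed:

* **Log-Count** — events per enrolled course per semester (intensity);
  modelled on the log1p scale because the raw counts are right-skewed.
* **Log-Entropy** — Shannon entropy (nats) of the distribution of a student's
  events over semester days (consistency; low = cramming).
* **Access-Rate** — fraction of semester days with at least one event
  (steadiness, independent of volume).

GPA on the 9-level 0–4.5 letter scale is carried along as the achievement
indicator.  Course inclusion rules: letter-graded courses worth at least two
credits; students must retain at least one qualifying course.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOGIN_ATTEMPT = "login-attempt"
COURSE_ACCESS = "course-access"
RETAINED_EVENT_TYPES = frozenset({LOGIN_ATTEMPT, COURSE_ACCESS})

#: 9-level letter-grade scale (A+ .. F). Note the D→F gap: there is no 0.5.
GRADE_POINTS: Mapping[str, float] = {
    "A+": 4.5, "A": 4.0, "B+": 3.5, "B": 3.0, "C+": 2.5,
    "C": 2.0, "D+": 1.5, "D": 1.0, "F": 0.0,
}

MIN_CREDITS = 2  # 1-credit courses proxy "< 1 h study per week" and are dropped


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass(frozen=True)
class SemesterCalendar:
    """Inclusive date span of one semester.

    ``n_days`` is the inclusive day count and is the Access-Rate denominator.
    """

    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError(
                f"end_date {self.end_date} must be after start_date {self.start_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def day_index(self, ts: datetime | date) -> int:
        """0-based semester day of a timestamp; time of day is discarded."""
        d = ts.date() if isinstance(ts, datetime) else ts
        return (d - self.start_date).days


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing columns: {missing}")


def filter_courses(enrollments: pd.DataFrame) -> pd.DataFrame:
    """Keep letter-graded enrollments worth at least :data:`MIN_CREDITS`.

    Pass/fail courses and 1-credit courses (mostly offline labs) are excluded
    from every downstream computation, including the event stream.
    """
    _require_columns(enrollments, ["grading_basis", "credits"], "enrollments")
    keep = (enrollments["grading_basis"] == "letter") & (
        enrollments["credits"] >= MIN_CREDITS
    )
    out = enrollments.loc[keep].copy()
    logger.info("filter_courses: %d of %d enrollments retained", len(out), len(enrollments))
    return out


def filter_students(qualifying_enrollments: pd.DataFrame) -> pd.Index:
    """Student ids with at least one qualifying course (post :func:`filter_courses`)."""
    _require_columns(qualifying_enrollments, ["student_id"], "enrollments")
    return pd.Index(qualifying_enrollments["student_id"].unique(), name="student_id")


def daily_activity(
    events: pd.DataFrame, calendar: SemesterCalendar
) -> np.ndarray:
    """Per-day event counts for one student-semester's filtered events.

    Returns a length ``calendar.n_days`` integer vector.  Events dated outside
    the calendar are dropped (counted in a warning).  Login attempts count as
    learning activities here just like course accesses.
    """
    _require_columns(events, ["timestamp"], "events")
    counts = np.zeros(calendar.n_days, dtype=np.int64)
    if events.empty:
        return counts
    ts = pd.to_datetime(events["timestamp"])
    idx = (ts.dt.normalize() - pd.Timestamp(calendar.start_date)).dt.days.to_numpy()
    in_range = (idx >= 0) & (idx < calendar.n_days)
    n_out = int((~in_range).sum())
    if n_out:
        logger.warning("daily_activity: dropped %d events outside the calendar", n_out)
    np.add.at(counts, idx[in_range], 1)
    return counts


def shannon_entropy(day_counts: Sequence[float] | np.ndarray, base: float | None = None) -> float:
    """Shannon entropy S = −Σ p_i log p_i of the daily activity distribution.

    ``p_i`` is the relative frequency of events on day *i*; zero-count days
    contribute nothing (0·log 0 := 0).  Natural log by default; pass ``base``
    to change it.  All-zero input is undefined and raises.
    """
    counts = np.asarray(day_counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("day_counts must be a 1-d vector")
    if (counts < 0).any():
        raise ValueError("day_counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero activity vector")
    p = counts[counts > 0] / total
    s = float(-(p * np.log(p)).sum())
    if base is not None:
        s /= math.log(base)
    return s


def access_rate(day_counts: Sequence[float] | np.ndarray, n_days: int) -> float:
    """Fraction of semester days with at least one learning activity."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    counts = np.asarray(day_counts)
    if counts.shape[0] != n_days:
        raise ValueError(f"day_counts length {counts.shape[0]} != n_days {n_days}")
    return float((counts > 0).sum() / n_days)


def log_count(total_events: float, n_courses: int) -> tuple[float, float]:
    """(raw, transformed) Log-Count: events per course, and ln(1 + raw).

    Descriptive tables report the raw value; models use the transform.
    """
    if n_courses < 1:
        raise ValueError("n_courses must be >= 1")
    if total_events < 0:
        raise ValueError("total_events must be >= 0")
    raw = total_events / n_courses
    return raw, math.log1p(raw)


def gpa(letter_grades: Sequence[str]) -> float:
    """Unweighted mean grade points over the 9-level letter scale."""
    if len(letter_grades) == 0:
        raise ValueError("at least one grade is required")
    try:
        points = [GRADE_POINTS[g] for g in letter_grades]
    except KeyError as exc:
        raise ValueError(f"unknown grade symbol: {exc.args[0]!r}") from None
    return float(np.mean(points))


@dataclass
class EngagementIndicators:
    """One student-semester's objective online-learning indicators."""

    student_id: object
    semester: object
    log_count_raw: float
    log_count: float
    log_entropy: float | None  # None when the student produced no events
    access_rate: float
    gpa: float
    n_courses: int
    n_events: int


def aggregate_student_semester(
    events: pd.DataFrame,
    enrollments: pd.DataFrame,
    calendars: Mapping[object, SemesterCalendar] | SemesterCalendar,
) -> pd.DataFrame:
    """One indicator row per included student-semester.

    Applies the course and student inclusion filters, restricts course-access
    events to qualifying courses (login attempts have no course and always
    count), and combines the five indicator computations.  ``calendars`` maps
    semester label → :class:`SemesterCalendar`; a single calendar is applied
    to every semester label present.
    """
    _require_columns(
        enrollments,
        ["student_id", "semester", "course_id", "grading_basis", "credits", "grade"],
        "enrollments",
    )
    _require_columns(
        events, ["student_id", "semester", "course_id", "event_type", "timestamp"], "events"
    )
    bad = set(events["event_type"].unique()) - RETAINED_EVENT_TYPES
    if bad:
        raise ValueError(f"unsupported event types: {sorted(bad)}")

    kept_courses = filter_courses(enrollments)
    event_groups = {k: g for k, g in events.groupby(["student_id", "semester"], sort=False)}
    empty_events = events.iloc[0:0]
    rows: list[EngagementIndicators] = []
    for (student, semester), enr in kept_courses.groupby(["student_id", "semester"], sort=True):
        cal = calendars if isinstance(calendars, SemesterCalendar) else calendars[semester]
        ev = event_groups.get((student, semester), empty_events)
        is_login = ev["event_type"] == LOGIN_ATTEMPT
        in_course = ev["course_id"].isin(set(enr["course_id"]))
        ev = ev[is_login | in_course]

        counts = daily_activity(ev, cal)
        total = int(counts.sum())
        n_courses = len(enr)
        raw, transformed = log_count(total, n_courses)
        entropy = shannon_entropy(counts) if total > 0 else None
        rows.append(
            EngagementIndicators(
                student_id=student,
                semester=semester,
                log_count_raw=raw,
                log_count=transformed,
                log_entropy=entropy,
                access_rate=access_rate(counts, cal.n_days),
                gpa=gpa(list(enr["grade"])),
                n_courses=n_courses,
                n_events=total,
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    logger.info("aggregate_student_semester: %d student-semester rows", len(out))
    return out
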