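"""Seeded synthetic cohort generator.

No student-level data are published for the cohort this package models, so
every downstream stage is exercised against generated cohorts that share its
structure: four dual-continua mental-health groups at the observed
prevalences, group-dependent engagement intensity and day-to-day consistency,
group-dependent grades and academic distress, and a minority of students
observed in both semesters whose outcomes share a student-level intercept.

Generating model per student-semester:

* group ~ categorical(group_probs); latent student intercept u ~ N(0, 1);
* engagement: each semester day is active with a Beta-heterogeneous,
  group-specific probability; event mass over active days is Dirichlet with
  a group-specific concentration (higher ⇒ more even ⇒ higher Log-Entropy);
  course-access counts are Poisson with total rate
  group_rate × n_courses × semester_days; one-plus-Poisson login-attempt
  events are added on days the student used the LMS;
* survey items are drawn from group-specific response distributions built so
  the diagnostic rules recover the assigned group (≈98% of draws; the
  remainder flip through honest item-level noise near the cutoffs);
* grades discretize a latent achievement = group mean + 0.3·(standardized
  engagement) + shared-intercept and course noise onto the 9-level scale.

Everything is driven by one ``numpy`` Generator seeded from the config, so
identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .features import SemesterCalendar
from .scoring import (
    GROUP_ORDER,
    CCAPS_COLS,
    KMDI_COLS,
    MHCSF_COLS,
    MentalHealthGroup,
)

SEMESTERS = ("2020_fall", "2021_spring")


class ConfigurationError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters; defaults restate the reference cohort.

    Group order is flourishing-and-moderate, pure languishing, pure mental
    disorder, mental-disorder-and-languishing throughout.  Engagement
    parameters (``group_activity_rate`` in course-access events per course
    per day, ``group_active_day_prob``, ``group_concentration``) were
    calibrated once against the reference group means of Log-Count,
    Access-Rate and Log-Entropy over a 112-day semester.
    """

    n_students: int = 500
    semester_days: int = 112
    group_probs: tuple[float, ...] = (0.7760, 0.1548, 0.0426, 0.0266)
    courses_per_student_mean: float = 5.09
    group_activity_rate: tuple[float, ...] = (3.48, 3.17, 2.95, 3.03)
    group_active_day_prob: tuple[float, ...] = (0.565, 0.545, 0.525, 0.515)
    group_concentration: tuple[float, ...] = (0.62, 0.61, 0.56, 0.51)
    group_distress_mean: tuple[float, ...] = (4.34, 7.98, 6.92, 11.59)
    distress_sd: float = 3.3
    group_gpa_mean: tuple[float, ...] = (3.92, 3.83, 3.64, 3.35)
    repeat_fraction: float = 0.1303
    icc: float = 0.6
    female_prob: float = 0.5765
    seed: int = 0

    def validate(self) -> None:
        if self.n_students < 1:
            raise ConfigurationError("n_students must be a positive count")
        if self.semester_days < 1:
            raise ConfigurationError("semester_days must be a positive count")
        for name in (
            "group_probs",
            "group_activity_rate",
            "group_active_day_prob",
            "group_concentration",
            "group_distress_mean",
            "group_gpa_mean",
        ):
            vec = getattr(self, name)
            if len(vec) != 4:
                raise ConfigurationError(f"{name} must have exactly 4 entries")
            if any(v < 0 for v in vec):
                raise ConfigurationError(f"{name} entries must be nonnegative")
        if abs(sum(self.group_probs) - 1.0) > 1e-12:
            raise ConfigurationError("group_probs must sum to 1")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ConfigurationError("repeat_fraction must be in [0, 1]")
        if not 0.0 <= self.icc < 1.0:
            raise ConfigurationError("icc must be in [0, 1)")
        if self.courses_per_student_mean <= 0:
            raise ConfigurationError("courses_per_student_mean must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fields = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()
        }
        return cls(**fields)


def default_config(**overrides) -> CohortConfig:
    """The reference-cohort configuration, optionally with overrides."""
    cfg = CohortConfig()
    return replace(cfg, **overrides) if overrides else cfg


def default_calendars(semester_days: int = 112) -> dict[str, SemesterCalendar]:
    """16-week calendars for the two study semesters."""
    spans = {"2020_fall": date(2020, 9, 1), "2021_spring": date(2021, 3, 2)}
    return {
        sem: SemesterCalendar(start, start + timedelta(days=semester_days - 1))
        for sem, start in spans.items()
    }


@dataclass
class SyntheticCohort:
    """Generated tables mirroring the real data feeds.

    ``truth`` records the latent generating state (assigned group, student
    intercept, engagement multiplier) for recovery tests; real cohorts have
    no such table.
    """

    students: pd.DataFrame
    events: pd.DataFrame
    enrollments: pd.DataFrame
    surveys: pd.DataFrame
    truth: pd.DataFrame
    calendars: dict[str, SemesterCalendar]
    config: CohortConfig = field(repr=False, default=None)

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out / "events.csv", index=False)
        self.enrollments.to_csv(out / "enrollments.csv", index=False)
        self.surveys.to_csv(out / "surveys.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        if self.config is not None:
            self.config.to_yaml(out / "config.yaml")


# ---------------------------------------------------------------------------
# survey item response distributions, by group
#
# Non-languishing well-being profiles never produce item values <= 1, so the
# languishing rule cannot fire; languishing profiles are constructive (at
# least one low emotional item and at least six low social/psychological
# items by design).  The disorder flag is controlled through the dysfunction
# item's tail, which is also the only source of label noise (~2%).

_MHCSF_IID = {
    MentalHealthGroup.FLOURISHING_MODERATE: [0, 0, 0.10, 0.30, 0.35, 0.25],
    MentalHealthGroup.PURE_DISORDER: [0, 0.05, 0.20, 0.35, 0.25, 0.15],
}
# (extra-low-emotional p, extra-low-rest p, low-item mean, non-low value probs on 3/4/5)
_MHCSF_LANG = {
    MentalHealthGroup.PURE_LANGUISHING: (0.3, 0.25, 0.8, [0.20, 0.30, 0.50]),
    MentalHealthGroup.DISORDER_LANGUISHING: (0.4, 0.3, 0.7, [0.35, 0.40, 0.25]),
}
_KMDI_SYMPTOMS = {
    MentalHealthGroup.FLOURISHING_MODERATE: [0.20, 0.28, 0.30, 0.15, 0.07],
    MentalHealthGroup.PURE_LANGUISHING: [0.12, 0.25, 0.30, 0.22, 0.11],
    MentalHealthGroup.PURE_DISORDER: [0.05, 0.15, 0.30, 0.32, 0.18],
    MentalHealthGroup.DISORDER_LANGUISHING: [0.00, 0.05, 0.25, 0.45, 0.25],
}
_KMDI_DYSFUNCTION = {
    MentalHealthGroup.FLOURISHING_MODERATE: [0.59, 0.40, 0.01, 0.00],
    MentalHealthGroup.PURE_LANGUISHING: [0.57, 0.41, 0.02, 0.00],
    MentalHealthGroup.PURE_DISORDER: [0.00, 0.02, 0.55, 0.43],
    MentalHealthGroup.DISORDER_LANGUISHING: [0.00, 0.02, 0.50, 0.48],
}


def generate_survey_items(
    group: MentalHealthGroup | str, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw one MHC-SF and one K-MDI item vector for the given group.

    The construction targets the group's published scale means while making
    the diagnostic rules recover the group label for ≈98% of draws.
    """
    group = MentalHealthGroup(group)
    if group in _MHCSF_IID:
        mhcsf = rng.choice(6, size=14, p=_MHCSF_IID[group])
    else:
        p_emo, p_rest, low_mean, nonlow_p = _MHCSF_LANG[group]
        mhcsf = np.empty(14, dtype=np.int64)
        n_low_emo = 1 + rng.binomial(2, p_emo)
        n_low_rest = 6 + rng.binomial(5, p_rest)
        low_emo = rng.choice(3, size=n_low_emo, replace=False)
        low_rest = 3 + rng.choice(11, size=n_low_rest, replace=False)
        low = np.concatenate([low_emo, low_rest])
        mask = np.zeros(14, dtype=bool)
        mask[low] = True
        mhcsf[mask] = rng.binomial(1, low_mean, size=mask.sum())
        mhcsf[~mask] = rng.choice([3, 4, 5], size=(~mask).sum(), p=nonlow_p)
    symptoms = rng.choice(5, size=13, p=_KMDI_SYMPTOMS[group])
    dysfunction = rng.choice(4, p=_KMDI_DYSFUNCTION[group])
    kmdi = np.append(symptoms, dysfunction)
    return {"mhcsf": mhcsf.astype(np.int64), "kmdi": kmdi.astype(np.int64)}


def _distress_items(target_total: float, rng: np.random.Generator) -> np.ndarray:
    """Four 0–4 items summing to round(clip(target_total, 0, 16))."""
    total = int(np.clip(round(target_total), 0, 16))
    items = np.zeros(4, dtype=np.int64)
    for _ in range(total):
        open_slots = np.flatnonzero(items < 4)
        items[rng.choice(open_slots)] += 1
    return items


_GRADE_LEVELS = np.array([0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5])
_GRADE_SYMBOLS = np.array(["F", "D", "D+", "C", "C+", "B", "B+", "A", "A+"])


def _snap_grades(latent: np.ndarray) -> np.ndarray:
    idx = np.abs(latent[:, None] - _GRADE_LEVELS[None, :]).argmin(axis=1)
    return _GRADE_SYMBOLS[idx]


def generate_cohort(config: CohortConfig, with_events: bool = True) -> SyntheticCohort:
    """Generate a full cohort; deterministic given ``config.seed``.

    ``with_events=False`` skips the (large) event table — useful for tests
    that only touch surveys, grades, or classification.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cals = default_calendars(config.semester_days)
    D = config.semester_days
    sqrt_icc = np.sqrt(config.icc)
    sqrt_res = np.sqrt(1.0 - config.icc)

    n = config.n_students
    groups_idx = rng.choice(4, size=n, p=np.asarray(config.group_probs) / sum(config.group_probs))
    u = rng.normal(size=n)  # stable student intercept (standardized scale)
    # distress has its own stable intercept, negatively correlated with the
    # engagement/achievement one (consistent students are less distressed)
    u_distress = -0.35 * u + np.sqrt(1 - 0.35**2) * rng.normal(size=n)
    female = rng.random(n) < config.female_prob
    age_mu = np.array([21.09, 21.38, 21.85, 21.88])
    age = np.clip(np.rint(rng.normal(age_mu[groups_idx], 2.2)), 17, 35).astype(int)
    school_year = rng.choice([1, 2, 3, 4], size=n, p=[0.27, 0.26, 0.25, 0.22])
    income = np.clip(np.rint(rng.normal(6.5, 2.9, size=n)), 1, 10).astype(int)

    is_repeat = rng.random(n) < config.repeat_fraction
    single_sem = np.where(rng.random(n) < 0.614, 0, 1)  # singles skew to 2020

    students_rows, enroll_rows, survey_rows, truth_rows = [], [], [], []
    ev_student, ev_sem, ev_course, ev_type, ev_ts = [], [], [], [], []

    for s in range(n):
        g = int(groups_idx[s])
        glabel = GROUP_ORDER[g].value
        sid = f"S{s:05d}"
        sems = SEMESTERS if is_repeat[s] else (SEMESTERS[single_sem[s]],)
        for sem in sems:
            cal = cals[sem]
            eps = rng.normal()
            z_sem = sqrt_icc * u[s] + sqrt_res * eps  # semester-level latent score

            n_courses = 1 + min(int(rng.poisson(config.courses_per_student_mean - 1.0)), 8)
            course_ids = [f"{sem}-C{s:05d}-{k}" for k in range(n_courses)]
            credits = rng.choice([2, 3, 4], size=n_courses, p=[0.25, 0.6, 0.15])

            # engagement: active days, day weights, Poisson event mass
            mult = float(np.exp(0.25 * z_sem))
            q = rng.beta(
                config.group_active_day_prob[g] * 30,
                (1 - config.group_active_day_prob[g]) * 30,
            )
            active = rng.random(D) < q
            if not active.any():
                active[rng.integers(D)] = True
            w = np.zeros(D)
            w[active] = rng.dirichlet(
                np.full(int(active.sum()), config.group_concentration[g])
            )
            day_counts = rng.poisson(
                config.group_activity_rate[g] * n_courses * D * mult * w
            )
            login_counts = np.where(day_counts > 0, 1 + rng.poisson(0.5, size=D), 0)

            if with_events:
                start = np.datetime64(cal.start_date)
                n_access = int(day_counts.sum())
                n_login = int(login_counts.sum())
                days = np.concatenate(
                    [
                        np.repeat(np.arange(D), day_counts),
                        np.repeat(np.arange(D), login_counts),
                    ]
                )
                secs = rng.integers(8 * 3600, 24 * 3600, size=n_access + n_login)
                ts = start + days.astype("timedelta64[D]") + secs.astype("timedelta64[s]")
                course_pick = rng.integers(n_courses, size=n_access)
                courses = np.concatenate(
                    [
                        np.asarray(course_ids, dtype=object)[course_pick],
                        np.full(n_login, "", dtype=object),
                    ]
                )
                types = np.concatenate(
                    [
                        np.full(n_access, "course-access", dtype=object),
                        np.full(n_login, "login-attempt", dtype=object),
                    ]
                )
                ev_student.append(np.full(n_access + n_login, sid, dtype=object))
                ev_sem.append(np.full(n_access + n_login, sem, dtype=object))
                ev_course.append(courses)
                ev_type.append(types)
                ev_ts.append(ts)

            # grades: latent achievement on the grade-point scale; z_sem doubles
            # as the standardized engagement score since it drives the multiplier
            latent = (
                config.group_gpa_mean[g]
                + 0.3 * 0.59 * z_sem  # 0.59 = reference GPA pooled SD
                + rng.normal(0.0, 0.35, size=n_courses)
            )
            grades = _snap_grades(latent)
            for cid, cr, gr in zip(course_ids, credits, grades):
                enroll_rows.append((sid, sem, cid, int(cr), "letter", gr))
            # occasional non-qualifying course, dropped by the filters
            if rng.random() < 0.35:
                kind = rng.random() < 0.5
                enroll_rows.append(
                    (
                        sid,
                        sem,
                        f"{sem}-X{s:05d}",
                        1 if kind else 2,
                        "letter" if kind else "pass_fail",
                        "A" if kind else "P",
                    )
                )

            items = generate_survey_items(GROUP_ORDER[g], rng)
            z_dist = sqrt_icc * u_distress[s] + sqrt_res * rng.normal()
            distress = _distress_items(
                config.group_distress_mean[g] + config.distress_sd * z_dist * 0.85, rng
            )
            survey_rows.append(
                {
                    "student_id": sid,
                    "semester": sem,
                    **dict(zip(MHCSF_COLS, items["mhcsf"])),
                    **dict(zip(KMDI_COLS, items["kmdi"])),
                    **dict(zip(CCAPS_COLS, distress)),
                    "sex": "female" if female[s] else "male",
                    "age": int(age[s]),
                    "school_year": int(school_year[s]),
                    "income_decile": int(income[s]),
                    "applied_credits": int(credits.sum()),
                }
            )
            students_rows.append(
                {
                    "student_id": sid,
                    "semester": sem,
                    "group": glabel,
                    "sex": "female" if female[s] else "male",
                    "age": int(age[s]),
                    "school_year": int(school_year[s]),
                    "income_decile": int(income[s]),
                }
            )
            truth_rows.append(
                {
                    "student_id": sid,
                    "semester": sem,
                    "group": glabel,
                    "student_intercept": u[s],
                    "semester_score": z_sem,
                    "engagement_multiplier": mult,
                    "n_courses": n_courses,
                }
            )

    if ev_ts:
        events = pd.DataFrame(
            {
                "student_id": np.concatenate(ev_student),
                "course_id": np.concatenate(ev_course),
                "event_type": np.concatenate(ev_type),
                "timestamp": pd.to_datetime(np.concatenate(ev_ts)),
                "semester": np.concatenate(ev_sem),
            }
        )
    else:
        events = pd.DataFrame(
            columns=["student_id", "course_id", "event_type", "timestamp", "semester"]
        )
    enrollments = pd.DataFrame(
        enroll_rows,
        columns=["student_id", "semester", "course_id", "credits", "grading_basis", "grade"],
    )
    return SyntheticCohort(
        students=pd.DataFrame(students_rows),
        events=events,
        enrollments=enrollments,
        surveys=pd.DataFrame(survey_rows),
        truth=pd.DataFrame(truth_rows),
        calendars=cals,
        config=config,
    )
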