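"""End-to-end orchestration: filters → features → scoring → statistics.

``run_pipeline`` reproduces the analysis sequence on either a synthetic
cohort or user-supplied CSV feeds: engagement indicators from the event log,
questionnaire scoring and dual-continua classification, group descriptives,
correlations among the five online-learning indicators, one-way ANOVAs with
Bonferroni post-hoc, and the random-intercept mixed models that test whether
languishing and mental disorder are independently associated with each
indicator.  ``consistency_report`` re-derives whole-cohort statistics from
group-level summaries and compares them against supplied reference values.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference as ref
from .features import SemesterCalendar, aggregate_student_semester
from .lmm import LmmResult, fit_lmm
from .scoring import GROUP_ORDER, score_survey_table
from .stats import (
    AnovaResult,
    anova_from_summary,
    chi_squared,
    oneway_anova,
    pearson_corr_matrix,
    pooled_mean,
    reconstruct_counts,
    standardize,
)
from .synthetic import CohortConfig, SyntheticCohort, default_config, generate_cohort

logger = logging.getLogger(__name__)

OUTCOMES = ("academic_distress", "gpa", "log_count", "log_entropy", "access_rate")
DESCRIPTIVE_VARS = (
    "mhcsf_total",
    "kmdi_total",
    "academic_distress",
    "gpa",
    "log_count_raw",
    "log_entropy",
    "access_rate",
)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Exactly one of ``input_dir`` (CSV feeds) or ``synthetic`` must be set."""

    synthetic: bool = False
    cohort: CohortConfig | None = None
    input_dir: Path | None = None
    calendars: Mapping[str, SemesterCalendar] | None = None
    output_dir: Path | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic == (self.input_dir is not None):
            raise PipelineConfigError(
                "exactly one of synthetic=True or input_dir must be configured"
            )
        if not self.synthetic and self.calendars is None:
            raise PipelineConfigError("real-data runs need semester calendars")


@dataclass
class ReportBundle:
    scored: pd.DataFrame
    group_counts: pd.Series
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame
    anovas: dict[str, AnovaResult]
    lmms: dict[str, LmmResult]
    log: list[str] = field(default_factory=list)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.scored.to_csv(index=False).encode())
        h.update(self.descriptives.to_csv().encode())
        h.update(self.correlations.round(12).to_csv().encode())
        for name in OUTCOMES:
            h.update(self.lmms[name].fixed_effects.round(12).to_csv(index=False).encode())
        return h.hexdigest()


def build_analysis_table(
    indicators: pd.DataFrame, scored_surveys: pd.DataFrame
) -> pd.DataFrame:
    """Merge engagement indicators with scored surveys on student-semester."""
    return indicators.merge(scored_surveys, on=["student_id", "semester"], how="inner")


def build_lmm_design(df: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects design for the mixed models.

    Continuous covariates standardized; indicators 0/1 with references:
    flourishing-and-moderate, no disorder, male, school year 1, year 2020.
    """
    design = pd.DataFrame(index=df.index)
    design["intercept"] = 1.0
    design["languishing"] = df["wellbeing_category"].eq("languishing").astype(float)
    design["disorder"] = df["disorder"].astype(float)
    design["age"] = standardize(df["age"])
    for year in (2, 3, 4):
        design[f"school_year_{year}"] = (df["school_year"] == year).astype(float)
    design["female"] = df["sex"].eq("female").astype(float)
    design["income_decile"] = standardize(df["income_decile"])
    design["applied_credits"] = standardize(df["applied_credits"])
    design["year_2021"] = df["semester"].astype(str).str.startswith("2021").astype(float)
    return design


def group_descriptives(analysis: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, %, and mean/SD of every descriptive variable."""
    order = [g.value for g in GROUP_ORDER]
    rows = {}
    counts = analysis["group"].value_counts()
    for g in order:
        sub = analysis[analysis["group"] == g]
        row = {"n": len(sub), "pct": 100 * len(sub) / len(analysis)}
        for var in DESCRIPTIVE_VARS:
            row[f"{var}_mean"] = sub[var].mean()
            row[f"{var}_sd"] = sub[var].std(ddof=1)
        rows[g] = row
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out["n"] = out["n"].astype(int)
    assert int(out["n"].sum()) == len(analysis), "group counts must conserve rows"
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and collect the report bundle; deterministic per seed."""
    config.validate()
    log: list[str] = []

    if config.synthetic:
        cohort_cfg = config.cohort or default_config(seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        events, enrollments, surveys = cohort.events, cohort.enrollments, cohort.surveys
        calendars = cohort.calendars
        log.append(f"simulated cohort: {cohort_cfg.n_students} students, seed {cohort_cfg.seed}")
    else:
        indir = Path(config.input_dir)
        events = pd.read_csv(indir / "events.csv", parse_dates=["timestamp"])
        enrollments = pd.read_csv(indir / "enrollments.csv")
        surveys = pd.read_csv(indir / "surveys.csv")
        calendars = config.calendars
        log.append(f"loaded input tables from {indir}")
    log.append(f"events in: {len(events)}; enrollments in: {len(enrollments)}; surveys in: {len(surveys)}")

    indicators = aggregate_student_semester(events, enrollments, calendars)
    log.append(f"indicator rows (included student-semesters): {len(indicators)}")

    scored = score_survey_table(surveys)
    analysis = build_analysis_table(indicators, scored)
    log.append(f"analysis rows after merge: {len(analysis)}")

    counts = analysis["group"].value_counts().reindex([g.value for g in GROUP_ORDER], fill_value=0)
    descriptives = group_descriptives(analysis)

    corr_cols = ["academic_distress", "gpa", "log_count", "log_entropy", "access_rate"]
    correlations, corr_p = pearson_corr_matrix(analysis, corr_cols)

    anovas = {
        name: oneway_anova(
            analysis[name].dropna(), analysis.loc[analysis[name].notna(), "group"]
        )
        for name in OUTCOMES
    }

    lmms: dict[str, LmmResult] = {}
    for name in OUTCOMES:
        rows = analysis[name].notna()
        sub = analysis[rows]
        design = build_lmm_design(sub)
        lmms[name] = fit_lmm(
            standardize(sub[name]), design, sub["student_id"].to_numpy()
        )
    log.append("fitted 5 ANOVA and 5 mixed models")

    bundle = ReportBundle(
        scored=analysis,
        group_counts=counts,
        descriptives=descriptives,
        correlations=correlations,
        correlation_p=corr_p,
        anovas=anovas,
        lmms=lmms,
        log=log,
    )
    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir) -> None:
    """CSV tables plus a plain-text rendering (2 dp descriptives, 3 dp tests)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.scored.to_csv(out / "analysis_table.csv", index=False)
    bundle.descriptives.to_csv(out / "descriptives.csv")
    bundle.correlations.to_csv(out / "correlations.csv")
    for name, res in bundle.lmms.items():
        res.fixed_effects.to_csv(out / f"lmm_{name}.csv", index=False)
    lines = ["Group descriptives", bundle.descriptives.round(2).to_string(), ""]
    lines += ["Correlations", bundle.correlations.round(2).to_string(), ""]
    for name, a in bundle.anovas.items():
        lines.append(
            f"ANOVA {name}: F({a.df_between}, {a.df_within}) = {a.F:.3f}, "
            f"p = {a.p:.3g}, eta2 = {a.eta2:.3f}"
        )
    lines.append("")
    for name, m in bundle.lmms.items():
        lines.append(
            f"LMM {name}: sigma2 = {m.sigma2:.2f}, tau00 = {m.tau00:.2f}, ICC = {m.icc:.2f}"
        )
        lines.append(m.fixed_effects.round(3).to_string(index=False))
        lines.append("")
    (out / "report.txt").write_text("\n".join(lines))
    (out / "log.txt").write_text("\n".join(bundle.log))


# ---------------------------------------------------------------------------
# consistency checks against published whole-cohort statistics


def consistency_report(
    reference: Mapping[str, float] | None = None,
    *,
    group_ns=ref.GROUP_NS,
    summaries=ref.GROUP_SUMMARIES,
    sex_rows=ref.SEX_ROW_PERCENTS,
    timepoint_rows=ref.TIMEPOINT_ROW_PERCENTS,
    atol: float = 5e-3,
) -> pd.DataFrame:
    """Recompute whole-cohort statistics from group summaries and diff them.

    Each check recomputes one published number — pooled means, the
    contingency χ² from reconstructed counts, summary-statistics ANOVA F and
    η², and cohort share arithmetic — and reports the signed delta against
    the reference value.  A check passes when the recomputed value rounds to
    the reference at its printed precision (relative slack for test
    statistics whose inputs are themselves rounded).
    """
    if reference is None:
        reference = ref.REFERENCE_CHECKS
    if not reference:
        return pd.DataFrame(columns=["check", "computed", "reference", "delta", "passed"])

    computed: dict[str, float] = {}
    ns = np.asarray(group_ns, float)
    computed["pooled_mean_wellbeing"] = pooled_mean(ns, ref_means(summaries, "mental_wellbeing"))
    computed["pooled_mean_disorder"] = pooled_mean(ns, ref_means(summaries, "mental_disorder"))
    sex_table = reconstruct_counts(
        [sex_rows[k][0] for k in sex_rows], [sex_rows[k][1] for k in sex_rows]
    )
    computed["chi2_sex_group"] = chi_squared(sex_table).chi2
    tp_table = reconstruct_counts(
        [timepoint_rows[k][0] for k in timepoint_rows],
        [timepoint_rows[k][1] for k in timepoint_rows],
    )
    computed["chi2_timepoint_group"] = chi_squared(tp_table).chi2
    distress = anova_from_summary(
        ns, ref_means(summaries, "academic_distress"), ref_sds(summaries, "academic_distress")
    )
    computed["anova_distress_F"] = distress.F
    computed["anova_distress_eta2"] = distress.eta2
    gpa = anova_from_summary(ns, ref_means(summaries, "gpa"), ref_sds(summaries, "gpa"))
    computed["anova_gpa_eta2"] = gpa.eta2
    computed["repeat_responder_pct"] = 100 * ref.N_REPEAT_RESPONDERS / ref.N_UNIQUE_STUDENTS
    computed["female_pct"] = 100 * ref.N_FEMALE / ref.N_TOTAL
    computed["pure_disorder_prevalence_pct"] = 100 * group_ns[2] / sum(group_ns)

    rows = []
    for check, target in reference.items():
        if check not in computed:
            continue
        value = computed[check]
        delta = value - target
        # rounded-input test statistics get 0.3% relative slack, else printed precision
        tol = max(atol, 3e-3 * abs(target)) if "chi2" in check or check.endswith("_F") else atol + 5e-4 * abs(target)
        rows.append(
            {
                "check": check,
                "computed": value,
                "reference": target,
                "delta": delta,
                "passed": abs(delta) <= tol,
            }
        )
    return pd.DataFrame(rows)


def ref_means(summaries, variable: str) -> tuple[float, ...]:
    return tuple(m for m, _ in summaries[variable])


def ref_sds(summaries, variable: str) -> tuple[float, ...]:
    return tuple(s for _, s in summaries[variable])
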