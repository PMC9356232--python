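"""Reference-cohort summary statistics.

Published group-level summaries for a cohort of 2,933 South-Korean
university student-semesters (Fall 2020 / Spring 2021), classified into the
four dual-continua groups.  Only aggregates are available — group sizes, row
percentages of categorical covariates, and per-group means/SDs — which is
exactly what the reconstruction oracles in :mod:`lmswell.stats` consume.
Group order everywhere follows :data:`lmswell.scoring.GROUP_ORDER`:
flourishing-and-moderate, pure languishing, pure mental disorder,
mental-disorder-and-languishing.
"""

from __future__ import annotations

from types import MappingProxyType

#: group sizes (sum = 2,933)
GROUP_NS = (2276, 454, 125, 78)

N_TOTAL = 2933
N_FEMALE = 1691
N_2020 = 1724
N_2021 = 1209

#: unique respondents and how many answered in both semesters
N_UNIQUE_STUDENTS = 2595
N_REPEAT_RESPONDERS = 338

#: per-group (mean, sd) of the study variables
GROUP_SUMMARIES = MappingProxyType(
    {
        "mental_wellbeing": (
            (50.48, 11.03), (29.07, 5.29), (45.50, 9.91), (25.47, 5.37)),
        "mental_disorder": (
            (21.61, 5.85), (26.36, 6.71), (33.74, 7.69), (40.00, 6.23)),
        "academic_distress": (
            (4.34, 3.23), (7.98, 3.56), (6.92, 3.51), (11.59, 3.32)),
        "gpa": ((3.92, 0.54), (3.83, 0.64), (3.64, 0.69), (3.35, 1.07)),
        "log_count_raw": (
            (422.97, 199.96), (379.93, 186.99), (356.44, 168.53), (368.02, 179.45)),
        "log_entropy": ((3.52, 0.22), (3.48, 0.25), (3.41, 0.33), (3.36, 0.37)),
        "access_rate": ((0.51, 0.09), (0.49, 0.09), (0.47, 0.10), (0.46, 0.11)),
        "age": ((21.09, 2.18), (21.38, 2.31), (21.85, 2.42), (21.88, 2.46)),
        "income_decile": ((6.60, 2.85), (6.19, 2.91), (6.38, 3.09), (6.56, 3.10)),
        "applied_credits": ((15.01, 3.77), (14.52, 4.08), (14.57, 4.14), (14.18, 4.06)),
    }
)

#: row percentages of group membership within covariate levels, with row ns
SEX_ROW_PERCENTS = MappingProxyType(
    {
        "female": ((75.58, 17.45, 4.02, 2.96), N_FEMALE),
        "male": ((80.35, 12.80, 4.59, 2.25), N_TOTAL - N_FEMALE),
    }
)

TIMEPOINT_ROW_PERCENTS = MappingProxyType(
    {
        "2020_fall": ((77.96, 15.78, 3.71, 2.55), N_2020),
        "2021_spring": ((77.09, 15.05, 5.05, 2.81), N_2021),
    }
)

#: published whole-cohort statistics used as consistency-check references
REFERENCE_CHECKS = MappingProxyType(
    {
        "chi2_sex_group": 13.951,
        "chi2_timepoint_group": 3.454,
        "pooled_mean_wellbeing": 46.29,
        "pooled_mean_disorder": 23.35,
        "anova_distress_F": 267.867,
        "anova_distress_eta2": 0.215,
        "anova_gpa_eta2": 0.033,
        "repeat_responder_pct": 13.03,
        "female_pct": 57.65,
        "pure_disorder_prevalence_pct": 4.26,
    }
)


def group_means(variable: str) -> tuple[float, ...]:
    return tuple(m for m, _ in GROUP_SUMMARIES[variable])


def group_sds(variable: str) -> tuple[float, ...]:
    return tuple(s for _, s in GROUP_SUMMARIES[variable])
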