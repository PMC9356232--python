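"""Group-comparison statistics: χ² tests, one-way ANOVA with η² and
Bonferroni post-hoc, Pearson correlations, and summary-statistics
reconstruction.

The reconstruction helpers exist because published cohort tables typically
print group sizes, row percentages, and per-group means/SDs rather than raw
data; the contingency table, pooled means, and the full one-way ANOVA
decomposition are all exactly recoverable from those summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class ReconciliationError(ValueError):
    """Reconstructed counts do not add back to the stated totals."""


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass
class PairwiseComparison:
    group_i: object
    group_j: object
    mean_diff: float
    t: float
    p_raw: float
    p_adjusted: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta2: float
    ss_between: float
    ss_within: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)


def chi_squared(observed: Sequence[Sequence[float]] | np.ndarray) -> ContingencyResult:
    """Pearson χ² test of independence, no continuity correction."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("observed must be at least a 2x2 table")
    if (obs < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column sums to zero")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=obs, expected=expected, chi2=float(chi2), df=int(df), p=float(p))


def reconstruct_counts(
    row_percents: Sequence[Sequence[float]] | np.ndarray,
    row_ns: Sequence[float],
    expected_col_sums: Sequence[float] | None = None,
) -> np.ndarray:
    """Rebuild an integer contingency table from row percentages and row sizes.

    cell = round(percent/100 × row_n).  Each percent row must sum to
    100 ± 0.5.  Rounded cells that fail to add back to the stated row n raise
    :class:`ReconciliationError` with the residuals; ``expected_col_sums``
    (e.g. published group sizes) are verified the same way.
    """
    pct = np.asarray(row_percents, dtype=float)
    ns = np.asarray(row_ns, dtype=float)
    if pct.ndim != 2 or pct.shape[0] != ns.shape[0]:
        raise ValueError("row_percents rows must match row_ns length")
    bad = np.nonzero(np.abs(pct.sum(axis=1) - 100) > 0.5)[0]
    if bad.size:
        raise ValueError(
            f"percent row {bad[0]} sums to {pct[bad[0]].sum():.2f}, expected 100 ± 0.5"
        )
    counts = np.rint(pct / 100.0 * ns[:, None]).astype(np.int64)
    residuals = counts.sum(axis=1) - ns
    if (residuals != 0).any():
        raise ReconciliationError(
            f"reconstructed row sums differ from row_ns by {residuals.astype(int).tolist()}"
        )
    if expected_col_sums is not None:
        col_res = counts.sum(axis=0) - np.asarray(expected_col_sums)
        if (col_res != 0).any():
            raise ReconciliationError(
                f"reconstructed column sums differ from expected by {col_res.astype(int).tolist()}"
            )
    return counts


def pooled_mean(ns: Sequence[float], means: Sequence[float]) -> float:
    """Size-weighted grand mean of group means."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    if ns.shape != means.shape:
        raise ValueError("ns and means must have equal length")
    if (ns < 1).any():
        raise ValueError("group sizes must be >= 1")
    return float((ns * means).sum() / ns.sum())


def anova_from_summary(
    ns: Sequence[float], means: Sequence[float], sds: Sequence[float]
) -> AnovaResult:
    """One-way ANOVA recovered from group sizes, means and SDs.

    SS_between = Σ nᵢ(mᵢ − m̄)², SS_within = Σ (nᵢ−1)sᵢ² — identical to the
    raw-data decomposition, so published group summaries suffice.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape):
        raise ValueError("ns, means, sds must have equal length")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    grand = pooled_mean(ns, means)
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(((ns - 1) * sds**2).sum())
    df_b = len(ns) - 1
    df_w = int(ns.sum()) - len(ns)
    F = (ss_b / df_b) / (ss_w / df_w)
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=float(sps.f.sf(F, df_b, df_w)),
        eta2=ss_b / (ss_b + ss_w),
        ss_between=ss_b,
        ss_within=ss_w,
    )


def oneway_anova(values: Sequence[float], group_labels: Sequence[object]) -> AnovaResult:
    """One-way ANOVA with η² and Bonferroni pooled-variance post-hoc tests.

    The post-hoc family is all group pairs; adjusted p = min(1, raw × pairs).
    """
    y = np.asarray(values, dtype=float)
    labels = pd.Series(group_labels)
    if y.shape[0] != labels.shape[0]:
        raise ValueError("values and group_labels must have equal length")
    groups = {g: y[(labels == g).to_numpy()] for g in labels.unique()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    ns = np.array([v.size for v in groups.values()], dtype=float)
    means = np.array([v.mean() for v in groups.values()])
    sds = np.array([v.std(ddof=1) for v in groups.values()])
    result = anova_from_summary(ns, means, sds)

    ms_w = result.ss_within / result.df_within
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for gi, gj in combinations(groups, 2):
        vi, vj = groups[gi], groups[gj]
        diff = vi.mean() - vj.mean()
        se = np.sqrt(ms_w * (1 / vi.size + 1 / vj.size))
        t = diff / se
        p_raw = 2 * sps.t.sf(abs(t), result.df_within)
        result.posthoc.append(
            PairwiseComparison(
                group_i=gi,
                group_j=gj,
                mean_diff=float(diff),
                t=float(t),
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, p_raw * n_pairs)),
            )
        )
    return result


def pearson_corr_matrix(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix with p-values.

    Constant columns yield NaN entries (flagged, not fatal); the diagonal is
    exactly 1 with p = 0.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i, j in combinations(range(k), 2):
        pair = table[[cols[i], cols[j]]].dropna()
        x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if len(pair) < 3 or x.std() == 0 or y.std() == 0:
            rij, pij = np.nan, np.nan
        else:
            rij, pij = sps.pearsonr(x, y)
        r.iloc[i, j] = r.iloc[j, i] = rij
        p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def standardize(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """z-scores with the sample SD (n−1 denominator)."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd
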