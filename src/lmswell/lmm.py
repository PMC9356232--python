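"""Random-intercept linear mixed models with Satterthwaite inference.

The design of the underlying study — students may answer in one or two
semesters — needs exactly one random effect: a per-student intercept that
absorbs stable between-person differences.  The model is

    y_ij = x_ij' β + u_i + e_ij,   u_i ~ N(0, τ00),   e_ij ~ N(0, σ²),

fit by REML.  The implementation profiles the REML criterion down to the
single variance ratio λ = τ00/σ², which makes the τ00 ≥ 0 boundary (reached
exactly when every student contributes one row, where the model must
collapse to OLS) a plain bounded 1-d optimisation.  Per-coefficient t tests
use the Satterthwaite approximation: the degrees of freedom come from the
delta-method variance of Var(c'β̂) propagated through the observed
information of (σ², τ00).  The intraclass correlation τ00/(τ00 + σ²) is the
share of outcome variance attributable to stable student differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

logger = logging.getLogger(__name__)

_LAMBDA_MAX = 1e4
_BOUNDARY_TOL = 1e-7


class RankDeficiencyError(ValueError):
    """The fixed-effects design is singular."""


class ConvergenceError(RuntimeError):
    """The REML optimisation failed to converge."""


@dataclass
class LmmResult:
    """REML fit of a random-intercept model.

    ``fixed_effects`` has one row per design column: beta, se, ci_low,
    ci_high, t, df (Satterthwaite), p.
    """

    fixed_effects: pd.DataFrame
    sigma2: float
    tau00: float
    icc: float
    reml_loglik: float
    n_obs: int
    n_groups: int
    converged: bool = True

    @property
    def params(self) -> pd.Series:
        return self.fixed_effects.set_index("term")["beta"]


def icc(tau00: float, sigma2: float) -> float:
    """Intraclass correlation τ00 / (τ00 + σ²)."""
    if tau00 < 0 or sigma2 < 0:
        raise ValueError("variance components must be nonnegative")
    if tau00 + sigma2 == 0:
        raise ValueError("at least one variance component must be positive")
    return tau00 / (tau00 + sigma2)


def satterthwaite_df(
    var_contrast: float, grad: np.ndarray, cov_theta: np.ndarray
) -> float:
    """Satterthwaite df = 2·Var(c'β̂)² / Var̂[Var(c'β̂)].

    ``grad`` holds ∂Var(c'β̂)/∂θ over the variance components θ and
    ``cov_theta`` their estimated covariance (inverse observed information);
    the denominator is the delta-method variance g'·A·g.  With θ = (s₁², s₂²)
    of two independent sample means this reduces exactly to the
    Welch–Satterthwaite formula.
    """
    grad = np.asarray(grad, dtype=float)
    denom = float(grad @ cov_theta @ grad)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("non-positive delta-method variance")
    return 2.0 * var_contrast**2 / denom


class _RandomInterceptREML:
    """Sufficient statistics and REML algebra for one grouping factor.

    Within cluster i, (I + λJ)⁻¹ = I − λ/(1 + nᵢλ)·J, so every quantity
    reduces to cluster sums; nothing larger than p×p is ever formed.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        _, idx = np.unique(groups, return_inverse=True)
        self.n_groups = idx.max() + 1
        self.sizes = np.bincount(idx).astype(float)
        self.Sx = np.zeros((self.n_groups, self.p))
        np.add.at(self.Sx, idx, X)
        self.Sy = np.bincount(idx, weights=y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _whitened(self, shrink: np.ndarray):
        """X'W⁻¹X, X'W⁻¹y, y'W⁻¹y for W⁻¹ = I − shrinkᵢ·J per cluster."""
        c = shrink
        XtWX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtWy = self.Xty - self.Sx.T @ (c * self.Sy)
        ytWy = self.yty - float(c @ self.Sy**2)
        return XtWX, XtWy, ytWy

    def profiled_neg2_reml(self, lam: float) -> float:
        """−2·REML log-likelihood profiled over β and σ², up to a constant."""
        c = lam / (1.0 + self.sizes * lam)
        XtWX, XtWy, ytWy = self._whitened(c)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - float(beta @ XtWy)  # r'W⁻¹r at the GLS solution
        if rss <= 0:
            return np.inf
        df = self.n - self.p
        logdet_W = float(np.log1p(self.sizes * lam).sum())
        return logdet_W + df * np.log(rss / df) + logdet_XtWX

    def neg2_reml(self, sigma2: float, tau00: float) -> float:
        """−2·REML log-likelihood at explicit (σ², τ00), up to a constant."""
        if sigma2 <= 0 or tau00 < 0:
            return np.inf
        d = tau00 / (sigma2 + self.sizes * tau00)
        XtWX, XtWy, ytWy = self._whitened(d)  # here W⁻¹ = σ²·V⁻¹
        sign, logdet = np.linalg.slogdet(XtWX / sigma2)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        rss = (ytWy - float(beta @ XtWy)) / sigma2
        logdet_V = self.n * np.log(sigma2) + float(
            np.log1p(self.sizes * tau00 / sigma2).sum()
        )
        return logdet_V + logdet + rss

    def gls(self, sigma2: float, tau00: float):
        """β̂ and its covariance (X'V⁻¹X)⁻¹ at fixed variance components."""
        d = tau00 / (sigma2 + self.sizes * tau00)
        XtWX, XtWy, _ = self._whitened(d)
        cov = np.linalg.inv(XtWX / sigma2)
        beta = np.linalg.solve(XtWX, XtWy)
        return beta, cov


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) > len(kept):
                kept.append(j)
            else:
                aliased.append(names[j])
        raise RankDeficiencyError(f"design is rank-deficient; aliased columns: {aliased}")


def _variance_cov(core: _RandomInterceptREML, sigma2: float, tau00: float) -> np.ndarray:
    """Covariance of (σ̂², τ̂00) from the observed information (numeric Hessian)."""
    theta = np.array([sigma2, max(tau00, 0.0)])
    h = np.maximum(1e-5 * np.abs(theta), 1e-8)

    def nll(t):
        return 0.5 * core.neg2_reml(t[0], t[1])

    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ea = np.eye(2)[a] * h[a]
            eb = np.eye(2)[b] * h[b]
            f = nll
            H[a, b] = H[b, a] = (
                f(theta + ea + eb) - f(theta + ea - eb) - f(theta - ea + eb) + f(theta - ea - eb)
            ) / (4 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        if not (np.diag(cov) > 0).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("variance-component information not positive definite")
        return None
    return cov


def fit_lmm(
    outcome: np.ndarray | pd.Series,
    design: pd.DataFrame | np.ndarray,
    student_ids: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> LmmResult:
    """Fit y = Xβ + u_student + e by REML and test β with Satterthwaite df.

    ``design`` must already contain the intercept column; continuous
    variables are expected pre-standardized by the caller (categorical
    indicators enter as 0/1).  When τ00 is estimated at the boundary —
    in particular whenever every student has a single row — the fit equals
    OLS and residual degrees of freedom n − p are used.
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(student_ids)
    if not (len(y) == X.shape[0] == len(groups)):
        raise ValueError("outcome, design and student_ids must have equal length")
    _check_design(X, names)

    core = _RandomInterceptREML(y, X, groups)
    n, p = core.n, core.p

    if core.sizes.max() == 1:
        lam_hat = 0.0
    else:
        res = optimize.minimize_scalar(
            core.profiled_neg2_reml,
            bounds=(0.0, _LAMBDA_MAX),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise ConvergenceError(f"profiled REML optimisation failed: {res.message}")
        # the bounded minimiser never evaluates the endpoints exactly
        lam_hat = 0.0 if core.profiled_neg2_reml(0.0) <= res.fun else float(res.x)

    c = lam_hat / (1.0 + core.sizes * lam_hat)
    XtWX, XtWy, ytWy = core._whitened(c)
    beta = np.linalg.solve(XtWX, XtWy)
    sigma2 = (ytWy - float(beta @ XtWy)) / (n - p)
    tau00 = lam_hat * sigma2
    at_boundary = lam_hat <= _BOUNDARY_TOL

    beta, cov_beta = core.gls(sigma2, tau00)
    se = np.sqrt(np.diag(cov_beta))

    if at_boundary:
        dfs = np.full(p, float(n - p))
    else:
        cov_theta = _variance_cov(core, sigma2, tau00)
        dfs = np.empty(p)
        for j in range(p):
            if cov_theta is None:
                dfs[j] = n - p  # fallback: residual df
                continue
            g = np.empty(2)
            theta = np.array([sigma2, tau00])
            h = np.maximum(1e-5 * theta, 1e-9)
            for a in range(2):
                tp, tm = theta.copy(), theta.copy()
                tp[a] += h[a]
                tm[a] -= h[a]
                vp = core.gls(tp[0], tp[1])[1][j, j]
                vm = core.gls(tm[0], tm[1])[1][j, j]
                g[a] = (vp - vm) / (2 * h[a])
            try:
                dfs[j] = satterthwaite_df(cov_beta[j, j], g, cov_theta)
            except ValueError:
                logger.warning("Satterthwaite df failed for %s; using residual df", names[j])
                dfs[j] = n - p

    t_stat = beta / se
    p_vals = 2 * sps.t.sf(np.abs(t_stat), dfs)
    crit = sps.t.ppf(1 - alpha / 2, dfs)
    fixed = pd.DataFrame(
        {
            "term": names,
            "beta": beta,
            "se": se,
            "ci_low": beta - crit * se,
            "ci_high": beta + crit * se,
            "t": t_stat,
            "df": dfs,
            "p": p_vals,
        }
    )
    # REML criterion with its constant, comparable across fits of the same design
    loglik = -0.5 * (core.neg2_reml(sigma2, tau00) + (n - p) * np.log(2 * np.pi))
    return LmmResult(
        fixed_effects=fixed,
        sigma2=float(sigma2),
        tau00=float(tau00),
        icc=icc(tau00, sigma2),
        reml_loglik=float(loglik),
        n_obs=n,
        n_groups=core.n_groups,
    )
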