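"""Shared linear-model engine.

Everything downstream (SNP-telomere association, cis-mQTL scanning,
mediation, interaction testing) is ordinary least squares on a common
covariate design:

    intercept + dummy-coded categoricals + numeric covariates
    + 6 of 7 cell proportions + analysis-specific extra terms.

The seventh cell proportion (granulocytes, the largest cord-blood
fraction) is dropped to break the sum-to-one collinearity.  The mQTL scan
additionally moderates residual variances across features with an
empirical-Bayes scaled inverse chi-square prior (the microarray
moderated-t approach): per-feature variances s_g^2 with d residual df are
shrunk toward a prior s0^2 with d0 prior df,

    s~_g^2 = (d0*s0^2 + d*s_g^2) / (d0 + d),

and the moderated t-statistic is referred to a t distribution with
d + d0 degrees of freedom.  (d0, s0^2) are estimated by the
method-of-moments fit to the log-variances (trigamma inversion).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import (
    BINARY_COVARIATES,
    CATEGORICAL_COVARIATES,
    CELL_TYPES,
    COVARIATE_COLUMNS,
    NUMERIC_COVARIATES,
    CovariateTable,
)

#: Cell-proportion column excluded from designs (sum-to-one reference).
DROPPED_CELL_TYPE = "Gran"


@dataclass
class DesignMatrix:
    names: list[str]
    X: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]  # full column rank is enforced at construction

    def with_columns(self, extra: dict[str, np.ndarray]) -> "DesignMatrix":
        """A new design with extra columns appended (rank re-checked)."""
        cols = [self.X] + [np.asarray(v, dtype=float).reshape(-1, 1)
                           for v in extra.values()]
        return _checked_design(self.names + list(extra), np.hstack(cols))


@dataclass
class OLSFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    s2: float          # residual variance
    df: int            # residual degrees of freedom
    n: int

    def coef_named(self, name: str) -> tuple[float, float, float, float]:
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i]), float(self.t[i]), float(self.p[i])


@dataclass
class ModerationParams:
    d0: float       # prior degrees of freedom (may be inf)
    s0_sq: float    # prior variance


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message lists dependent columns."""


def _dependent_columns(names: list[str], X: np.ndarray) -> list[str]:
    # greedy left-to-right: a column is dependent if it adds no rank to the
    # columns before it (so later-added terms get the blame)
    dep = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, :j + 1])
        if r == rank:
            dep.append(names[j])
        rank = r
    return dep


def _checked_design(names: list[str], X: np.ndarray) -> DesignMatrix:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        dep = _dependent_columns(names, X)
        raise RankDeficientError(
            f"design is rank deficient; dependent columns: {dep}")
    return DesignMatrix(names, X)


def build_design(covariates: CovariateTable | None,
                 extra_terms: dict[str, np.ndarray] | None = None,
                 n_samples: int | None = None) -> DesignMatrix:
    """Construct the full-rank covariate design matrix.

    ``covariates=None`` yields an intercept-only design of ``n_samples``
    rows (used by the simulation experiments that switch covariates off).
    Categoricals are dummy coded with the first declared level as
    reference; all seven cell proportions may be present in the table but
    only six enter the design.
    """
    extra_terms = extra_terms or {}
    if covariates is None:
        if n_samples is None:
            if not extra_terms:
                raise ValueError("need covariates, n_samples or extra terms")
            n_samples = len(next(iter(extra_terms.values())))
        names = ["intercept"]
        cols = [np.ones((n_samples, 1))]
    else:
        df = covariates.data
        if df[list(COVARIATE_COLUMNS)].isna().any().any():
            raise ValueError("missing covariate values; complete data required")
        n_samples = len(df)
        names = ["intercept"]
        cols = [np.ones((n_samples, 1))]
        for c in BINARY_COVARIATES:
            names.append(c)
            cols.append(df[c].to_numpy(dtype=float).reshape(-1, 1))
        for c in NUMERIC_COVARIATES:
            names.append(c)
            cols.append(df[c].to_numpy(dtype=float).reshape(-1, 1))
        for c, levels in CATEGORICAL_COVARIATES.items():
            vals = df[c].astype(str).to_numpy()
            for lvl in levels[1:]:
                names.append(f"{c}[{lvl}]")
                cols.append((vals == lvl).astype(float).reshape(-1, 1))
        for ct in CELL_TYPES:
            if ct == DROPPED_CELL_TYPE:
                continue
            names.append(f"cell_{ct}")
            cols.append(df[ct].to_numpy(dtype=float).reshape(-1, 1))
    for name, v in extra_terms.items():
        v = np.asarray(v, dtype=float).reshape(-1, 1)
        if len(v) != n_samples:
            raise ValueError(f"extra term {name!r} has wrong length")
        names.append(name)
        cols.append(v)
    return _checked_design(names, np.hstack(cols))


def _solve_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of (possibly multi-response) Y on X.

    Returns (beta, residual sums of squares per response, XtX inverse).
    """
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid) if Y.ndim == 2 else float(resid @ resid)
    return beta, rss, xtx_inv


def fit_ols(design: DesignMatrix | np.ndarray, response: np.ndarray,
            names: list[str] | None = None) -> OLSFit:
    """OLS with classical t-based inference.

    Standard errors come from s^2 (X'X)^-1 with s^2 = RSS / (n - rank);
    p-values are two-sided from the t distribution on the residual df.
    """
    if isinstance(design, DesignMatrix):
        X, names = design.X, design.names
    else:
        X = np.asarray(design, dtype=float)
        names = names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n = {n} <= rank = {k}: no residual degrees of freedom")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in response or design")
    beta, rss, xtx_inv = _solve_ols(X, y)
    df = n - k
    s2 = rss / df
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(list(names), beta, se, t, p, float(s2), int(df), int(n))


def fit_ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Fit many responses (columns of Y) against one design.

    Returns (beta k x m, se k x m, s2 length-m, residual df).  Used by the
    mQTL scan where thousands of CpGs share a design.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError("no residual degrees of freedom")
    beta, rss, xtx_inv = _solve_ols(X, Y)
    df = n - k
    s2 = rss / df
    diag = np.diag(xtx_inv)[:, None]
    se = np.sqrt(np.maximum(diag * s2[None, :], 0.0))
    return beta, se, s2, int(df)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Mirrors the standard microarray-moderation implementation: monotone
    Newton updates on x with convergence at relative step < ``tol``.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def ebayes_moderate(residual_variances: np.ndarray, residual_df: int
                    ) -> tuple[ModerationParams, np.ndarray, np.ndarray]:
    """Empirical-Bayes variance moderation across features.

    Fits the scaled inverse chi-square prior (d0, s0^2) to the observed
    per-feature variances by the method of moments on log variances, then
    returns the shrunken variances and the multiplier that converts each
    ordinary t into its moderated t (ordinary_t * s_g / s~_g).

    If the log-variance dispersion does not exceed what sampling alone
    implies (var <= trigamma(df/2)), the prior df is infinite and every
    moderated variance equals s0^2.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    if s2.size < 10:
        raise ValueError("need >= 10 variances to fit the prior")
    if (s2 <= 0).any():
        raise ValueError("non-positive residual variance")
    df = float(residual_df)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    dispersion = e_var - float(special.polygamma(1, df / 2.0))
    if dispersion > 0:
        d0 = 2.0 * trigamma_inverse(dispersion)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        # observed dispersion within sampling noise: point-mass prior at the
        # arithmetic mean of the variances (so constant variances moderate
        # to themselves and the moderated t is the ordinary t)
        d0 = math.inf
        s0_sq = float(s2.mean())
        s2_tilde = np.full_like(s2, s0_sq)
    t_multiplier = np.sqrt(s2 / s2_tilde)
    return ModerationParams(d0, s0_sq), s2_tilde, t_multiplier


def moderated_pvalues(t_ordinary: np.ndarray, t_multiplier: np.ndarray,
                      residual_df: int, d0: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and their two-sided p-values."""
    t_mod = np.asarray(t_ordinary) * np.asarray(t_multiplier)
    total_df = residual_df + d0
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), total_df)
    return t_mod, p


def bonferroni(p_values: np.ndarray, alpha: float = 0.05
               ) -> tuple[np.ndarray, float]:
    """Family-wise error control: flag p <= alpha/m (ties at the threshold
    are flagged significant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / p.size
    return p <= threshold, threshold
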