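"""Regressions and correlations along the productivity gradient.

Site-level assemblage responses (colony density, mean forager number,
mean nearest-neighbor distance) are regressed on mean annual
precipitation by ordinary least squares, with an optional log10
transform of the response to meet normality/homoscedasticity
assumptions.  Differences in slope between the two functional groups
(generalist foragers vs. seed specialists) are tested by a
homogeneity-of-slopes ANCOVA: a significant group × precipitation
interaction means the groups track productivity at different rates.
Rank (Spearman) and product-moment (Pearson) correlations cover the
covariate cross-checks (precipitation vs. biomass, vs. yearly rainfall)
and the density/NND associations.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .data import AncovaResult, Colony, RegressionResult

__all__ = [
    "linear_fit",
    "ancova_slopes",
    "spearman",
    "pearson",
    "aggregate_forager_numbers",
    "GradientRegression",
    "SlopeAncova",
]


class GradientRegression(BaseEstimator, RegressorMixin):
    """Ordinary least-squares regression of a site-level response on the
    precipitation covariate.

    Parameters
    ----------
    log10_y : bool, default=False
        Fit log10(response); all responses must then be positive.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted line (on the log10 scale when ``log10_y``).
    r2_ : float
        Coefficient of determination.
    f_stat_, df_, p_value_ : regression F test with df (1, n−2).
    result_ : RegressionResult
    """

    def __init__(self, log10_y: bool = False):
        self.log10_y = log10_y

    def fit(self, X, y):
        x = _as_1d(X, "x")
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        n = x.size
        if n < 3:
            raise ValueError("regression needs at least 3 points")
        if np.ptp(x) == 0:
            raise ValueError("covariate has zero variance")
        if self.log10_y:
            bad = np.nonzero(y <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"log10 transform requires positive responses; rows {bad.tolist()} "
                    f"have values {y[bad].tolist()}"
                )
            y = np.log10(y)
        df = (1, n - 2)
        if np.ptp(y) == 0:
            # constant response: null fit by convention
            self._set(0.0, float(y[0]), 0.0, 0.0, df, 1.0, n)
            return self
        model = sm.OLS(y, sm.add_constant(x)).fit()
        self._set(
            float(model.params[1]),
            float(model.params[0]),
            float(model.rsquared),
            float(model.fvalue),
            df,
            float(model.f_pvalue),
            n,
        )
        return self

    def _set(self, slope, intercept, r2, f, df, p, n):
        self.slope_ = slope
        self.intercept_ = intercept
        self.r2_ = r2
        self.f_stat_ = f
        self.df_ = df
        self.p_value_ = p
        self.result_ = RegressionResult(
            slope=slope, intercept=intercept, r2=r2, f_stat=f, df=df, p=p,
            n=n, log10_response=self.log10_y,
        )

    def predict(self, X):
        x = _as_1d(X, "x")
        yhat = self.intercept_ + self.slope_ * x
        return 10**yhat if self.log10_y else yhat


def linear_fit(x, y, log10_y: bool = False) -> RegressionResult:
    """Functional wrapper over :class:`GradientRegression`."""
    return GradientRegression(log10_y=log10_y).fit(x, y).result_


class SlopeAncova(BaseEstimator):
    """Homogeneity-of-slopes ANCOVA between exactly two groups.

    Fits ``y ~ group + x + group:x`` and reports the interaction F test
    (df (1, n−4)); per-group slopes and their standard errors come from
    separate per-group regressions, matching how per-group lines are
    reported alongside the pooled interaction test.

    Attributes
    ----------
    slope_by_group_ : dict group -> (slope, se)
    interaction_f_, interaction_df_, interaction_p_ : the slope-
        heterogeneity test.
    result_ : AncovaResult
    """

    def fit(self, X, y, group=None):
        x = _as_1d(X, "x")
        y = np.asarray(y, dtype=float).ravel()
        if group is None:
            raise ValueError("group labels are required")
        group = np.asarray(group)
        levels = sorted(pd.unique(group).tolist())
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        for lev in levels:
            if (group == lev).sum() < 3:
                raise ValueError(f"group {lev!r} has fewer than 3 points")
            if np.ptp(x[group == lev]) == 0:
                raise ValueError(f"covariate has zero variance within group {lev!r}")
        n = x.size
        is_b = (group == levels[1]).astype(float)
        design = np.column_stack([np.ones(n), is_b, x, is_b * x])
        if np.linalg.matrix_rank(design) < 4:
            raise ValueError("singular ANCOVA design")
        model = sm.OLS(y, design).fit()
        t_int = float(model.tvalues[3])
        f_int = t_int**2
        df = (1, n - 4)
        p_int = float(st.f.sf(f_int, *df)) if np.isfinite(f_int) else float("nan")
        slopes = {}
        for lev in levels:
            m = sm.OLS(y[group == lev], sm.add_constant(x[group == lev])).fit()
            slopes[lev] = (float(m.params[1]), float(m.bse[1]))
        self.slope_by_group_ = slopes
        self.interaction_f_ = f_int
        self.interaction_df_ = df
        self.interaction_p_ = p_int
        self.result_ = AncovaResult(
            slope_by_group=slopes,
            interaction_f=f_int,
            interaction_df=df,
            interaction_p=p_int,
            n=n,
        )
        return self


def ancova_slopes(x, y, group) -> AncovaResult:
    """Functional wrapper over :class:`SlopeAncova`."""
    return SlopeAncova().fit(x, y, group=group).result_


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    ``method='t'`` (default) gives the two-tailed p from the
    t-approximation t = rho·sqrt((n−2)/(1−rho²)) on n−2 df, the
    convention of standard statistics packages; ``method='exact'``
    enumerates all rank permutations (n ≤ 8).  |rho| = 1 is reported
    with p = 0.0 (print as "< 0.001")."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance")
    rx, ry = st.rankdata(x), st.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        return rho, _spearman_exact_p(rx, ry, rho)
    if method != "t":
        raise ValueError(f"unknown method {method!r}")
    if abs(rho) >= 1.0 - 1e-12:
        return float(np.sign(rho)), 0.0
    n = x.size
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * st.t.sf(abs(t), n - 2))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    if n > 8:
        raise ValueError("exact permutation p only for n <= 8")
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-tailed t test on
    n−2 df."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def aggregate_forager_numbers(
    colonies: Sequence[Colony],
) -> pd.DataFrame:
    """Mean forager number (maximum worker count over sampling periods)
    per species, the per-site response row for the forager regressions.

    Returns a frame with columns ``species, group, mean_foragers, n_colonies``.
    """
    from .data import forager_number

    rows: dict[str, list] = {}
    for c in colonies:
        rows.setdefault(c.species, []).append(c)
    out = []
    for sp in sorted(rows):
        cols = rows[sp]
        out.append(
            {
                "species": sp,
                "group": cols[0].functional_group,
                "mean_foragers": float(np.mean([forager_number(c) for c in cols])),
                "n_colonies": len(cols),
            }
        )
    return pd.DataFrame(out)


def _as_1d(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 2 and a.shape[1] == 1:
        a = a.ravel()
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-D (or a single-column 2-D array)")
    return a
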