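"""Statistical analyses for the per-cell table.

Covers the analyses the cell table feeds: median/IQR group summaries,
two-tailed Mann-Whitney-Wilcoxon comparisons, one-way ANOVA, and robust
linear regression of counts/min on dry mass by iteratively reweighted least
squares (IRLS) with Huber weights — weights w_i = min(1, c*s/|r_i|) with the
classical 95%-efficiency tuning constant c = 1.345 and the normalized median
absolute deviation as the scale s, iterated to coefficient convergence.
Goodness of fit is reported as adjusted R^2 = 1 - (1-R^2)(n-1)/(n-2), from
both the final weighted fit and the plain unweighted fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

HUBER_C = 1.345
#: Phi^-1(0.75): divides the MAD to make it consistent for a normal scale.
MAD_NORMALIZER = 0.6744897501960817


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    adjusted_r_squared: float
    ols_adjusted_r_squared: float
    p_value_slope: float
    n: int
    converged: bool
    n_irls_iterations: int
    # (intercept, slope) covariance of the final weighted fit, for CI bands
    param_cov: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def prediction_band(self, x, level: float = 0.95):
        """Symmetric confidence half-width of the fitted mean at points x."""
        x = np.asarray(x, dtype=float)
        cov = np.asarray(self.param_cov)
        var = cov[0, 0] + 2.0 * x * cov[0, 1] + x**2 * cov[1, 1]
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return tcrit * np.sqrt(np.maximum(var, 0.0))


@dataclass
class GroupComparison:
    mw_p_two_tailed: float
    mw_u: float
    anova_f: float
    anova_p: float
    per_group_median: dict
    per_group_iqr: dict


def _weighted_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    design = np.column_stack([np.ones_like(x), x])
    wd = design * w[:, None]
    coef, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ y, rcond=None)
    return coef


def _adjusted_r2(y: np.ndarray, resid: np.ndarray, w: np.ndarray) -> float:
    ybar = float(np.average(y, weights=w))
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -math.inf
    r2 = 1.0 - ss_res / ss_tot
    n = len(y)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def huber_irls(
    x,
    y,
    tuning_c: float = HUBER_C,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RegressionResult:
    """Robust line fit by IRLS with Huber weights.

    When every |residual| <= c*scale all weights are 1 and the result is
    exactly ordinary least squares.  Non-convergence within ``max_iter`` is
    flagged on the result, never silent.  The slope p-value is the two-sided
    t test of the final weighted fit.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and congruent")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")

    w = np.ones(n)
    coef = _weighted_fit(x, y, w)
    ols_resid = y - (coef[0] + coef[1] * x)
    ols_adj_r2 = _adjusted_r2(y, ols_resid, np.ones(n))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - (coef[0] + coef[1] * x)
        med = float(np.median(resid))
        scale = float(np.median(np.abs(resid - med))) / MAD_NORMALIZER
        if scale <= 0:
            converged = True  # perfect fit
            break
        absr = np.abs(resid)
        w = np.minimum(1.0, tuning_c * scale / np.maximum(absr, 1e-300))
        new_coef = _weighted_fit(x, y, w)
        if np.max(np.abs(new_coef - coef)) < tol * (1.0 + np.max(np.abs(coef))):
            coef = new_coef
            converged = True
            break
        coef = new_coef

    resid = y - (coef[0] + coef[1] * x)
    adj_r2 = _adjusted_r2(y, resid, w)

    # two-sided t test on the slope of the final weighted fit
    design = np.column_stack([np.ones(n), x])
    wd = design * w[:, None]
    xtx_inv = np.linalg.inv(wd.T @ design)
    dof = n - 2
    s2 = float(np.sum(w * resid**2)) / dof
    se_slope = math.sqrt(max(s2 * xtx_inv[1, 1], 0.0))
    if se_slope == 0:
        p_slope = 0.0 if coef[1] != 0 else 1.0
    else:
        t = coef[1] / se_slope
        p_slope = float(2.0 * sps.t.sf(abs(t), dof))

    cov = s2 * xtx_inv
    return RegressionResult(
        slope=float(coef[1]),
        intercept=float(coef[0]),
        adjusted_r_squared=float(adj_r2),
        ols_adjusted_r_squared=float(ols_adj_r2),
        p_value_slope=p_slope,
        n=n,
        converged=converged,
        n_irls_iterations=it,
        param_cov=((float(cov[0, 0]), float(cov[0, 1])), (float(cov[1, 0]), float(cov[1, 1]))),
    )


def mann_whitney_two_tailed(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney-Wilcoxon test; returns (p, U).

    Exact null enumeration for small samples (<= 10 total, no ties), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size + b.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), float(res.statistic)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0  # all values identical: no variance anywhere
    f, p = sps.f_oneway(*groups)
    if math.isnan(f):  # zero within-group variance with zero between-group spread
        return 0.0, 1.0
    return float(f), float(p)


def summarize(groups: dict) -> dict:
    """Per-group median and [Q1, Q3] (linear-interpolation quartiles).

    Returns {name: {"n", "median", "q1", "q3"}} plus a metadata entry
    recording the quartile convention.
    """
    out: dict = {"quartile_method": "linear"}
    for name, values in groups.items():
        v = np.asarray(values, dtype=np.float64)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[str(name)] = {
            "n": int(v.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    return out


def compare_groups(a, b, groups: dict | None = None) -> GroupComparison:
    """Mann-Whitney (a vs b) plus ANOVA and summaries over all supplied groups."""
    p_mw, u = mann_whitney_two_tailed(a, b)
    if groups is None:
        groups = {"a": a, "b": b}
    f, p_anova = anova_oneway(list(groups.values()))
    summary = summarize(groups)
    return GroupComparison(
        mw_p_two_tailed=p_mw,
        mw_u=u,
        anova_f=f,
        anova_p=p_anova,
        per_group_median={k: v["median"] for k, v in summary.items() if isinstance(v, dict)},
        per_group_iqr={
            k: (v["q1"], v["q3"]) for k, v in summary.items() if isinstance(v, dict)
        },
    )
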