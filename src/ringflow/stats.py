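"""Correlation, outlier and group-summary statistics for closure tables.

Pearson correlations use the t-transform ``t = r sqrt((n-2)/(1-r^2))``
for two-sided p-values; outliers against a simple linear regression are
called by externally studentized residuals (leave-one-out variance)
exceeding a conservative threshold of 3. Group summaries report mean,
SD and the 95% confidence interval ``t_{0.975, n-1} * SD / sqrt(n)`` per
metric, plus cross-group correlations computed on unweighted group
means.

One-way ANOVA with Holm-Sidak-corrected pairwise Welch tests and the
plain Welch t-test are exposed as thin pass-throughs to scipy /
statsmodels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "pearson_with_p",
    "flag_outliers_studentized",
    "summarize_groups",
    "cross_group_correlation",
    "anova_oneway",
    "welch_ttest",
    "holm_sidak",
]


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Requires n >= 3 finite pairs and non-zero variance in both
    variables. Returns ``(r, p, n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D arrays")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx ** 2).sum())
    sy = np.sqrt((dy ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float((dx * dy).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p, n


def flag_outliers_studentized(x, y, threshold: float = 3.0):
    """Outlier flags from externally studentized residuals.

    Fits ``y ~ x`` by ordinary least squares and computes leave-one-out
    (externally) studentized residuals; points with ``|t_i| >
    threshold`` are flagged. Requires n >= 4. Returns
    ``(residuals, flags)``.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for studentized residuals")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    # an (essentially) exact fit leaves 0/0 residuals that come out as
    # numerical noise; report them as zero deviations
    scale = max(float(np.abs(y).max()), 1.0)
    if model.ssr <= len(y) * (1e-10 * scale) ** 2:
        resid = np.zeros(len(y))
    else:
        resid = model.get_influence().resid_studentized_external
        resid = np.where(np.isfinite(resid), resid, 0.0)
    return resid, np.abs(resid) > threshold


def summarize_groups(table: pd.DataFrame, metrics: list[str],
                     group_col: str) -> pd.DataFrame:
    """Per-group mean, SD and 95% CI half-width for each metric.

    Returns a frame indexed by group with columns
    ``(metric, {mean, sd, ci95, n})``. Groups need n >= 2.
    """
    missing = [m for m in metrics if m not in table.columns]
    if missing or group_col not in table.columns:
        raise KeyError(
            f"missing columns {missing + ([group_col] if group_col not in table.columns else [])}; "
            f"available: {list(table.columns)}")
    rows = {}
    for g, sub in table.groupby(group_col):
        entry = {}
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            n = len(vals)
            if n < 2:
                raise ValueError(f"group {g!r} has n < 2 for metric {m!r}")
            mean = vals.mean()
            sd = vals.std(ddof=1)
            ci = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            entry[(m, "mean")] = mean
            entry[(m, "sd")] = sd
            entry[(m, "ci95")] = ci
            entry[(m, "n")] = n
        rows[g] = entry
    out = pd.DataFrame(rows).T
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    out.index.name = group_col
    return out


def cross_group_correlation(group_table: pd.DataFrame, metric_x: str,
                            metric_y: str) -> tuple[float, float, int]:
    """Pearson correlation of two metrics across group means (unweighted)."""
    x = group_table[(metric_x, "mean")].to_numpy(dtype=float)
    y = group_table[(metric_y, "mean")].to_numpy(dtype=float)
    if len(x) == 2:
        warnings.warn("correlation over 2 group means is degenerate (+/-1)")
        r = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
        return r, float("nan"), 2
    return pearson_with_p(x, y)


# ---------------------------------------------------------------------------
# thin pass-throughs to standard routines

def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p (scipy pass-through)."""
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (scipy pass-through)."""
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak-adjusted p-values (statsmodels pass-through)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float),
                         method="holm-sidak")[1]
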