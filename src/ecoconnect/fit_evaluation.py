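"""Quantify agreement between predictive and empirical differentiation.

Because predictive (model) and empirical pairwise F_ST use the same
Weir-Cockerham estimator, a perfect prediction lies on the 1:1 line.  The
fit of each parameter combination is therefore summarized by the ordinary
least squares regression of empirical on predictive values over all site
pairs: its slope, adjusted R^2, Spearman rank correlation, and a composite
goodness-of-fit scalar

    gof = 1 - sqrt(((slope - 1)^2 + (adj_R2 - 1)^2) / 2),

the rescaled Euclidean distance of (slope, adj_R2) from the perfect point
(1, 1); gof = 1 iff slope = adj_R2 = 1.  Grid-level attribution uses rank
statistics (top-fraction value shares) and a one-way eta-squared variance
decomposition, both robust to monotone redefinitions of the composite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ecoconnect.popgen import FstMatrix

#: FitResult fields carried through grid tables
FIT_FIELDS = ("slope", "intercept", "adjusted_r2", "spearman_rho", "gof")


@dataclass(frozen=True)
class FitResult:
    """Regression summary of empirical vs predictive pairwise F_ST."""

    slope: float
    intercept: float
    adjusted_r2: float
    spearman_rho: float
    gof: float
    n_pairs: int


def goodness_of_fit(slope: float, adjusted_r2: float) -> float:
    """Composite fit scalar: 1 minus scaled distance from (slope, R^2) = (1, 1)."""
    if not (np.isfinite(slope) and np.isfinite(adjusted_r2)):
        raise ValueError("goodness_of_fit requires finite slope and adjusted R^2")
    return 1.0 - np.sqrt(((slope - 1.0) ** 2 + (adjusted_r2 - 1.0) ** 2) / 2.0)


def compare_fst(predictive: FstMatrix, empirical: FstMatrix) -> FitResult:
    """OLS of empirical on predictive F_ST over matched site pairs.

    Both matrices must cover the same site set; the empirical matrix is
    re-ordered to the predictive site order before the lower triangles are
    vectorized.  Pairs where either value is NaN are dropped.
    """
    if set(predictive.sites) != set(empirical.sites):
        raise ValueError("predictive and empirical matrices must share site sets")
    order = [empirical.sites.index(s) for s in predictive.sites]
    emp = empirical.values[np.ix_(order, order)]
    idx = np.tril_indices(len(predictive.sites), k=-1)
    x = predictive.values[idx]
    y = emp[idx]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"regression needs at least 3 site pairs, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("predictive values are constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rho = float(stats.spearmanr(x, y).statistic)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adjusted_r2=float(adj),
        spearman_rho=rho,
        gof=float(goodness_of_fit(res.slope, adj)),
        n_pairs=n,
    )


def aggregate_replicates(
    rows: pd.DataFrame, param_columns: Sequence[str]
) -> pd.DataFrame:
    """Average per-replicate FitResult rows into one row per parameter cell.

    ``rows`` must contain the parameter columns plus the FitResult fields;
    the result adds ``n_replicates``.
    """
    fields = [f for f in FIT_FIELDS if f in rows.columns]
    grouped = rows.groupby(list(param_columns), sort=True, dropna=False)
    out = grouped[fields].mean()
    out["n_replicates"] = grouped.size()
    return out.reset_index()


def top_fraction_contributions(
    grid: pd.DataFrame,
    param_columns: Sequence[str],
    fraction: float = 0.2,
    score_column: str = "gof",
) -> dict[str, pd.Series]:
    """Share of each parameter value among the best-fitting grid cells.

    Selects the top ``fraction`` of rows by ``score_column`` and, for every
    parameter, reports the proportion of selected rows carrying each tested
    value (shares per parameter sum to 1).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if grid.empty:
        raise ValueError("grid is empty")
    n_top = max(int(np.ceil(fraction * len(grid))), 1)
    top = grid.nlargest(n_top, score_column)
    return {
        p: top[p].value_counts(normalize=True).sort_index()
        for p in param_columns
    }


def variance_explained(
    grid: pd.DataFrame,
    param_columns: Sequence[str],
    score_column: str = "gof",
) -> pd.Series:
    """Percent of goodness-of-fit variance attributable to each parameter.

    One-way eta-squared per parameter: between-level sum of squares over
    total sum of squares of the score, in percent.  For a binary parameter
    this equals the squared point-biserial correlation.  Constant scores give
    0 for every parameter.
    """
    y = grid[score_column].to_numpy(dtype=float)
    ss_total = ((y - y.mean()) ** 2).sum()
    out = {}
    for p in param_columns:
        levels = grid[p]
        if levels.nunique() < 2:
            raise ValueError(f"parameter {p!r} has fewer than 2 levels")
        if ss_total == 0.0:
            out[p] = 0.0
            continue
        ss_between = sum(
            len(sub) * (sub.mean() - y.mean()) ** 2
            for _, sub in grid.groupby(p, dropna=False)[score_column]
        )
        out[p] = 100.0 * ss_between / ss_total
    return pd.Series(out, name="percent_variance_explained")


def rank_candidates(
    grid: pd.DataFrame,
    candidate_column: str,
    connectivity: Optional[pd.Series] = None,
    score_column: str = "gof",
) -> pd.DataFrame:
    """Rank candidate matrices/scenarios by mean goodness of fit.

    Returns a table sorted by descending mean score with one row per
    candidate; when a per-candidate ``connectivity`` series is supplied, it
    is joined in and the Spearman correlation between mean score and
    connectivity is stored in ``result.attrs['rho_connectivity']``.
    """
    mean_score = (
        grid.groupby(candidate_column)[score_column].mean().sort_values(ascending=False)
    )
    out = mean_score.to_frame(f"mean_{score_column}")
    if connectivity is not None:
        out = out.join(connectivity.rename("mean_connectivity"))
        rho = stats.spearmanr(
            out[f"mean_{score_column}"], out["mean_connectivity"]
        ).statistic
        out.attrs["rho_connectivity"] = float(rho)
    return out
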