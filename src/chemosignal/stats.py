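"""Regression, rank-correlation and group-comparison statistics.

These are the conventional analyses wrapped around the tree-based
signal tests: ordinary least squares with per-effect partial
(drop-one) sums of squares, simple linear regression, Spearman rank
correlation (appropriate for sparse, zero-inflated concentration data),
Kruskal-Wallis for count responses, one-way ANOVA for continuous
responses, and a single-degree-of-freedom contrast comparing the two
populations of a species within a cell-means model.

Standard machinery (ranking, F/chi-square/t tails) comes from scipy;
the partial-SS effect table is assembled here by explicit reduced-model
refits so that each effect's SS is SSE(model without the effect) minus
SSE(full model), matching the usual marginal ANOVA table for a
regression.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "multiple_regression_anova",
    "simple_linreg",
    "spearman",
    "kruskal_wallis",
    "one_way_anova",
    "population_contrast",
    "normalized_range",
]


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def multiple_regression_anova(
    y: pd.Series | Sequence[float],
    X: pd.DataFrame,
    sequential: bool = False,
) -> pd.DataFrame:
    """OLS regression with a per-effect ANOVA table.

    Each predictor's SS is partial (marginal): SSE of the model refit
    without that predictor minus SSE of the full model, tested with
    F = (SS / df) / MSE_full. With ``sequential=True`` the SS are
    instead type-I (order of ``X`` columns matters). The model row tests
    all predictors jointly.

    Returns a DataFrame with rows ``model``, one per predictor, and
    ``error``; columns ``SS``, ``df``, ``F``, ``p``.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xv = np.asarray(X, dtype=float)
    n, k = Xv.shape
    if n != y.size:
        raise ValueError(f"y has {y.size} rows but X has {n}")
    if not (np.isfinite(Xv).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} observations for {k} predictors, got {n}")
    ones = np.ones((n, 1))
    full = np.hstack([ones, Xv])
    sse_full, rank = _sse(full, y)
    if rank < k + 1:
        # name the columns involved in the rank deficiency
        culprits = []
        for j in range(k):
            reduced = np.delete(full, j + 1, axis=1)
            if _sse(reduced, y)[1] == rank:
                culprits.append(names[j])
        raise ValueError(f"collinear design matrix; dependent columns include: {culprits}")
    dfe = n - (k + 1)
    mse = sse_full / dfe
    sst = float(((y - y.mean()) ** 2).sum())
    ss_model = sst - sse_full

    rows = []
    f_model = (ss_model / k) / mse
    rows.append(("model", ss_model, k, f_model, float(sps.f.sf(f_model, k, dfe))))
    prev_sse = sst
    for j, name in enumerate(names):
        if sequential:
            sub = np.hstack([ones, Xv[:, : j + 1]])
            sse_j, _ = _sse(sub, y)
            ss = prev_sse - sse_j
            prev_sse = sse_j
        else:
            reduced = np.delete(full, j + 1, axis=1)
            ss = _sse(reduced, y)[0] - sse_full
        ss = max(ss, 0.0)
        f = (ss / 1) / mse
        rows.append((name, ss, 1, f, float(sps.f.sf(f, 1, dfe))))
    rows.append(("error", sse_full, dfe, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["effect", "SS", "df", "F", "p"]).set_index("effect")
    table.attrs["n"] = n
    table.attrs["r_squared"] = ss_model / sst if sst > 0 else np.nan
    return table


def simple_linreg(x, y) -> dict:
    """Least-squares line with a two-sided F test of zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope is undefined")
    res = sps.linregress(x, y)
    f = res.rvalue**2 * (x.size - 2) / max(1.0 - res.rvalue**2, np.finfo(float).tiny)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "F": float(f),
        "p": float(res.pvalue),
        "r_squared": float(res.rvalue**2),
        "n": int(x.size),
    }


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks; t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError(f"need n >= 4, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation is undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis H (tie-corrected) with the chi-square approximation.

    If every observation is identical across all groups, H is 0 and
    p is 1 by convention (no rank information at all).
    """
    _check_groups(groups)
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(samples)
    df = len(samples) - 1
    if pooled.size < len(samples) + 1:
        raise ValueError("need total n >= number of groups + 1")
    if np.ptp(pooled) == 0:
        return {"H": 0.0, "df": df, "p": 1.0}
    h, p = sps.kruskal(*samples)
    return {"H": float(h), "df": df, "p": float(p)}


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way fixed-effects ANOVA (between/within decomposition)."""
    _check_groups(groups)
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    n = sum(s.size for s in samples)
    df1 = len(samples) - 1
    df2 = n - len(samples)
    if df2 < 1:
        raise ValueError("no error degrees of freedom (one observation per group)")
    sse = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    if sse == 0:
        raise ValueError("zero within-group variance everywhere: F is undefined")
    f, p = sps.f_oneway(*samples)
    return {"F": float(f), "df1": df1, "df2": df2, "p": float(p)}


def population_contrast(
    table: pd.DataFrame,
    species: str,
    species_col: str = "species",
    population_col: str = "population",
    value_col: str = "total_gs_umol_g",
) -> dict:
    """Single-df contrast between the two populations of one species.

    A cell-means model over every (species, population) group supplies
    the pooled error mean square; the contrast is the difference of the
    target species' two population means, with SE from the pooled MSE
    and a two-sided t test on the pooled error df.
    """
    cells = {
        key: np.asarray(sub[value_col], dtype=float)
        for key, sub in table.groupby([species_col, population_col], sort=False)
    }
    target = [key for key in cells if str(key[0]) == str(species)]
    if len(target) != 2:
        raise ValueError(
            f"species {species!r} must have exactly 2 populations, found "
            f"{[k[1] for k in target]}"
        )
    if any(cells[key].size < 2 for key in target):
        raise ValueError(f"both populations of {species!r} need >= 2 plants")
    n_total = sum(v.size for v in cells.values())
    df_error = n_total - len(cells)
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in cells.values())
    mse = sse / df_error
    (a, b) = target
    diff = cells[a].mean() - cells[b].mean()
    se = np.sqrt(mse * (1.0 / cells[a].size + 1.0 / cells[b].size))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df_error)
    return {
        "estimate": float(diff),
        "t_ratio": float(t),
        "df": int(df_error),
        "p": float(p),
        "populations": (str(a[1]), str(b[1])),
    }


def normalized_range(means: Sequence[float]) -> float:
    """(max - min) of per-species values divided by their overall mean."""
    means = np.asarray(means, dtype=float)
    overall = means.mean()
    if overall == 0:
        raise ValueError("overall mean is zero: normalized range is undefined")
    return float((means.max() - means.min()) / overall)


def _check_groups(groups: Mapping[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    empty = [k for k, v in groups.items() if len(v) == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")
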