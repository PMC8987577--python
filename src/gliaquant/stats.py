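"""Spatial aggregation and statistics over plane scores.

Plane scores are collected in a long-format table (one row per plane per
animal, columns ``animal_id``, ``group``, ``z_index``, ``z_norm``, ``ami``,
``ais``, ...).  This module aggregates planes to per-animal global scores,
builds sliding-window depth profiles along the normalized ventral-dorsal
axis, and provides the statistical machinery used downstream:

* Spearman rank correlation (AMI vs AIS; mid-ranks for ties, exact
  permutation p-values for very small samples);
* Kruskal-Wallis with Dunn pairwise post-hoc comparisons (group effects on
  non-normal, possibly ordinal-like scores);
* OLS validation regression of automated against manual scores, with the
  discrepancy-outlier rule;
* ICC(3,k) -- two-way mixed, consistency, average-of-k-raters intraclass
  correlation -- for agreement among manual raters.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

SCORE_COLUMNS = ("ami", "ais")


def animal_global_scores(
    table: pd.DataFrame, score_cols: Sequence[str] = SCORE_COLUMNS
) -> pd.DataFrame:
    """Unweighted per-animal mean of plane scores; missing planes excluded.

    Animals whose scores are all missing are dropped with a warning.
    """
    cols = list(score_cols)
    grouped = table.groupby(["animal_id", "group"], sort=True)[cols].mean()
    all_missing = grouped[cols].isna().all(axis=1)
    if all_missing.any():
        dropped = [idx[0] for idx in grouped.index[all_missing]]
        warnings.warn(
            f"excluding animals with no scored planes: {dropped}", stacklevel=2
        )
        grouped = grouped[~all_missing]
    return grouped.reset_index()


def spearman(
    x: Sequence[float], y: Sequence[float], *, exact_max_n: int = 8
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    ``rho`` is the Pearson correlation of the rank vectors.  For samples of
    ``exact_max_n`` or fewer pairs, the two-sided p-value is computed by
    exhaustive permutation of one rank vector; larger samples use the
    standard large-sample t approximation.  A constant input vector leaves
    rho undefined: returns ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        count = 0
        total = 0
        sx = rx - rx.mean()
        denom_x = math.sqrt(float(sx @ sx))
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            p = np.asarray(perm) - ry.mean()
            r = float(sx @ p) / (denom_x * math.sqrt(float(p @ p)))
            count += abs(r) >= target
            total += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


@dataclass(frozen=True)
class KruskalDunnResult:
    h: float
    p: float
    pairwise: pd.DataFrame  # group_1, group_2, z, p_raw, p_holm


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn pairwise post-hoc z tests.

    Dunn's z for groups i, j uses pooled mid-ranks:

        z = (Rbar_i - Rbar_j) / sqrt(V * (1/n_i + 1/n_j)),
        V = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)),

    with the sum over tie groups of the pooled sample.  Raw two-sided
    normal p-values are reported alongside Holm-adjusted ones; no single
    adjustment is canonical, so both are emitted.  If every observation is
    identical there is no rank separation: H = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    big_n = pooled.size
    if big_n < 3:
        raise ValueError("need at least 3 observations in total")

    pairs = list(itertools.combinations(range(len(names)), 2))
    if np.ptp(pooled) == 0:
        pairwise = pd.DataFrame(
            [
                {"group_1": names[i], "group_2": names[j], "z": 0.0, "p_raw": 1.0, "p_holm": 1.0}
                for i, j in pairs
            ]
        )
        return KruskalDunnResult(h=0.0, p=1.0, pairwise=pairwise)

    h, p = scipy.stats.kruskal(*arrays)

    ranks = scipy.stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(ranks[offsets[i] : offsets[i + 1]].mean()) for i in range(len(names))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = big_n * (big_n + 1) / 12.0 - tie_term / (12.0 * (big_n - 1))

    rows = []
    for i, j in pairs:
        se = math.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_1": names[i],
                "group_2": names[j],
                "z": z,
                "p_raw": 2.0 * scipy.stats.norm.sf(abs(z)),
            }
        )
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return KruskalDunnResult(h=float(h), p=float(p), pairwise=pairwise)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r2: float
    p: float
    outliers: np.ndarray  # boolean, |manual - auto| > threshold
    refit_slope: float | None = None
    refit_slope_ci: tuple[float, float] | None = None


def validation_regression(
    manual: Sequence[float],
    auto: Sequence[float],
    *,
    outlier_threshold: float = 6.0,
    refit_without_outliers: bool = True,
) -> RegressionResult:
    """OLS of automated on manual scores with discrepancy-outlier flags.

    Perfect agreement would give slope 1.  Pairs whose absolute
    manual-automated difference exceeds ``outlier_threshold`` (default 6
    score units) are flagged, and the regression is optionally refit with
    them excluded.  The slope confidence interval is the t-based 95% CI.
    """
    manual = np.asarray(manual, dtype=float)
    auto = np.asarray(auto, dtype=float)
    if manual.shape != auto.shape or manual.ndim != 1:
        raise ValueError("manual and auto must be 1-D vectors of equal length")
    if manual.size < 3:
        raise ValueError("need at least 3 score pairs")
    if np.ptp(manual) == 0:
        raise ValueError("manual scores are constant: regression undefined")

    def _fit(m: np.ndarray, a: np.ndarray):
        model = sm.OLS(a, sm.add_constant(m)).fit()
        ci = model.conf_int(alpha=0.05)
        return model, (float(ci[1][0]), float(ci[1][1]))

    model, slope_ci = _fit(manual, auto)
    outliers = np.abs(manual - auto) > outlier_threshold

    refit_slope = refit_ci = None
    if refit_without_outliers and outliers.any():
        keep = ~outliers
        if keep.sum() >= 3 and np.ptp(manual[keep]) > 0:
            refit_model, refit_ci = _fit(manual[keep], auto[keep])
            refit_slope = float(refit_model.params[1])

    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=slope_ci,
        r2=float(model.rsquared),
        p=float(model.pvalues[1]),
        outliers=outliers,
        refit_slope=refit_slope,
        refit_slope_ci=refit_ci,
    )


@dataclass(frozen=True)
class ICCResult:
    icc: float
    f: float
    p: float
    ms_targets: float
    ms_error: float


def icc3k(ratings: np.ndarray) -> ICCResult:
    """ICC(3,k): two-way mixed model, consistency, average of k raters.

    ``ratings`` is a complete targets-by-raters matrix.  From the two-way
    ANOVA decomposition without interaction,

        ICC(3,k) = (MS_targets - MS_error) / MS_targets,

    where MS_error is the residual mean square after removing target and
    rater effects.  The F test is MS_targets / MS_error on
    (n-1, (n-1)(k-1)) degrees of freedom.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("ratings must be a targets x raters matrix, each >= 2")
    if np.isnan(r).any():
        raise ValueError("ratings matrix must be complete (no missing cells)")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_total = float(((r - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("zero target variance: ICC undefined")
    icc = (ms_rows - ms_err) / ms_rows
    if ms_err > 0:
        f = ms_rows / ms_err
        p = float(scipy.stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        f, p = float("inf"), 0.0
    return ICCResult(icc=float(icc), f=f, p=p, ms_targets=ms_rows, ms_error=ms_err)


def sliding_window(
    table: pd.DataFrame,
    width: float = 10.0,
    step: float = 1.0,
    score_cols: Sequence[str] = SCORE_COLUMNS,
    min_animals: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth profiles along the normalized ventral-dorsal axis.

    For each window center ``c`` in ``0, step, ..., 100``, planes with
    ``z_norm`` in ``[c - width/2, c + width/2)`` (clipped to [0, 100];
    closed on the right where the window reaches the dorsal surface at 100,
    so the dorsal-most planes are not orphaned) are averaged per animal.
    Group means and SEMs are taken across animals, and Spearman's rho
    between the windowed per-animal AMI and AIS is computed pooling all
    groups.  Windows with fewer than ``min_animals`` animals carrying both
    scores are flagged unusable (rho missing).

    Returns ``(profiles, correlation)``: per-group window statistics and
    the pooled per-window correlation.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    cols = list(score_cols)
    z = table["z_norm"].to_numpy(dtype=float)
    centers = np.arange(0.0, 100.0 + step / 2.0, step)

    profile_rows = []
    corr_rows = []
    for c in centers:
        lo = max(0.0, c - width / 2.0)
        hi = min(100.0, c + width / 2.0)
        if hi >= 100.0:
            sel = (z >= lo) & (z <= hi)
        else:
            sel = (z >= lo) & (z < hi)
        sub = table.loc[sel]
        if len(sub) == 0:
            corr_rows.append(
                {"window_center": c, "rho": np.nan, "p_value": np.nan, "n_animals": 0, "usable": False}
            )
            continue
        per_animal = sub.groupby(["animal_id", "group"], sort=True)[cols].mean().reset_index()
        for group_name, g in per_animal.groupby("group", sort=True):
            row = {"window_center": c, "group": group_name, "n_animals": len(g)}
            for col in cols:
                vals = g[col].dropna()
                row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{col}_sem"] = (
                    vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
                )
            profile_rows.append(row)

        both = per_animal.dropna(subset=cols)
        usable = (
            len(both) >= min_animals
            and len(cols) >= 2
            and np.ptp(both[cols[0]]) > 0
            and np.ptp(both[cols[1]]) > 0
        )
        if usable:
            rho, p = spearman(both[cols[0]], both[cols[1]])
            usable = not math.isnan(rho)
        else:
            rho, p = np.nan, np.nan
        corr_rows.append(
            {
                "window_center": c,
                "rho": rho,
                "p_value": p,
                "n_animals": len(both),
                "usable": bool(usable),
            }
        )

    return pd.DataFrame(profile_rows), pd.DataFrame(corr_rows)
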