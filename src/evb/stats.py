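"""Nonparametric group comparison and correlation stages.

Marker levels across diagnostic groups are compared with Kruskal-Wallis
tests followed by Dunn's pairwise z tests (Bonferroni-adjusted by default),
associations with plasma NfL and clinical scales use two-tailed Spearman
correlations, descriptives are median/IQR under the linear-interpolation
(type-7) quartile convention, and monotone trends are illustrated with
least-squares isotonic fits (pool-adjacent-violators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "GroupComparison",
    "CorrelationMatrix",
    "median_iqr",
    "kruskal_wallis",
    "dunn_pairwise",
    "spearman_matrix",
    "monotone_fit",
]


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis H plus Dunn pairwise z tests for k groups."""

    h_statistic: float
    df: int
    p_global: float
    group_names: tuple[str, ...]
    # rows (group_a, group_b, z, p_raw, p_adjusted), one per unordered pair
    pairwise: tuple[tuple[str, str, float, float, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairwise, columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix with p-values and counts."""

    variables: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.variables)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    (self.variables[i], self.variables[j], self.r[i, j], self.p[i, j], int(self.n[i, j]))
                )
        return pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p", "n"])


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (q1, q3 by linear interpolation, numpy default).

    Missing values are dropped; an empty vector after dropping is an error.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("median_iqr of an empty vector")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 linear interpolation
    return float(med), float(q1), float(q3)


def _check_groups(groups) -> list[np.ndarray]:
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float).ravel()
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError("every group needs at least one finite value")
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    return cleaned


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p-value.

    All-identical data across groups give H = 0, p = 1 rather than an error.
    """
    cleaned = _check_groups(groups)
    pooled = np.concatenate(cleaned)
    df = len(cleaned) - 1
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*cleaned)
    return float(h), df, float(p)


def dunn_pairwise(groups, group_names=None, adjust: str = "bonferroni") -> GroupComparison:
    """Dunn's post-hoc z tests on the pooled midranks after Kruskal-Wallis.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with the tie term ``T = sum(t^3 - t)`` over tied values; two-sided normal
    p-values adjusted over all k(k-1)/2 pairs by Bonferroni (capped at 1,
    the GraphPad convention), Holm, or left raw.
    """
    cleaned = _check_groups(groups)
    k = len(cleaned)
    if group_names is None:
        group_names = tuple(f"group{i}" for i in range(k))
    group_names = tuple(group_names)
    if len(group_names) != k:
        raise ValueError("group_names length mismatch")
    if adjust not in ("bonferroni", "holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    h, df, p_global = kruskal_wallis(cleaned)
    pooled = np.concatenate(cleaned)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in cleaned]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = []
    p_raw_list = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            pairs.append((group_names[i], group_names[j], float(z)))
            p_raw_list.append(min(1.0, float(p_raw)))

    m = len(p_raw_list)
    if adjust == "bonferroni":
        p_adj = [min(1.0, p * m) for p in p_raw_list]
    elif adjust == "holm":
        order = np.argsort(p_raw_list)
        p_adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw_list[idx])
            p_adj[idx] = min(1.0, running)
    else:
        p_adj = list(p_raw_list)

    pairwise = tuple(
        (a, b, z, p_raw, p_a) for (a, b, z), p_raw, p_a in zip(pairs, p_raw_list, p_adj)
    )
    return GroupComparison(h, df, p_global, group_names, pairwise)


def spearman_matrix(
    table: pd.DataFrame,
    variables,
    within: str | None = None,
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Spearman correlation matrix with pairwise-complete deletion.

    ``within`` filters to one diagnosis before correlating.  Entries with
    fewer than ``min_pairs`` complete pairs are flagged missing (NaN), never
    fabricated.  Two-sided p-values use the t approximation
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    """
    variables = tuple(variables)
    df = table[table["diagnosis"] == within] if within is not None else table
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(np.isfinite(pd.to_numeric(df[variables[i]], errors="coerce")).sum())
    for i in range(k):
        for j in range(i + 1, k):
            x = pd.to_numeric(df[variables[i]], errors="coerce").to_numpy()
            y = pd.to_numeric(df[variables[j]], errors="coerce").to_numpy()
            mask = np.isfinite(x) & np.isfinite(y)
            n[i, j] = n[j, i] = int(mask.sum())
            if mask.sum() < min_pairs:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rho, pval = stats.spearmanr(x[mask], y[mask])
            r[i, j] = r[j, i] = float(rho)
            p[i, j] = p[j, i] = float(pval)
    return CorrelationMatrix(variables, r, p, n)


def monotone_fit(x, y, direction: str = "auto") -> np.ndarray:
    """Least-squares monotone (isotonic) fit of y on x, PAVA on x-sorted data.

    ``direction="auto"`` fits both orientations and keeps the one with the
    smaller residual sum of squares.  Returns fitted values in the original
    order of x.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two points")

    def fit(increasing: bool) -> np.ndarray:
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        return iso.fit_transform(x, y)

    if direction == "increasing":
        return fit(True)
    if direction == "decreasing":
        return fit(False)
    if direction == "auto":
        up, down = fit(True), fit(False)
        return up if np.sum((y - up) ** 2) <= np.sum((y - down) ** 2) else down
    raise ValueError(f"unknown direction {direction!r}")
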