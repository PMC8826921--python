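"""Disease-progression profiling: top-k analyte ranking and the two-way
Ward/Pearson hierarchical clustering behind the group-mean heatmap.

Analytes are ranked by their most significant pairwise Welch t-test across
the three groups (CTR, dn2PD, advPD); the selected analytes are z-scored
across all samples, averaged within groups, and both axes of the resulting
matrix are clustered with Ward's minimum-variance agglomeration on
1 - Pearson correlation distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .synthetic import ConcentrationTable


class ZeroVarianceProfileError(ValueError):
    """An item has a constant profile; its Pearson distance is undefined."""


def rank_top_features(
    table: ConcentrationTable, groups: list[str], k: int = 30
) -> pd.DataFrame:
    """Rank analytes by the smallest pairwise Welch t-test p-value.

    For every analyte the Welch t statistic is computed for each pair of the
    requested groups; the ranking score is the smallest of those p-values.
    Returns the k top-ranked analytes, most contrasting first, with the
    winning p-value and group pair.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gvec = np.array([m.group for m in table.meta])
    masks = {}
    for g in groups:
        m = gvec == g
        if m.sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        masks[g] = m
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for j, name in enumerate(table.analyte_names):
        best_p, best_pair = 1.0, None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                x = table.values[masks[groups[a]], j]
                y = table.values[masks[groups[b]], j]
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                if p < best_p or best_pair is None:
                    best_p, best_pair = p, (groups[a], groups[b])
        rows.append({"analyte": name, "min_pairwise_p": best_p,
                     "best_pair": "/".join(best_pair)})
    df = pd.DataFrame(rows).sort_values("min_pairwise_p", kind="mergesort")
    return df.head(k).reset_index(drop=True)


def pearson_distance_matrix(m: np.ndarray, axis: int = 0) -> np.ndarray:
    """Pairwise 1 - Pearson correlation distances between rows (axis=0) or
    columns (axis=1)."""
    m = np.asarray(m, dtype=float)
    profiles = m if axis == 0 else m.T
    sd = profiles.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ZeroVarianceProfileError(f"constant profile(s) at index {bad}")
    r = np.corrcoef(profiles)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def ward_cluster(m: np.ndarray, axis: int = 0) -> np.ndarray:
    """Ward's minimum-variance merge tree on 1 - Pearson distances.

    Agglomeration uses the Lance-Williams recurrence on the precomputed
    correlation distances; returns the standard (n-1, 4) linkage matrix
    (merged pair, height, cluster size).
    """
    d = pearson_distance_matrix(m, axis=axis)
    return linkage(squareform(d, checks=False), method="ward")


@dataclass
class HeatmapResult:
    """Top-k group-mean heatmap with two-way Ward/Pearson merge trees."""

    analytes: list[str]
    group_means: pd.DataFrame  # analytes x groups, z-scored then averaged
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    ranking: pd.DataFrame


def heatmap_summary(
    table: ConcentrationTable, groups: list[str], k: int = 30
) -> HeatmapResult:
    """Select top-k analytes, z-score each across all samples, average within
    groups and cluster both axes.

    The z-scoring puts analytes of different concentration scales on one
    colour scale before group averaging.
    """
    ranking = rank_top_features(table, groups, k=k)
    names = ranking["analyte"].tolist()
    idx = [table.analyte_names.index(n) for n in names]
    gvec = np.array([m.group for m in table.meta])
    sub = table.values[:, idx]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    means = np.vstack([z[gvec == g].mean(axis=0) for g in groups]).T  # analytes x groups
    gm = pd.DataFrame(means, index=names, columns=groups)
    return HeatmapResult(
        analytes=names,
        group_means=gm,
        row_linkage=ward_cluster(means, axis=0),
        col_linkage=ward_cluster(means, axis=1),
        ranking=ranking,
    )


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string (heights as branch
    lengths), for interoperable inspection of the merge trees."""
    link = np.asarray(link)
    n = link.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[2 * n - 2] + ";"
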