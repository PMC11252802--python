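"""Inter-patient heterogeneity via cluster-balanced resampled Shannon entropy.

Cells are grouped by PhenoGraph-style community detection (PCA -> kNN graph
with shared-neighbour Jaccard weights -> Leiden modularity optimization); each
cluster's patient composition is then summarized by the Shannon entropy of
patient frequencies, computed on fixed-size resamples drawn with replacement
so that cluster size does not confound the comparison. Low entropy means a
patient-specific phenotype; high entropy means a phenotype shared across
patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "ClusterLabels",
    "EntropyResult",
    "knn_graph_cluster",
    "shannon_entropy",
    "subsampled_entropy",
    "compare_entropy",
    "significance_tier",
]


@dataclass
class ClusterLabels:
    labels: pd.Series  # cell_id -> cluster id (int)
    params: dict

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


@dataclass
class EntropyResult:
    """Resampled entropies per cluster plus their summary."""

    reps: pd.DataFrame      # columns: cluster, rep, entropy
    summary: pd.DataFrame   # columns: cluster, mean, sd, n_cells


def knn_graph_cluster(
    data, k: int = 30, n_pcs: int = 30, resolution: float = 1.0, seed: int = 0
) -> ClusterLabels:
    """PhenoGraph-style clustering: PCA, kNN, Jaccard SNN weights, Leiden.

    ``data`` is an ExpressionMatrix (cells = columns) or an ActivityMatrix-like
    object with ``values``/``cell_ids``; deterministic given ``seed``.
    """
    if isinstance(data, ExpressionMatrix):
        X, cell_ids = data.values.T, list(data.cell_ids)
    else:
        X, cell_ids = np.asarray(data.values).T, list(data.cell_ids)
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k = {k} must be < n_cells = {n}")
    n_comp = min(n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(
        X - X.mean(axis=0)
    )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, ind = nn.kneighbors(pcs)
    neigh = [set(row[1:]) for row in ind]

    edges, weights = [], []
    for i in range(n):
        for j in ind[i, 1:]:
            if j > i or i not in neigh[j]:
                inter = len(neigh[i] & neigh[j])
                union = len(neigh[i] | neigh[j])
                if inter:
                    edges.append((i, int(j)))
                    weights.append(inter / union)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights=weights,
        resolution_parameter=resolution, seed=seed, n_iterations=-1,
    )
    labels = pd.Series(part.membership, index=cell_ids, name="cluster")
    return ClusterLabels(labels, params={"k": k, "n_pcs": n_pcs,
                                         "resolution": resolution, "seed": seed})


def shannon_entropy(frequencies) -> float:
    """H = -sum p_i ln p_i (natural log, 0 ln 0 = 0).

    Frequencies must be non-negative; they are renormalized (with a warning)
    if they miss summing to 1 by more than 1e-6.
    """
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0):
        raise ValidationError("frequencies must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("frequencies sum to zero")
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"frequencies sum to {total:.6g}; renormalizing")
    p = p / total
    return float(stats.entropy(p))


def subsampled_entropy(
    clusters: ClusterLabels,
    patients: pd.Series,
    n_per_cluster: int = 100,
    n_reps: int = 100,
    seed: int = 0,
) -> EntropyResult:
    """Patient-frequency entropy of fixed-size with-replacement resamples.

    For every cluster and repetition, ``n_per_cluster`` cells are drawn with
    replacement (so clusters smaller than the draw are still usable) and the
    Shannon entropy of the resulting patient frequencies recorded.
    """
    rng = np.random.default_rng(seed)
    pats = patients.reindex(clusters.labels.index)
    rows, summ = [], []
    for cl, members in clusters.labels.groupby(clusters.labels):
        cells = list(members.index)
        if len(cells) == 0:
            warnings.warn(f"cluster {cl} is empty; skipped")
            continue
        cell_pats = pats.loc[cells].to_numpy()
        ents = np.empty(n_reps)
        for rep in range(n_reps):
            draw = rng.choice(cell_pats, size=n_per_cluster, replace=True)
            freqs = pd.Series(draw).value_counts(normalize=True).to_numpy()
            ents[rep] = shannon_entropy(freqs)
        rows.append(pd.DataFrame({"cluster": cl, "rep": np.arange(n_reps), "entropy": ents}))
        summ.append({"cluster": cl, "mean": float(ents.mean()),
                     "sd": float(ents.std(ddof=1)), "n_cells": len(cells)})
    return EntropyResult(pd.concat(rows, ignore_index=True), pd.DataFrame(summ))


_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional star annotation (ns/*/**/***/****)."""
    for cut, tier in _TIERS:
        if p < cut:
            return tier
    return "ns"


def compare_entropy(result: EntropyResult, grouping: pd.Series | dict) -> pd.DataFrame:
    """Pairwise rank tests of per-cluster mean entropies between groups.

    ``grouping`` maps cluster -> group label. Groups are unpaired cluster
    sets, so a two-sided Wilcoxon rank-sum (Mann-Whitney) test is used; each
    row carries the group medians, p-value and its star tier.
    """
    grouping = pd.Series(grouping)
    summ = result.summary.copy()
    summ["group"] = summ["cluster"].map(grouping)
    summ = summ.dropna(subset=["group"])
    groups = sorted(summ["group"].unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups with clusters to compare")
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            a = summ.loc[summ["group"] == ga, "mean"].to_numpy()
            b = summ.loc[summ["group"] == gb, "mean"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                try:
                    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
                    p = float(res.pvalue)
                except ValueError:
                    rows.append({"group_a": ga, "group_b": gb, "n_a": len(a),
                                 "n_b": len(b), "median_a": np.median(a) if len(a) else np.nan,
                                 "median_b": np.median(b) if len(b) else np.nan,
                                 "statistic": np.nan, "p": np.nan, "tier": "untestable"})
                    continue
            else:
                method = "exact" if (len(a) + len(b) <= 12
                                     and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
                                     ) else "asymptotic"
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
                p = float(res.pvalue)
            rows.append({"group_a": ga, "group_b": gb, "n_a": len(a), "n_b": len(b),
                         "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                         "statistic": float(res.statistic), "p": p,
                         "tier": significance_tier(p)})
    return pd.DataFrame(rows)
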