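"""GRN cell-state discovery from regulon activity.

Cells are clustered hierarchically (Ward on the z-scaled, clipped activity
matrix); the number of GRN states is chosen by maximizing the resampling
stability of the cut, measured with the adjusted Rand index (ARI) between the
full-data partition and partitions re-estimated on random subsamples. Regulons
are then assigned to GRNs by the regulon specificity score (RSS), a
Jensen-Shannon-divergence-based measure of how concentrated a regulon's
activity is in one cluster, with significance from label permutations.

``GRNStateModel`` wraps the whole stage in a model/results pair:

>>> res = GRNStateModel(activity).fit(k_range=range(2, 16), seed=0)
>>> res.partition.n_grns, res.rss, res.summary()
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .activity import ActivityMatrix, module_score
from .io import ExpressionMatrix, ValidationError

__all__ = [
    "adjusted_rand_index",
    "DendrogramModel",
    "GRNPartition",
    "cluster_dendrogram",
    "select_cut_by_ari",
    "regulon_specificity",
    "assign_regulons",
    "holdout_robustness",
    "grn_marker_summary",
    "GRNStateModel",
    "GRNStateResults",
]

logger = logging.getLogger("grnstates")


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 for identical partitions (up to relabeling), ~0 for random agreement;
    can be negative for worse-than-chance agreement.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError(f"label lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("need >= 2 items to compare partitions")
    return float(adjusted_rand_score(a, b))


@dataclass
class DendrogramModel:
    """Agglomerative merge record plus the selected cut."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4 record
    metric: str = "euclidean"
    method: str = "ward"
    cut_height: float | None = None
    n_clusters: int | None = None

    def cut(self, k: int) -> np.ndarray:
        """Labels from cutting the tree into exactly k groups."""
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def height_interval(self, k: int) -> tuple[float, float]:
        """Height interval (low, high) whose thresholds yield exactly k clusters."""
        h = np.sort(self.linkage_matrix[:, 2])
        n = len(h) + 1
        low = h[n - k - 1] if k < n else 0.0
        high = h[n - k] if k > 1 else np.inf
        return float(low), float(high)


@dataclass
class GRNPartition:
    """Cell -> GRN labels with the dendrogram and stability profile behind them."""

    labels: pd.Series  # cell_id -> "GRN1", ...
    n_grns: int
    dendrogram: DendrogramModel | None
    ari_profile: pd.DataFrame  # columns: k, mean_ari, sd_ari

    def cells_of(self, grn: str) -> list[str]:
        return list(self.labels.index[self.labels == grn])

    @property
    def grn_names(self) -> list[str]:
        return sorted(self.labels.unique(), key=lambda g: int(g.replace("GRN", "")))


def cluster_dendrogram(
    activity: ActivityMatrix, metric: str = "euclidean", method: str = "ward",
    zclip: float = 2.0,
) -> DendrogramModel:
    """Full hierarchical merge record over cells of the scaled activity view."""
    X = activity.scaled(zclip).T  # cells x regulons
    X = X[:, ~np.all(np.isnan(X), axis=0)]
    if X.shape[0] < 2:
        raise ValidationError("need >= 2 cells to cluster")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in the activity matrix")
    Z = linkage(X, method=method, metric=metric)
    return DendrogramModel(Z, metric=metric, method=method)


def _relabel(raw: np.ndarray, cell_ids: list[str]) -> pd.Series:
    """Map raw integer clusters to GRN names ordered by descending size."""
    order = pd.Series(raw).value_counts().index
    name = {c: f"GRN{i + 1}" for i, c in enumerate(order)}
    return pd.Series([name[c] for c in raw], index=cell_ids, name="grn")


def select_cut_by_ari(
    activity: ActivityMatrix,
    dendrogram: DendrogramModel | None = None,
    k_range=range(2, 16),
    n_resamples: int = 20,
    subsample_frac: float = 0.8,
    seed: int = 0,
    zclip: float = 2.0,
) -> GRNPartition:
    """Choose the dendrogram cut by resampling stability of the ARI.

    For each candidate k, the full-data cut P_k is compared (ARI) against cuts
    re-estimated on ``n_resamples`` random ``subsample_frac`` subsets; the k
    with the highest mean ARI wins, ties broken toward smaller k. Degenerate
    inputs (all cells identical) yield a single GRN and an empty profile.
    """
    n = activity.n_cells
    k_range = [k for k in k_range]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    X = activity.scaled(zclip).T
    X = X[:, ~np.all(np.isnan(X), axis=0)]
    if np.allclose(X, X[0]):
        warnings.warn("all cells identical; returning a single GRN")
        labels = pd.Series(["GRN1"] * n, index=activity.cell_ids, name="grn")
        return GRNPartition(labels, 1, dendrogram,
                            pd.DataFrame(columns=["k", "mean_ari", "sd_ari"]))
    if dendrogram is None:
        dendrogram = cluster_dendrogram(activity, zclip=zclip)

    rng = np.random.default_rng(seed)
    full_cuts = {k: dendrogram.cut(k) for k in k_range}
    m = max(2, int(round(subsample_frac * n)))
    aris = {k: [] for k in k_range}
    for _ in range(n_resamples):
        sub = rng.choice(n, size=m, replace=False)
        Zs = linkage(X[sub], method=dendrogram.method, metric=dendrogram.metric)
        for k in k_range:
            sub_labels = fcluster(Zs, t=k, criterion="maxclust")
            aris[k].append(adjusted_rand_index(full_cuts[k][sub], sub_labels))
    profile = pd.DataFrame({
        "k": k_range,
        "mean_ari": [float(np.mean(aris[k])) for k in k_range],
        "sd_ari": [float(np.std(aris[k], ddof=1)) for k in k_range],
    })
    best_k = int(profile.loc[profile["mean_ari"].idxmax(), "k"])  # idxmax: first max = smallest k
    low, high = dendrogram.height_interval(best_k)
    dendrogram.cut_height = (low + high) / 2 if np.isfinite(high) else low
    dendrogram.n_clusters = best_k
    labels = _relabel(full_cuts[best_k], list(activity.cell_ids))
    return GRNPartition(labels, best_k, dendrogram, profile)


def _rss_one(p_reg: np.ndarray, in_cluster: np.ndarray) -> float:
    q = in_cluster / in_cluster.sum()
    return float(1.0 - jensenshannon(p_reg, q, base=2))


def regulon_specificity(activity: ActivityMatrix, partition: GRNPartition) -> pd.DataFrame:
    """RSS = 1 - sqrt(JSD) between a regulon's activity distribution and each GRN.

    The regulon's raw (non-negative) activities over cells are normalized to a
    probability vector; the GRN is represented as the uniform distribution over
    its cells. Base-2 logs bound the JSD in [0, 1], so RSS is in [0, 1] with 1
    for a regulon active exactly and uniformly in the GRN and 0 for disjoint
    support. All-zero regulons are reported as missing.
    """
    labels = partition.labels.reindex(activity.cell_ids)
    if labels.isna().any():
        raise ValidationError("partition does not cover all scored cells")
    rows = []
    for i, reg in enumerate(activity.regulon_ids):
        a = activity.values[i]
        total = np.nansum(a)
        if not np.isfinite(total) or total <= 0 or np.any(a < 0):
            warnings.warn(f"regulon {reg} has no positive activity; RSS missing")
            for grn in partition.grn_names:
                rows.append({"regulon": reg, "grn": grn, "rss": np.nan})
            continue
        p = np.nan_to_num(a) / total
        for grn in partition.grn_names:
            rows.append({
                "regulon": reg, "grn": grn,
                "rss": _rss_one(p, (labels == grn).to_numpy().astype(float)),
            })
    return pd.DataFrame(rows)


def assign_regulons(
    rss_table: pd.DataFrame,
    activity: ActivityMatrix,
    partition: GRNPartition,
    n_perm: int = 1000,
    top_n: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank regulons within each GRN by RSS and attach permutation significance.

    The empirical p-value of each (regulon, GRN) pair is the fraction of
    ``n_perm`` label permutations whose RSS meets or exceeds the observed one
    (with the +1 continuity correction); BH adjustment is applied across
    regulons within each GRN. ``rank = 1`` marks the most specific regulon.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives p-value resolution {1.0 / n_perm:.3f}")
    rng = np.random.default_rng(seed)
    labels = partition.labels.reindex(activity.cell_ids).to_numpy()
    grns = partition.grn_names
    regs = activity.regulon_ids

    p_regs = {}
    for i, reg in enumerate(regs):
        a = np.nan_to_num(activity.values[i])
        tot = a.sum()
        p_regs[reg] = a / tot if tot > 0 else None

    observed = rss_table.set_index(["regulon", "grn"])["rss"]
    exceed = {key: 0 for key in observed.index}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        masks = {g: (perm == g).astype(float) for g in grns}
        for reg in regs:
            p = p_regs[reg]
            if p is None:
                continue
            for g in grns:
                r = _rss_one(p, masks[g])
                if r >= observed[(reg, g)] - 1e-12:
                    exceed[(reg, g)] += 1

    out = rss_table.copy()
    out["p"] = [
        (exceed[(r, g)] + 1) / (n_perm + 1) if np.isfinite(v) else np.nan
        for r, g, v in zip(out["regulon"], out["grn"], out["rss"])
    ]
    out["rank"] = out.groupby("grn")["rss"].rank(ascending=False, method="first")
    adj = np.full(len(out), np.nan)
    for g in grns:
        mask = (out["grn"] == g) & out["p"].notna()
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["p_adj"] = np.maximum(adj, out["p"])  # BH never below raw p
    out["top"] = out["rank"] <= top_n
    return out.sort_values(["grn", "rank"]).reset_index(drop=True)


def holdout_robustness(
    activity: ActivityMatrix, partition: GRNPartition, unit_labels: pd.Series,
    zclip: float = 2.0,
) -> pd.Series:
    """Leave-one-unit-out stability: recluster without each unit, ARI on the rest.

    ``unit_labels`` maps cell_id -> unit (e.g. patient). For each unit, its
    cells are removed, the remaining cells are re-clustered at the same k, and
    the ARI against the original partition restricted to the retained cells is
    reported. Units covering all cells are an error; empty units are skipped.
    """
    units = unit_labels.reindex(activity.cell_ids)
    uniq = [u for u in pd.unique(units.dropna())]
    if len(uniq) < 2:
        raise ValidationError("need >= 2 units for holdout robustness")
    X = activity.scaled(zclip).T
    k = partition.n_grns
    orig = partition.labels.reindex(activity.cell_ids).to_numpy()
    out = {}
    for u in uniq:
        keep = (units != u).to_numpy()
        if keep.sum() == 0:
            raise ValidationError(f"unit {u!r} contains all cells")
        if (~keep).sum() == 0:
            warnings.warn(f"unit {u!r} has no cells; skipped")
            continue
        if keep.sum() <= k:
            warnings.warn(f"unit {u!r} leaves too few cells; skipped")
            continue
        Z = linkage(X[keep], method="ward")
        sub_labels = fcluster(Z, t=k, criterion="maxclust")
        out[u] = adjusted_rand_index(orig[keep], sub_labels)
    return pd.Series(out, name="holdout_ari")


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def grn_marker_summary(
    expr: ExpressionMatrix,
    partition: GRNPartition,
    genes: list[str],
    module_sets: dict[str, list] | None = None,
    seed: int = 0,
) -> dict:
    """Per-GRN marker/antigen summary and gene-vs-module-score association.

    Returns ``{"table": per-(grn, gene) means with min-max scaled values,
    "scores": per-GRN mean module scores, "association": Pearson r and Lin CCC
    of each gene's scaled per-GRN means against each module score}``. A gene
    constant across GRNs scales to all-0 with a warning.
    """
    from .markers import lin_ccc  # local import: avoids a module cycle

    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"genes not in expression matrix: {missing[:10]}")
    labels = partition.labels.reindex(expr.cell_ids)
    if labels.isna().any():
        raise ValidationError("partition does not cover all cells in the matrix")
    grns = partition.grn_names
    gi = {g: expr.gene_index([g])[0] for g in genes}

    mean_rows = []
    for grn in grns:
        mask = (labels == grn).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"GRN {grn} has zero cells")
        for g in genes:
            mean_rows.append({"grn": grn, "gene": g,
                              "mean_lognorm": float(expr.values[gi[g], mask].mean())})
    table = pd.DataFrame(mean_rows)
    table["scaled"] = 0.0
    for g in genes:
        mask = table["gene"] == g
        v = table.loc[mask, "mean_lognorm"].to_numpy()
        if np.ptp(v) == 0:
            warnings.warn(f"gene {g} constant across GRNs; scaled values set to 0")
        table.loc[mask, "scaled"] = _minmax(v)

    scores = pd.DataFrame(index=grns)
    if module_sets:
        for name, gene_set in module_sets.items():
            ms = module_score(expr, gene_set, seed=seed)
            scores[name] = [float(ms[labels == grn].mean()) for grn in grns]

    assoc_rows = []
    for name in scores.columns:
        y = scores[name].to_numpy()
        for g in genes:
            x = table.loc[table["gene"] == g, "scaled"].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0 or len(grns) < 3:
                r = ccc = np.nan
            else:
                r = float(pearsonr(x, y).statistic)
                ccc = lin_ccc(x, y).estimate
            assoc_rows.append({"gene": g, "module": name, "pearson_r": r, "lin_ccc": ccc})
    return {"table": table, "scores": scores, "association": pd.DataFrame(assoc_rows)}


# ---------------------------------------------------------------------------
# model / results faces
# ---------------------------------------------------------------------------

class GRNStateModel:
    """GRN cell-state model over a regulon activity matrix.

    Parameters
    ----------
    activity : ActivityMatrix
        Regulons x cells AUC activities.
    zclip : float
        Clip bound for the z-scaled view used by the clustering.
    """

    def __init__(self, activity: ActivityMatrix, zclip: float = 2.0):
        self.activity = activity
        self.zclip = zclip

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, regulons, top_fraction: float = 0.05,
                        tie_seed: int = 0, zclip: float = 2.0) -> "GRNStateModel":
        from .activity import aucell_score
        return cls(aucell_score(expr, regulons, top_fraction, tie_seed), zclip=zclip)

    def fit(self, k_range=range(2, 16), n_resamples: int = 20,
            subsample_frac: float = 0.8, n_perm: int = 1000, top_n: int = 10,
            seed: int = 0) -> "GRNStateResults":
        dend = cluster_dendrogram(self.activity, zclip=self.zclip)
        part = select_cut_by_ari(self.activity, dend, k_range=k_range,
                                 n_resamples=n_resamples,
                                 subsample_frac=subsample_frac, seed=seed,
                                 zclip=self.zclip)
        rss = regulon_specificity(self.activity, part)
        ranked = assign_regulons(rss, self.activity, part, n_perm=n_perm,
                                 top_n=top_n, seed=seed)
        return GRNStateResults(self, part, ranked)


@dataclass
class GRNStateResults:
    """Fitted GRN partition with the ranked, significance-annotated RSS table."""

    model: GRNStateModel
    partition: GRNPartition
    rss: pd.DataFrame

    @property
    def n_grns(self) -> int:
        return self.partition.n_grns

    def top_regulons(self, grn: str, n: int = 10) -> pd.DataFrame:
        sub = self.rss[self.rss["grn"] == grn]
        return sub.nsmallest(n, "rank")[["regulon", "rss", "rank", "p", "p_adj"]]

    def holdout_robustness(self, unit_labels: pd.Series) -> pd.Series:
        return holdout_robustness(self.model.activity, self.partition, unit_labels,
                                  zclip=self.model.zclip)

    def summary(self) -> str:
        lines = [
            "GRN cell-state discovery",
            f"  cells: {self.model.activity.n_cells}   "
            f"regulons: {len(self.model.activity.regulon_ids)}",
            f"  selected k (GRNs): {self.n_grns}",
        ]
        if len(self.partition.ari_profile):
            prof = self.partition.ari_profile
            best = prof.loc[prof["mean_ari"].idxmax()]
            lines.append(f"  stability ARI at k={int(best['k'])}: "
                         f"{best['mean_ari']:.3f} (sd {best['sd_ari']:.3f})")
        sizes = self.partition.labels.value_counts()
        for grn in self.partition.grn_names:
            top = self.top_regulons(grn, 3)
            tops = ", ".join(f"{r.regulon} (RSS {r.rss:.2f})" for r in top.itertuples())
            lines.append(f"  {grn}: {sizes[grn]} cells; top regulons: {tops}")
        return "\n".join(lines)
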