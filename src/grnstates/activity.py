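"""Per-cell regulon activity and expression-derived scores.

``aucell_score`` is a rank-based recovery-curve AUC: for each cell, genes are
ranked by descending expression and a regulon's activity is the area under the
step curve of cumulative regulon-gene hits over the top fraction of the
ranking, normalized by the maximal attainable area. Being rank-based it is
invariant to any monotone transform of a cell's expression profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, RegulonSet, ValidationError

__all__ = ["ActivityMatrix", "aucell_score", "zscale_clip", "module_score", "diffuse_impute"]

logger = logging.getLogger("grnstates")


@dataclass
class ActivityMatrix:
    """Regulons x cells AUC activities in [0, 1] (NaN = regulon not scoreable)."""

    values: np.ndarray
    regulon_ids: list[str]
    cell_ids: list[str]
    params: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regulon_ids), len(self.cell_ids)):
            raise ValidationError("activity shape does not match id lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("activities must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def scaled(self, zclip: float = 2.0) -> np.ndarray:
        """Z-scored (per regulon, across cells) and clipped view; see zscale_clip."""
        return zscale_clip(self.values, zclip=zclip)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regulon_ids, columns=self.cell_ids)


def _rank_matrix(values: np.ndarray, tie_seed: int, tie_break: str) -> np.ndarray:
    """1-based rank of each gene within each cell, descending expression.

    Ties are broken by a seeded random permutation of genes (shared across
    cells) or, with ``tie_break='gene_id'``, by input gene order.
    """
    n_genes, n_cells = values.shape
    if tie_break == "seeded":
        tiebreak = np.random.default_rng(tie_seed).permutation(n_genes)
    elif tie_break == "gene_id":
        tiebreak = np.arange(n_genes)
    else:
        raise ValidationError(f"unknown tie_break {tie_break!r}")
    ranks = np.empty((n_genes, n_cells), dtype=np.int64)
    rr = np.arange(1, n_genes + 1)
    for j in range(n_cells):
        order = np.lexsort((tiebreak, -values[:, j]))
        ranks[order, j] = rr
    return ranks


def aucell_score(
    expr: ExpressionMatrix,
    regulons: RegulonSet,
    top_fraction: float = 0.05,
    tie_seed: int = 0,
    tie_break: str = "seeded",
) -> ActivityMatrix:
    """AUCell-style recovery-curve AUC of each regulon in each cell.

    With T = ceil(top_fraction * n_genes) and hits(r) = number of regulon genes
    at rank <= r, the raw AUC is sum_{r=1..T} hits(r) and the activity is the
    raw AUC divided by its maximum sum_{r=1..T} min(r, m) for m regulon genes
    present. Regulons with no gene in the matrix get NaN with a warning.
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError("top_fraction must be in (0, 1]")
    if expr.layer not in ("lognorm", "imputed", "counts"):
        raise ValidationError(f"unexpected layer {expr.layer!r}")
    n_genes = expr.n_genes
    T = math.ceil(top_fraction * n_genes)
    ranks = _rank_matrix(expr.values, tie_seed, tie_break)

    present = set(expr.gene_ids)
    if not any(g in present for r in regulons for g in r.genes()):
        raise ValidationError("no regulon gene is present in the expression matrix")

    acts = np.full((len(regulons), expr.n_cells), np.nan)
    for i, reg in enumerate(regulons):
        idx = expr.gene_index(sorted(reg.genes()))
        m = len(idx)
        if m == 0:
            logger.warning("regulon %s has no genes in the matrix; activity is missing", reg.tf)
            continue
        # area under the recovery curve: each hit at rank g contributes T-g+1
        contrib = np.clip(T - ranks[idx, :] + 1, 0, None)
        raw = contrib.sum(axis=0)
        mm = min(m, T)
        max_auc = mm * (mm + 1) // 2 + (T - mm) * mm
        acts[i] = raw / max_auc
    return ActivityMatrix(
        acts, regulons.tf_names, list(expr.cell_ids),
        params={"top_fraction": top_fraction, "tie_seed": tie_seed, "tie_break": tie_break},
    )


def zscale_clip(values: np.ndarray, zclip: float = 2.0) -> np.ndarray:
    """Per-row z-score across columns, clipped to [-zclip, +zclip].

    Rows with zero variance map to 0. Requires >= 2 columns (sd undefined
    otherwise). Uses population (1/n) moments.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] < 2:
        raise ValidationError("z-scaling needs at least 2 cells")
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return np.clip(z, -zclip, zclip)


def module_score(
    expr: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control gene-set score per cell.

    Genes are binned by their average expression across cells (equal-frequency
    bins on the rank of the average); the score is the mean expression of the
    set genes minus the mean of a seeded random control pool drawn from the
    same bins (``n_ctrl`` controls per set gene, with replacement). Centered
    near 0 under exchangeability.
    """
    genes = [g for g in gene_set]
    idx = expr.gene_index(genes)
    if len(idx) == 0:
        raise ValidationError(f"no gene of the set is present: {sorted(genes)[:10]}")
    if n_bins > expr.n_genes:
        raise ValidationError("n_bins exceeds the number of genes")
    rng = np.random.default_rng(seed)

    avg = expr.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(expr.n_genes, dtype=int)
    bin_of[order] = np.arange(expr.n_genes) * n_bins // expr.n_genes

    ctrl_idx = []
    members = {b: np.where(bin_of == b)[0] for b in np.unique(bin_of)}
    for gi in idx:
        pool = members[bin_of[gi]]
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)

    score = expr.values[idx].mean(axis=0) - expr.values[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=expr.cell_ids, name="module_score")


def diffuse_impute(
    expr: ExpressionMatrix, k: int = 20, t: int = 1, n_pcs: int = 20
) -> ExpressionMatrix:
    """MAGIC-style diffusion imputation: X_imputed = X @ M^t.

    M is a row-stochastic Markov matrix over cells built from a k-nearest-
    neighbour graph in PCA space: adaptive Gaussian kernel with per-cell
    bandwidth equal to the distance to the ceil(k/3)-th neighbour (self
    affinity 1), symmetrized by the mean, then row-normalized. ``t=0`` returns
    the input unchanged.
    """
    if t < 0:
        raise ValidationError("t must be >= 0")
    if k >= expr.n_cells:
        raise ValidationError(f"k = {k} must be < n_cells = {expr.n_cells}")
    if t == 0:
        return ExpressionMatrix(expr.values.copy(), list(expr.gene_ids),
                                list(expr.cell_ids), layer="imputed")

    X = expr.values.T  # cells x genes
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        pcs = np.zeros((X.shape[0], 1))
    else:
        pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, ind = nn.kneighbors(pcs)  # first neighbour is self (distance 0)
    dist, ind = dist[:, 1:], ind[:, 1:]
    bw = dist[:, math.ceil(k / 3) - 1].copy()
    bw[bw == 0] = 1.0  # duplicate cells: any bandwidth; distances are 0 anyway

    n = expr.n_cells
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, ind.ravel()] = np.exp(-((dist / bw[:, None]) ** 2)).ravel()
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2.0
    M = W / W.sum(axis=1, keepdims=True)
    Mt = np.linalg.matrix_power(M, t)
    vals = expr.values @ Mt.T  # mix cells along columns
    return ExpressionMatrix(np.clip(vals, 0, None), list(expr.gene_ids),
                            list(expr.cell_ids), layer="imputed")
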