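"""Concordance, group-comparison and differential-expression statistics.

Covers Lin's concordance correlation coefficient (agreement with the identity
line, penalizing location and scale shifts) with Fisher-z confidence
intervals, Wilcoxon tests with the star-tier annotation convention, a two-part
(hurdle) differential-expression model for sparse single-cell data,
Benjamini-Hochberg control, hypergeometric overlap tests and the cross-cohort
shared-DEG comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .heterogeneity import significance_tier
from .io import ExpressionMatrix, ValidationError

__all__ = [
    "ConcordanceResult",
    "lin_ccc",
    "pearson_corr",
    "wilcoxon_test",
    "hurdle_de",
    "benjamini_hochberg",
    "OverlapResult",
    "overlap_fisher",
    "cross_cohort_compare",
]


@dataclass
class ConcordanceResult:
    statistic: str  # "lin_ccc" or "pearson"
    estimate: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not -1 <= self.estimate <= 1:
            raise ValidationError("estimate must lie in [-1, 1]")


def _fisher_ci(est: float, se_z: float) -> tuple[float, float]:
    z = np.arctanh(np.clip(est, -1 + 1e-15, 1 - 1e-15))
    lo, hi = z - 1.959963984540054 * se_z, z + 1.959963984540054 * se_z
    return float(np.tanh(lo)), float(np.tanh(hi))


def lin_ccc(x, y, ci_method: str = "fisher_z", n_boot: int = 2000, seed: int = 0) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with a 95% CI.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population (1/n)
    moments. The default CI applies Lin's asymptotic variance on the Fisher
    z-transformed scale; ``ci_method='bootstrap'`` uses a seeded percentile
    bootstrap instead (preferable at small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValidationError("x and y must be equal-length with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    sx2, sy2 = x.var(), y.var()  # population moments
    if sx2 == 0 and sy2 == 0:
        raise ValidationError("CCC undefined: both inputs have zero variance")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    shift = (x.mean() - y.mean()) ** 2
    ccc = 2 * sxy / (sx2 + sy2 + shift)

    if ci_method == "fisher_z":
        if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1:
            lo, hi = ccc, ccc
        else:
            r = sxy / np.sqrt(sx2 * sy2)
            r = r if abs(r) > 1e-15 else 1e-15
            u2 = shift / np.sqrt(sx2 * sy2)  # Lin's u^2 location-shift term
            c2 = ccc ** 2
            # Lin's asymptotic variance of the z-transformed CCC
            var_z = (
                (1 - r ** 2) * c2 / ((1 - c2) * r ** 2)
                + 4 * ccc ** 3 * (1 - ccc) * u2 / (r * (1 - c2) ** 2)
                - 2 * ccc ** 4 * u2 ** 2 / (r ** 2 * (1 - c2) ** 2)
            ) / (n - 2)
            var_z = max(var_z, 0.0)
            lo, hi = _fisher_ci(ccc, np.sqrt(var_z))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            denom = xb.var() + yb.var() + (xb.mean() - yb.mean()) ** 2
            if denom > 0:
                reps.append(2 * ((xb - xb.mean()) * (yb - yb.mean())).mean() / denom)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return ConcordanceResult("lin_ccc", float(np.clip(ccc, -1, 1)),
                             float(min(lo, ccc)), float(max(hi, ccc)), n)


def pearson_corr(x, y) -> ConcordanceResult:
    """Product-moment correlation with the standard Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValidationError("x and y must be equal-length with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValidationError("Pearson correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = _fisher_ci(r, 1.0 / np.sqrt(n - 3)) if n > 3 else (-1.0, 1.0)
    return ConcordanceResult("pearson", r, min(lo, r), max(hi, r), n)


def wilcoxon_test(x, y, paired: bool = False) -> tuple[float, float, str]:
    """Two-sided Wilcoxon comparison with the star-tier annotation.

    Unpaired inputs use the rank-sum (Mann-Whitney) test, exact for small
    tie-free samples (n_x + n_y <= 12) and normal-approximated with tie
    correction otherwise; paired inputs use the signed-rank test. Returns
    (statistic, p, tier); all-zero paired differences give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValidationError("paired test needs equal-length inputs")
        if np.all(x == y):
            return 0.0, 1.0, "ns"
        mode = "exact" if len(x) <= 15 and len(np.unique(np.abs(x - y)[x != y])) == np.sum(x != y) else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", mode=mode)
    else:
        if len(x) == 0 or len(y) == 0:
            raise ValidationError("both samples must be nonempty")
        small = len(x) + len(y) <= 12
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if small and no_ties else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, significance_tier(p)


def _binomial_lr(detected: np.ndarray, group: np.ndarray) -> tuple[float, int]:
    """G-statistic (LR chi-square, df=1) for a group effect on detection."""
    lr, df = 0.0, 0
    n = len(detected)
    k = detected.sum()
    if k == 0 or k == n:
        return 0.0, 0  # detection constant overall: part inestimable
    p0 = k / n

    def ll(kk, nn, p):
        if nn == 0:
            return 0.0
        eps = 1e-300
        return kk * np.log(p + eps) + (nn - kk) * np.log(1 - p + eps)

    ll0 = ll(k, n, p0)
    ll1 = 0.0
    for g in (0, 1):
        mask = group == g
        kk, nn = detected[mask].sum(), mask.sum()
        ll1 += ll(kk, nn, kk / nn if nn else 0.0)
    lr = 2 * (ll1 - ll0)
    return max(lr, 0.0), 1


def _gaussian_lr(values: np.ndarray, group: np.ndarray) -> tuple[float, int]:
    """LR chi-square (df=1) for a group mean effect, Gaussian working model."""
    n = len(values)
    if n < 3 or len(np.unique(group)) < 2:
        return 0.0, 0
    rss0 = np.sum((values - values.mean()) ** 2)
    rss1 = 0.0
    for g in (0, 1):
        v = values[group == g]
        rss1 += np.sum((v - v.mean()) ** 2)
    if rss1 <= 0 or rss0 <= 0:
        return 0.0, 0
    return max(n * np.log(rss0 / rss1), 0.0), 1


def hurdle_de(
    expr: ExpressionMatrix, cells_a, cells_b, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Two-part (hurdle) differential expression between two cell groups.

    Per gene: a likelihood-ratio test of the group effect on the
    detected/undetected indicator (binomial part) plus a likelihood-ratio test
    on expression among detected cells (Gaussian working model on the
    log-normalized values); the combined chi-square is the sum of the two with
    summed degrees of freedom, inestimable parts dropped. log2FC is computed
    on the depth-normalized scale, log2((mean_A + eps) / (mean_B + eps)) with
    eps = ``pseudocount``, so it is always finite. BH adjustment across genes.
    Genes undetected in every cell of both groups are excluded with a note.
    """
    if expr.layer != "lognorm":
        raise ValidationError("hurdle_de expects the lognorm layer")
    pos = {c: i for i, c in enumerate(expr.cell_ids)}
    idx_a = np.array([pos[c] for c in cells_a], dtype=int)
    idx_b = np.array([pos[c] for c in cells_b], dtype=int)
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValidationError("both groups need >= 3 cells")
    X = expr.values[:, np.concatenate([idx_a, idx_b])]
    group = np.concatenate([np.ones(len(idx_a), dtype=int), np.zeros(len(idx_b), dtype=int)])
    norm = np.expm1(X)  # back to the depth-normalized scale

    rows = []
    n_dropped = 0
    for gi, gene in enumerate(expr.gene_ids):
        v = X[gi]
        det = (v > 0).astype(int)
        if det.sum() == 0:
            n_dropped += 1
            continue
        lr_d, df_d = _binomial_lr(det, group)
        vd = v[det == 1]
        gd = group[det == 1]
        lr_c, df_c = _gaussian_lr(vd, gd) if (gd == 1).any() and (gd == 0).any() else (0.0, 0)
        chi2, df = lr_d + lr_c, df_d + df_c
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        mean_a = norm[gi, group == 1].mean()
        mean_b = norm[gi, group == 0].mean()
        rows.append({
            "gene": gene,
            "log2FC": float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount))),
            "mean_A": float(mean_a), "mean_B": float(mean_b),
            "det_frac_A": float(det[group == 1].mean()),
            "det_frac_B": float(det[group == 0].mean()),
            "chi2": float(chi2), "df": int(df), "p": p,
        })
    if n_dropped:
        warnings.warn(f"{n_dropped} genes undetected in both groups were excluded")
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH-adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    odds_ratio: float
    p: float
    overlap_genes: list[str]


def overlap_fisher(set_a, set_b, universe) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test of two gene sets' overlap.

    p = P(X >= |A intersect B|) under the hypergeometric null of drawing |B|
    genes from the universe, |A| of which are marked.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    stray = (A | B) - U
    if stray:
        raise ValidationError(f"sets not contained in universe: {sorted(stray)[:10]}")
    k = len(A & B)
    table = [[k, len(A) - k], [len(B) - k, len(U) - len(A) - len(B) + k]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return OverlapResult(len(A), len(B), k, len(U), float(odds), float(p),
                         sorted(A & B))


def cross_cohort_compare(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    fc_threshold: float = 0.4,
    fdr: float = 0.05,
    universe=None,
    direction: str = "up",
) -> dict:
    """Shared differentially-expressed genes between two cohorts' contrasts.

    A gene is significant in a cohort when |log2FC| > ``fc_threshold``,
    p_adj < ``fdr`` and its sign matches ``direction`` ('up', 'down' or
    'both'); the shared set is the intersection, tested for enrichment with
    the hypergeometric tail over the common universe (default: genes scored
    in both cohorts).
    """
    g1, g2 = set(de1["gene"]), set(de2["gene"])
    common = g1 & g2
    if universe is None:
        universe = common
    universe = set(universe)
    if not universe:
        raise ValidationError("empty common gene universe")

    def sig(de: pd.DataFrame) -> set:
        fc = de["log2FC"]
        if direction == "up":
            keep = fc > fc_threshold
        elif direction == "down":
            keep = fc < -fc_threshold
        else:
            keep = fc.abs() > fc_threshold
        keep &= de["p_adj"] < fdr
        return set(de.loc[keep, "gene"]) & universe

    sig1, sig2 = sig(de1), sig(de2)
    overlap = overlap_fisher(sig1, sig2, universe)
    scatter = pd.merge(
        de1[["gene", "log2FC"]], de2[["gene", "log2FC"]],
        on="gene", suffixes=("_cohort1", "_cohort2"),
    )
    return {"sig_cohort1": sig1, "sig_cohort2": sig2, "shared": sig1 & sig2,
            "overlap": overlap, "scatter": scatter,
            "thresholds": {"fc": fc_threshold, "fdr": fdr, "direction": direction}}
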