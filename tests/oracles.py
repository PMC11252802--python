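"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: recovery curves are walked
rank by rank, pair counts enumerated pairwise, hypergeometric tails summed
term by term, and rank-test p-values obtained by exhaustive enumeration of
group assignments.
"""

import itertools
import math

import numpy as np


def aucell_bruteforce(expr_values, gene_ids, regulon_genes, top_fraction, tiebreak_perm):
    """Walk the per-cell ranking explicitly and integrate the recovery curve."""
    n_genes, n_cells = expr_values.shape
    T = math.ceil(top_fraction * n_genes)
    reg_idx = {i for i, gid in enumerate(gene_ids) if gid in set(regulon_genes)}
    m = len(reg_idx)
    if m == 0:
        return np.full(n_cells, np.nan)
    max_auc = sum(min(r, m) for r in range(1, T + 1))
    out = np.empty(n_cells)
    for j in range(n_cells):
        order = sorted(range(n_genes),
                       key=lambda i: (-expr_values[i, j], tiebreak_perm[i]))
        auc = 0
        hits = 0
        for r, gi in enumerate(order[:T], start=1):
            if gi in reg_idx:
                hits += 1
            auc += hits
        out[j] = auc / max_auc
    return out


def ari_pair_counting(a, b):
    """ARI from explicit enumeration of all item pairs."""
    a, b = list(a), list(b)
    n = len(a)
    both = a_only = b_only = neither = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            both += 1
        elif sa:
            a_only += 1
        elif sb:
            b_only += 1
        else:
            neither += 1
    total = both + a_only + b_only + neither
    idx = both
    exp = (both + a_only) * (both + b_only) / total
    mx = ((both + a_only) + (both + b_only)) / 2
    if mx == exp:
        return 1.0
    return (idx - exp) / (mx - exp)


def fisher_enumeration(n_a, n_b, n_overlap, universe):
    """P(X >= n_overlap) by summing over all placements of the B set."""
    total = math.comb(universe, n_b)
    p = 0
    for k in range(n_overlap, min(n_a, n_b) + 1):
        p += math.comb(n_a, k) * math.comb(universe - n_a, n_b - k)
    return p / total


def wilcoxon_enumeration(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    exp = nx * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        s = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(s - exp) >= abs(obs - exp) - 1e-12:
            count += 1
    return count / total


def jsd_summation(p, q):
    """Base-2 Jensen-Shannon divergence by direct summation."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2
    def kl(a, b):
        mask = a > 0
        return np.sum(a[mask] * np.log2(a[mask] / b[mask]))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
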