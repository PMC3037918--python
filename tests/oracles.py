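"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles (sorting, enumeration,
exact rational arithmetic) and deliberately shares no code with the
package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def brute_rank_normalize(values):
    """Sort, assign average ranks to tied blocks, rescale to [0, 1]."""
    values = list(values)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of 1-based positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return [(r - 1.0) / (n - 1.0) for r in ranks]


def brute_gene_delta(matrix, disease_cols, normal_cols, gene):
    """Explicit per-sample ranking then group means, for one gene.

    `matrix` is a mapping gene -> {sample -> value} or a pandas DataFrame.
    """
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        matrix = {g: dict(matrix.loc[g]) for g in matrix.index}
    genes = sorted(matrix)
    cols = list(disease_cols) + list(normal_cols)
    normed = {}
    for s in cols:
        col = [matrix[g][s] for g in genes]
        rho = brute_rank_normalize(col)
        for g, r in zip(genes, rho):
            normed[(g, s)] = r
    mean_dz = sum(normed[(gene, s)] for s in disease_cols) / len(disease_cols)
    mean_nm = sum(normed[(gene, s)] for s in normal_cols) / len(normal_cols)
    return mean_dz - mean_nm


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by exact rational enumeration over the support.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs)
    return float(total)


def chi2_textbook(table):
    """Pearson chi-square from the textbook formula sum (O-E)^2 / E."""
    arr = np.asarray(table, dtype=float)
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    stat = float(((arr - expected) ** 2 / expected).sum())
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def _avg_ranks(pooled):
    return brute_rank_normalize(pooled)  # monotone relabelling; only order matters


def permutation_rank_sum_p(group_a, group_b):
    """Exhaustive two-sided permutation p for the rank-sum statistic.

    Enumerates every split of the pooled values into groups of the
    observed sizes and counts splits whose rank-sum deviates from its mean
    at least as much as the observed one.
    """
    a = list(group_a)
    b = list(group_b)
    pooled = a + b
    n1, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled, method="average")
    mu = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mu) >= obs - 1e-9:
            count += 1
    return count / total


def permutation_kruskal_p(groups):
    """Exhaustive permutation p for the tie-corrected Kruskal-Wallis H."""
    sizes = [len(g) for g in groups]
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = stats.rankdata(pooled, method="average")

    def h_stat(assign):
        # assign: tuple of index tuples per group
        h = 0.0
        for idx in assign:
            r = sum(ranks[i] for i in idx)
            h += r * r / len(idx)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        ties = 1.0 - float((counts.astype(float) ** 3 - counts).sum()) / (n**3 - n)
        return h / ties

    def splits(indices, sizes):
        if len(sizes) == 1:
            yield (tuple(indices),)
            return
        for first in itertools.combinations(indices, sizes[0]):
            rest = [i for i in indices if i not in set(first)]
            for tail in splits(rest, sizes[1:]):
                yield (first,) + tail

    obs = h_stat(tuple(tuple(range(sum(sizes[:i]), sum(sizes[: i + 1]))) for i in range(len(sizes))))
    count = total = 0
    for assign in splits(list(range(n)), sizes):
        total += 1
        if h_stat(assign) >= obs - 1e-9:
            count += 1
    return count / total
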