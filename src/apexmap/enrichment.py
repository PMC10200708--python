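"""Rank-sum differential expression and hypergeometric overlap tests.

Marker/differential-expression testing between cell groups uses the
two-sided Wilcoxon (Mann-Whitney) rank-sum test per gene with Bonferroni
correction. The p-value is exact (full enumeration, tie-aware) when the
smaller group has at most ``EXACT_MAX`` cells and the enumeration stays
tractable, and comes from the tie-corrected normal approximation
otherwise. Gene-set overlaps are scored by fold enrichment and
hypergeometric p-values (one-sided tail, and a two-sided minimum-
likelihood construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io_qc import CountMatrix, percell_normalize

EXACT_MAX = 8
# full enumeration visits C(n1+n2, min) assignments; 8-vs-8 gives 12,870
_EXACT_MAX_COMBINATIONS = 20_000


def _use_exact(n1: int, n2: int) -> bool:
    from math import comb

    small = min(n1, n2)
    return small <= EXACT_MAX and comb(n1 + n2, small) <= _EXACT_MAX_COMBINATIONS


# ---------------------------------------------------------------------------
# cell selection
# ---------------------------------------------------------------------------

def select_expressing_cells(matrix: CountMatrix, gene_list) -> np.ndarray:
    """Barcodes of cells with a nonzero count for at least one listed gene."""
    rows = matrix.gene_index(list(gene_list))
    mask = np.asarray((matrix.counts[rows, :] > 0).sum(axis=0) > 0).ravel()
    return matrix.cells[mask]


def subsample_background(barcodes, n: int = 1000, seed: int = 0) -> np.ndarray:
    """Uniform subsample of barcodes without replacement, seeded."""
    barcodes = np.asarray(barcodes, dtype=object)
    if n > len(barcodes):
        raise ValueError(f"cannot draw {n} barcodes from {len(barcodes)}")
    rng = np.random.default_rng(seed)
    return barcodes[rng.choice(len(barcodes), size=n, replace=False)]


# ---------------------------------------------------------------------------
# rank-sum differential expression
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (handles ties).

    Enumerates every assignment of the pooled values to the two groups
    and counts assignments whose U statistic is at least as far from its
    null mean as the observed one.
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    dev_obs = abs(u_obs - center)
    total = 0
    extreme = 0
    for comb in combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p for one gene; exact for small group sizes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if _use_exact(len(x), len(y)):
        return _exact_rank_sum_p(x, y)
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
    )


@dataclass
class DeResult:
    """Per-gene DE table with Bonferroni-adjusted p-values."""

    table: pd.DataFrame
    n_tested: int


def rank_sum_de(
    matrix: CountMatrix,
    group_a,
    group_b,
    normalize: bool = True,
    normalize_target: float = 1e4,
    pseudocount: float = 0.5,
) -> DeResult:
    """Wilcoxon rank-sum DE of group A vs group B over every gene.

    ``group_a``/``group_b`` are disjoint barcode collections. Expression
    is per-cell normalized (target total ``normalize_target``) unless
    ``normalize`` is False. No fold-change or expression floor is applied;
    the Bonferroni factor is the number of genes tested.
    """
    a = np.asarray(list(group_a), dtype=object)
    b = np.asarray(list(group_b), dtype=object)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if set(a) & set(b):
        raise ValueError("groups overlap")
    cell_pos = {c: i for i, c in enumerate(matrix.cells)}
    ia = np.array([cell_pos[c] for c in a])
    ib = np.array([cell_pos[c] for c in b])
    if normalize:
        expr, _ = percell_normalize(matrix, target=normalize_target)
    else:
        expr = matrix.counts
    dense = np.asarray(expr.todense()) if sp.issparse(expr) else np.asarray(expr)
    xa, xb = dense[:, ia], dense[:, ib]
    m = matrix.n_genes
    if _use_exact(len(ia), len(ib)):
        pvals = np.array([_exact_rank_sum_p(xa[g], xb[g]) for g in range(m)])
    else:
        pvals = scipy.stats.mannwhitneyu(
            xa, xb, axis=1, alternative="two-sided", method="asymptotic"
        ).pvalue
        # a gene identical across both groups is uninformative: p = 1
        const = np.all(dense[:, np.concatenate([ia, ib])] ==
                       dense[:, [ia[0]]], axis=1)
        pvals = np.where(const, 1.0, pvals)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": matrix.genes,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount),
            "pvalue": pvals,
            "p_bonf": np.minimum(pvals * m, 1.0),
        }
    ).set_index("gene_id", drop=False)
    return DeResult(table=table, n_tested=m)


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Fold enrichment and hypergeometric p-values of a set overlap."""

    universe: int
    size_a: int
    size_b: int
    overlap: int
    fold: float
    p_one_sided: float
    p_two_sided: float


def hypergeometric_overlap(
    universe: int, size_a: int, size_b: int, overlap: int,
    two_sided_method: str = "minlike",
) -> OverlapResult:
    """Overlap of two gene/cell sets drawn from a common universe.

    Fold enrichment is ``overlap / (size_a * size_b / universe)``. The
    one-sided p is P(X >= overlap) for X ~ Hypergeom(universe, size_a,
    size_b); the two-sided p sums the probabilities of all outcomes no
    more likely than the observed one (``minlike``) or doubles the
    smaller tail (``double``), capped at 1.
    """
    if not (0 <= overlap <= min(size_a, size_b) <= universe):
        raise ValueError("inconsistent set sizes")
    if max(size_a, size_b) > universe:
        raise ValueError("set larger than universe")
    expected = size_a * size_b / universe
    fold = overlap / expected if expected > 0 else np.nan
    dist = scipy.stats.hypergeom(universe, size_a, size_b)
    p_one = float(dist.sf(overlap - 1))
    support = np.arange(max(0, size_a + size_b - universe), min(size_a, size_b) + 1)
    pmf = dist.pmf(support)
    if two_sided_method == "minlike":
        p_two = float(pmf[pmf <= pmf[support == overlap][0] * (1 + 1e-7)].sum())
    elif two_sided_method == "double":
        p_two = float(2 * min(dist.cdf(overlap), dist.sf(overlap - 1)))
    else:
        raise ValueError("two_sided_method must be 'minlike' or 'double'")
    return OverlapResult(
        universe=universe, size_a=size_a, size_b=size_b, overlap=overlap,
        fold=fold, p_one_sided=p_one, p_two_sided=min(p_two, 1.0),
    )


def category_enrichment(
    categories: pd.Series | np.ndarray,
    subset_mask: np.ndarray,
    two_sided_method: str = "minlike",
) -> pd.DataFrame:
    """Identity-category enrichment of a cell subset vs all cells.

    For each category, A = the subset, B = cells of that category, N =
    all cells; reports overlap, fold enrichment and hypergeometric
    p-values per category.
    """
    cats = pd.Series(np.asarray(categories, dtype=object))
    mask = np.asarray(subset_mask, dtype=bool)
    if len(cats) != len(mask):
        raise ValueError("categories and mask lengths differ")
    if mask.sum() == 0:
        raise ValueError("empty subset")
    n = len(cats)
    rows = []
    for cat in sorted(cats.unique()):
        in_cat = (cats == cat).to_numpy()
        res = hypergeometric_overlap(
            n, int(mask.sum()), int(in_cat.sum()), int((mask & in_cat).sum()),
            two_sided_method=two_sided_method,
        )
        rows.append(
            {"category": cat, "n_subset": res.size_a, "n_category": res.size_b,
             "overlap": res.overlap, "fold": res.fold,
             "p_one_sided": res.p_one_sided, "p_two_sided": res.p_two_sided}
        )
    return pd.DataFrame(rows)
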