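"""Per-cell index of cell identity (ICI) with a permutation null.

For each cell and tissue, the ICI summarizes expression of that tissue's
positive marker genes weighted by their bulk specificity scores:

    ICI = (mean of e_g * s_g over the expressed markers)
          * (fraction of the tissue's markers expressed in the cell)

which, because unexpressed markers contribute nothing to the sum, equals
``sum(e_g * s_g) / n_markers``. Significance is assessed against a null
built by repeatedly drawing random gene sets of the same size, assigning
each drawn gene the specificity score it would have as a marker of the
tissue, and recomputing the ICI for every cell. Cells significant for
exactly one tissue take that identity; cells significant for both are
"mixed"; cells significant for neither are reported as "none" (optionally
collapsed into "mixed").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import CountMatrix, percell_normalize
from .markers import MarkerSet, TissueReference

CATEGORY_NONE = "none"
CATEGORY_MIXED = "mixed"

_FORMULAS = ("expressed_mean", "alternative")


@dataclass
class IciParams:
    """Knobs of the ICI computation.

    ``significance_percentile`` is the null percentile an experimental
    ICI must strictly exceed to be significant (95 declares the upper 5%
    tail significant, i.e. permutation p < 0.05). ``expression_source``
    selects raw counts or per-cell normalized expression (target
    ``normalize_target`` total per cell) as e_g. ``formula`` picks the
    reading of the ICI normalization: ``"expressed_mean"`` divides the
    weighted sum by the expressed-marker count before multiplying by the
    expressed fraction; ``"alternative"`` divides both factors by the
    total marker count. ``pooled_null`` pools null values across cells
    (per-cell nulls otherwise).
    """

    n_permutations: int = 1000
    significance_percentile: float = 95.0
    expression_source: str = "normalized"
    normalize_target: float = 1e4
    formula: str = "expressed_mean"
    pooled_null: bool = True
    merge_none_into_mixed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.significance_percentile < 100.0:
            raise ValueError("significance_percentile must be in (0, 100)")
        if self.expression_source not in ("normalized", "raw"):
            raise ValueError("expression_source must be 'normalized' or 'raw'")
        if self.formula not in _FORMULAS:
            raise ValueError(f"formula must be one of {_FORMULAS}")


@dataclass
class IciResult:
    """Per-cell ICI values, significance and identity categories.

    ``table`` has one row per cell (barcode, per-tissue ICI, permutation
    p, significance flags, category); ``nulls`` maps tissue -> null ICI
    array of shape (n_permutations, n_cells); ``category_counts`` gives
    per-subset category tallies.
    """

    table: pd.DataFrame
    nulls: dict[str, np.ndarray]
    thresholds: dict[str, np.ndarray]
    category_counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def _ici_from_parts(weighted_sum, n_expr, n_total, formula):
    """Combine the two ICI factors under the configured reading."""
    if formula == "expressed_mean":
        # (sum/n_expr) * (n_expr/n_total) simplifies; 0/0 -> 0 handled by sum=0
        return weighted_sum / n_total
    return (weighted_sum / n_total) * (n_expr / n_total)


def compute_ici(
    cell_expression: pd.Series,
    markers: MarkerSet,
    formula: str = "expressed_mean",
) -> float:
    """ICI of a single cell for one tissue's marker set.

    ``cell_expression`` is indexed by gene; markers absent from the index
    count as unexpressed. Returns 0 when no marker is expressed.
    """
    if len(markers) == 0:
        raise ValueError("empty marker set")
    if formula not in _FORMULAS:
        raise ValueError(f"formula must be one of {_FORMULAS}")
    e = cell_expression.reindex(markers.genes, fill_value=0.0).to_numpy(dtype=float)
    s = markers.specificity
    n_total = len(markers)
    n_expr = int(np.count_nonzero(e > 0))
    if n_expr == 0:
        return 0.0
    return float(_ici_from_parts(float((e * s).sum()), n_expr, n_total, formula))


def _expression_matrix(m: CountMatrix, params: IciParams) -> np.ndarray:
    if params.expression_source == "normalized":
        expr, _ = percell_normalize(m, target=params.normalize_target)
    else:
        expr = m.counts
    return np.asarray(expr.todense()) if sp.issparse(expr) else np.asarray(expr)


def ici_scores(
    expr: np.ndarray, gene_ids: np.ndarray, markers: MarkerSet,
    formula: str = "expressed_mean",
) -> np.ndarray:
    """Vectorized ICI over all cells of a dense genes x cells matrix."""
    if len(markers) == 0:
        raise ValueError("empty marker set")
    lookup = {g: i for i, g in enumerate(gene_ids)}
    rows = np.array([lookup[g] for g in markers.genes if g in lookup], dtype=int)
    s = np.array(
        [sv for g, sv in zip(markers.genes, markers.specificity) if g in lookup]
    )
    if rows.size == 0:
        return np.zeros(expr.shape[1])
    sub = expr[rows, :]
    weighted = s @ sub
    n_expr = np.count_nonzero(sub > 0, axis=0)
    return np.asarray(
        _ici_from_parts(weighted, n_expr, len(markers), formula)
    ).ravel()


def permutation_null(
    expr: np.ndarray,
    gene_ids: np.ndarray,
    marker_sizes: dict[str, int],
    s_lookup: dict[str, np.ndarray],
    params: IciParams,
) -> dict[str, np.ndarray]:
    """Null ICI distributions from random marker sets of matched size.

    For each permutation and tissue, a uniform random gene subset of the
    tissue's marker-set size is drawn from the matrix's gene universe;
    each drawn gene is weighted by ``s_lookup[tissue]`` (its specificity
    score for that tissue, 0 for genes without reference information) and
    the ICI of every cell is computed. Returns, per tissue, an array of
    shape (n_permutations, n_cells).
    """
    n_genes, n_cells = expr.shape
    for tissue, size in marker_sizes.items():
        if size > n_genes:
            raise ValueError(f"marker size for {tissue!r} exceeds gene universe")
        if size < 1:
            raise ValueError("marker sizes must be >= 1")
    rng = np.random.default_rng(params.seed)
    nulls = {
        t: np.empty((params.n_permutations, n_cells)) for t in marker_sizes
    }
    for p in range(params.n_permutations):
        for tissue, size in marker_sizes.items():
            idx = rng.choice(n_genes, size=size, replace=False)
            s = s_lookup[tissue][idx]
            sub = expr[idx, :]
            weighted = s @ sub
            n_expr = np.count_nonzero(sub > 0, axis=0)
            nulls[tissue][p, :] = _ici_from_parts(
                weighted, n_expr, size, params.formula
            )
    return nulls


def _null_thresholds(
    null: np.ndarray, percentile: float, pooled: bool
) -> np.ndarray:
    """Per-cell significance thresholds from a (n_perm, n_cells) null."""
    if pooled:
        thr = np.percentile(null.ravel(), percentile)
        return np.full(null.shape[1], thr)
    return np.percentile(null, percentile, axis=0)


def assign_identity(
    ici: dict[str, np.ndarray],
    nulls: dict[str, np.ndarray],
    params: IciParams,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Significance flags, permutation p-values and identity categories.

    A cell is significant for a tissue when its ICI lies strictly above
    the configured percentile of that tissue's null (pooled across cells
    by default). Categories: one significant tissue -> that tissue; both
    -> mixed; neither -> none (or mixed when configured).
    """
    tissues = list(ici)
    if len(tissues) != 2:
        raise ValueError("identity assignment expects exactly two tissues")
    n_cells = len(ici[tissues[0]])
    flags, pvals, thresholds = {}, {}, {}
    for t in tissues:
        thr = _null_thresholds(
            nulls[t], params.significance_percentile, params.pooled_null
        )
        thresholds[t] = thr
        flags[t] = ici[t] > thr
        pool = nulls[t].ravel() if params.pooled_null else nulls[t]
        if params.pooled_null:
            exceed = (pool[None, :] >= ici[t][:, None]).mean(axis=1)
        else:
            exceed = (nulls[t] >= ici[t][None, :]).mean(axis=0)
        pvals[t] = exceed
    t1, t2 = tissues
    category = np.where(
        flags[t1] & flags[t2], CATEGORY_MIXED,
        np.where(flags[t1], t1, np.where(flags[t2], t2, CATEGORY_NONE)),
    )
    if params.merge_none_into_mixed:
        category = np.where(category == CATEGORY_NONE, CATEGORY_MIXED, category)
    out = pd.DataFrame({f"ici_{t}": ici[t] for t in tissues})
    for t in tissues:
        out[f"p_{t}"] = pvals[t]
        out[f"significant_{t}"] = flags[t]
    out["category"] = category
    return out, thresholds


def category_counts(
    table: pd.DataFrame,
    subsets: dict[str, np.ndarray],
    categories: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Category tallies for named cell subsets (boolean masks over cells)."""
    if categories is None:
        categories = tuple(sorted(table["category"].unique()))
    rows = []
    for name, mask in subsets.items():
        sub = table.loc[np.asarray(mask, dtype=bool), "category"]
        row = {"subset": name, "n_cells": int(len(sub))}
        for c in categories:
            row[c] = int((sub == c).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def ici_pipeline(
    matrix: CountMatrix,
    markers: dict[str, MarkerSet],
    reference: TissueReference,
    params: IciParams | None = None,
    subsets: dict[str, dict] | None = None,
) -> IciResult:
    """Full ICI analysis: scores, permutation null, categories, tallies.

    ``subsets`` optionally names cell groups for the category breakdown,
    each given either as ``{"genes": [...]}`` (cells expressing at least
    one listed gene, on raw counts) or ``{"barcodes": [...]}``. The
    "all_cells" subset is always included.
    """
    params = params or IciParams()
    tissues = list(markers)
    for t in tissues:
        if len(markers[t]) == 0:
            raise ValueError(f"empty marker set for tissue {t!r}")
    expr = _expression_matrix(matrix, params)
    ici = {
        t: ici_scores(expr, matrix.genes, markers[t], params.formula)
        for t in tissues
    }
    s_lookup = {
        t: reference.specificity(t).reindex(matrix.genes, fill_value=0.0).to_numpy()
        for t in tissues
    }
    nulls = permutation_null(
        expr, matrix.genes, {t: len(markers[t]) for t in tissues}, s_lookup, params
    )
    table, thresholds = assign_identity(ici, nulls, params)
    table.insert(0, "barcode", matrix.cells)

    masks: dict[str, np.ndarray] = {"all_cells": np.ones(matrix.n_cells, dtype=bool)}
    for name, spec_ in (subsets or {}).items():
        if "genes" in spec_:
            rows = matrix.gene_index(spec_["genes"])
            mask = np.asarray(
                (matrix.counts[rows, :] > 0).sum(axis=0) > 0
            ).ravel()
        elif "barcodes" in spec_:
            wanted = set(spec_["barcodes"])
            mask = np.array([b in wanted for b in matrix.cells])
        else:
            raise ValueError(f"subset {name!r} needs 'genes' or 'barcodes'")
        masks[name] = mask
    counts = category_counts(table, masks)
    return IciResult(
        table=table, nulls=nulls, thresholds=thresholds, category_counts=counts
    )
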