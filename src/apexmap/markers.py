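"""Tissue marker selection from a two-tissue bulk reference.

Given replicate bulk RNA-seq counts for two tissues (here adaxial and
abaxial leaf domains), this module computes per-gene specificity scores,
runs a simple differential-expression test between the tissues, and
selects positive marker sets for downstream per-cell identity scoring.
Externally computed DE tables (e.g. from edgeR) are accepted verbatim
through :func:`select_markers`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_qc import cpm

logger = logging.getLogger(__name__)


@dataclass
class TissueReference:
    """Replicate-averaged CPM for two named tissues over one gene universe.

    ``cpm`` is a DataFrame indexed by gene_id with one column per tissue;
    ``replicate_counts`` optionally holds the underlying per-replicate raw
    counts (columns ``{tissue}_{replicate}``).
    """

    t1: str
    t2: str
    cpm: pd.DataFrame
    replicate_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for t in (self.t1, self.t2):
            if t not in self.cpm.columns:
                raise ValueError(f"tissue {t!r} missing from CPM table")
        if (self.cpm[[self.t1, self.t2]].to_numpy() < 0).any():
            raise ValueError("CPM values must be nonnegative")

    @property
    def genes(self) -> np.ndarray:
        return self.cpm.index.to_numpy()

    def specificity(self, tissue: str) -> pd.Series:
        """Per-gene specificity score for ``tissue`` vs the other tissue.

        Genes with zero CPM in both tissues get a score of 0 (they carry
        no identity information and are never selected as markers).
        """
        other = self.t2 if tissue == self.t1 else self.t1
        if tissue not in (self.t1, self.t2):
            raise ValueError(f"unknown tissue {tissue!r}")
        a = self.cpm[tissue].to_numpy(dtype=float)
        b = self.cpm[other].to_numpy(dtype=float)
        total = a + b
        s = np.zeros_like(a)
        nz = total > 0
        s[nz] = (a[nz] - b[nz]) / total[nz]
        return pd.Series(s, index=self.cpm.index, name=f"s_{tissue}")


@dataclass
class MarkerSet:
    """Positive marker genes for one tissue with their selection statistics."""

    tissue: str
    genes: np.ndarray
    specificity: np.ndarray
    log2fc: np.ndarray = field(default=None)  # type: ignore[assignment]
    fdr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.specificity = np.asarray(self.specificity, dtype=float)
        if len(self.genes) != len(self.specificity):
            raise ValueError("genes and specificity lengths differ")
        if np.any(self.specificity <= 0):
            raise ValueError("marker sets hold positive markers only (s_g > 0)")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.genes, "tissue": self.tissue,
                            "s_g": self.specificity})
        if self.log2fc is not None:
            out["log2fc"] = self.log2fc
        if self.fdr is not None:
            out["fdr"] = self.fdr
        return out


def specificity_score(cpm_t1, cpm_t2):
    """Bounded contrast (CPM_t1 - CPM_t2)/(CPM_t1 + CPM_t2) in [-1, 1].

    Antisymmetric in its arguments. Undefined (raises) when both CPM are
    zero: such a gene carries no information and cannot be a marker.
    """
    a = np.asarray(cpm_t1, dtype=float)
    b = np.asarray(cpm_t2, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("CPM values must be nonnegative")
    total = a + b
    if np.any(total <= 0):
        raise ValueError("specificity undefined when both CPM are zero")
    return (a - b) / total


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simple_bulk_de(
    counts_t1: pd.DataFrame,
    counts_t2: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene two-tissue differential expression on replicate bulk counts.

    Each replicate library is CPM-normalized; log2 fold change is the ratio
    of replicate-mean CPM (with ``pseudocount`` added to both means), and
    the p-value is a two-sided Welch t-test on log2(CPM + pseudocount)
    across replicates, BH-adjusted. Genes with zero variance in both
    tissues get p = 1 when the means agree and p = 0 otherwise.

    Rows of both frames must share the same gene index; columns are
    replicates (>= 2 per tissue).
    """
    if counts_t1.shape[1] < 2 or counts_t2.shape[1] < 2:
        raise ValueError("need at least 2 replicates per tissue")
    if not counts_t1.index.equals(counts_t2.index):
        raise ValueError("replicate tables must share the same gene index")
    cpm1 = np.column_stack([cpm(counts_t1[c].to_numpy()) for c in counts_t1])
    cpm2 = np.column_stack([cpm(counts_t2[c].to_numpy()) for c in counts_t2])
    log2fc = np.log2(cpm1.mean(axis=1) + pseudocount) - np.log2(
        cpm2.mean(axis=1) + pseudocount
    )
    x1 = np.log2(cpm1 + pseudocount)
    x2 = np.log2(cpm2 + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_ind(x1, x2, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    same_mean = np.isclose(x1.mean(axis=1), x2.mean(axis=1))
    p = np.where(degenerate & same_mean, 1.0, p)
    p = np.where(degenerate & ~same_mean, 0.0, p)
    return pd.DataFrame(
        {"gene_id": counts_t1.index, "log2fc": log2fc, "pvalue": p,
         "fdr": bh_adjust(p)}
    ).set_index("gene_id", drop=False)


def select_markers(
    ref: TissueReference,
    de_table: pd.DataFrame,
    log2fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> dict[str, MarkerSet]:
    """Select positive marker sets for each tissue from a DE table.

    ``de_table`` needs columns ``gene_id``, ``log2fc`` (positive = higher
    in ``ref.t1``), ``pvalue``; an ``fdr`` column is used if present and
    computed by BH adjustment otherwise. Selection uses a strict
    ``log2fc > log2fc_min`` threshold (symmetric for the second tissue)
    and ``fdr < fdr_max``. Selected genes absent from the reference are
    dropped with a warning; genes whose specificity sign disagrees with
    the DE direction are dropped as well, so each set only carries
    positive markers (s_g > 0 for its tissue).
    """
    de = de_table.copy()
    if "fdr" not in de.columns:
        de["fdr"] = bh_adjust(de["pvalue"].to_numpy())
    in_ref = de["gene_id"].isin(ref.cpm.index)
    if (~in_ref).any():
        logger.warning(
            "dropping %d DE genes absent from the CPM reference", (~in_ref).sum()
        )
        de = de[in_ref]
    sets: dict[str, MarkerSet] = {}
    for tissue, sign in ((ref.t1, 1.0), (ref.t2, -1.0)):
        sel = (sign * de["log2fc"].to_numpy() > log2fc_min) & (
            de["fdr"].to_numpy() < fdr_max
        )
        genes = de.loc[sel, "gene_id"].to_numpy()
        s = ref.specificity(tissue).loc[genes].to_numpy()
        pos = s > 0
        sets[tissue] = MarkerSet(
            tissue=tissue,
            genes=genes[pos],
            specificity=s[pos],
            log2fc=(sign * de.loc[sel, "log2fc"].to_numpy())[pos],
            fdr=de.loc[sel, "fdr"].to_numpy()[pos],
        )
    return sets
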