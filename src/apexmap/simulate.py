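"""Synthetic two-genotype shoot-apex experiment with known ground truth.

Emulates the statistical structure the downstream analyses assume:

* a two-tissue (adaxial/abaxial) bulk reference with replicate
  negative-binomial counts and planted fold-change markers,
* droplet-style single cells drawn NB from population profiles that are
  proportional to one tissue's CPM profile (or a blend, for
  mixed-identity populations),
* a two-genotype x two-replicate design in which selected populations
  can be depleted in one genotype by a deterministic factor,
* mitochondrial genes contributing a controlled per-cell count fraction,
* latent 3-D embedding coordinates (population centroid + Gaussian
  noise) standing in for a transcriptional embedding.

Everything is driven by a single integer seed; fixed seeds give
bit-identical matrices, coordinates and ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_qc import (
    METADATA_FILE,
    TRUTH_FILE,
    CountMatrix,
    cpm,
    write_matrix,
)
from .markers import TissueReference

ADAXIAL = "adaxial"
ABAXIAL = "abaxial"
MIXED = "mixed"
IDENTITIES = (ADAXIAL, ABAXIAL, MIXED)


@dataclass
class PopulationSpec:
    """One simulated cell population.

    ``n_cells`` is the baseline number of cells per (sample, replicate);
    per-sample counts are scaled by ``depletion`` (factor in [0, 1],
    defaulting to 1 for samples not listed) and rounded, so expected
    abundances are exact by construction. ``blend`` is the adaxial weight
    of the expression profile for mixed-identity populations.
    """

    name: str
    identity: str
    cluster: int
    n_cells: int = 150
    depletion: dict[str, float] = field(default_factory=dict)
    blend: float = 0.5

    def __post_init__(self) -> None:
        if self.identity not in IDENTITIES:
            raise ValueError(f"unknown identity {self.identity!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for s, d in self.depletion.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"depletion factor for {s!r} outside [0, 1]")
        if not 0.0 <= self.blend <= 1.0:
            raise ValueError("blend must be in [0, 1]")

    def factor(self, sample: str) -> float:
        return self.depletion.get(sample, 1.0)


def _default_populations() -> list[PopulationSpec]:
    return [
        PopulationSpec("adaxial_epidermis", ADAXIAL, cluster=0),
        PopulationSpec("abaxial_epidermis", ABAXIAL, cluster=1),
        PopulationSpec("rim", MIXED, cluster=2),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe a modest desk-scale experiment: 2,000 genes of
    which 200 per tissue are planted markers with a log2 fold difference
    of ``marker_effect`` between the two bulk tissues, two genotype
    samples ("wt", "mut") x two replicates, NB counts with a shared
    dispersion, and sub-threshold mitochondrial fractions.
    """

    n_genes: int = 2000
    n_markers_per_tissue: int = 300
    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    samples: tuple[str, ...] = ("wt", "mut")
    n_replicates: int = 2
    n_bulk_replicates: int = 4
    nb_dispersion: float = 0.1
    marker_effect: float = 3.0
    mito_gene_count: int = 10
    mito_fraction_range: tuple[float, float] = (0.002, 0.008)
    embedding_noise_sd: float = 0.6
    mean_library_size: float = 5000.0
    library_size_sigma: float = 0.3
    bulk_library_size: int = 2_000_000
    mito_prefix: str = "MT-"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_markers_per_tissue, self.n_replicates,
               self.n_bulk_replicates, self.mito_gene_count) < 1:
            raise ValueError("counts must be >= 1")
        if 2 * self.n_markers_per_tissue > self.n_genes - self.mito_gene_count:
            raise ValueError("more planted markers than available genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be >= 0")
        lo, hi = self.mito_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("mito_fraction_range must be within [0, 1]")
        if self.embedding_noise_sd <= 0:
            raise ValueError("embedding_noise_sd must be positive")
        if len(self.populations) == 0:
            raise ValueError("need at least one population")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What was actually simulated.

    ``cells`` maps every barcode to its true identity and population;
    ``abundance`` gives the deterministic per-population, per-sample,
    per-replicate cell counts; ``markers`` lists the planted marker genes
    per tissue.
    """

    cells: pd.DataFrame
    abundance: pd.DataFrame
    markers: dict[str, np.ndarray]


def _gene_ids(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    n_nuc = cfg.n_genes - cfg.mito_gene_count
    ids = np.array(
        [f"GENE{i:05d}" for i in range(n_nuc)]
        + [f"{cfg.mito_prefix}{i:03d}" for i in range(cfg.mito_gene_count)],
        dtype=object,
    )
    is_mito = np.zeros(cfg.n_genes, dtype=bool)
    is_mito[n_nuc:] = True
    return ids, is_mito


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB counts with mean ``mean`` and variance mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = size / (size + np.maximum(mean, 1e-300))
    out = np.zeros(mean.shape, dtype=np.int64)
    nz = mean > 0
    out[nz] = rng.negative_binomial(size, p[nz])
    return out


def _tissue_means(cfg: SimConfig, rng: np.random.Generator):
    """Expected bulk expression per tissue, with planted marker effects."""
    base = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    n_nuc = cfg.n_genes - cfg.mito_gene_count
    marker_pool = rng.permutation(n_nuc)
    adax = marker_pool[: cfg.n_markers_per_tissue]
    abax = marker_pool[cfg.n_markers_per_tissue : 2 * cfg.n_markers_per_tissue]
    half = np.sqrt(2.0 ** cfg.marker_effect)
    mean_ad = base.copy()
    mean_ab = base.copy()
    mean_ad[adax] *= half
    mean_ab[adax] /= half
    mean_ad[abax] /= half
    mean_ab[abax] *= half
    return mean_ad, mean_ab, adax, abax


def generate_bulk_reference(
    cfg: SimConfig,
) -> tuple[TissueReference, dict[str, np.ndarray]]:
    """Simulate the two-tissue bulk reference with replicate NB counts.

    Planted adaxial markers have expected expression 2**marker_effect-fold
    higher in the adaxial tissue (symmetrically for abaxial markers); all
    other genes are exchangeable between tissues. Returns the reference
    (replicate counts attached) and the planted marker gene IDs per tissue.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids, _ = _gene_ids(cfg)
    mean_ad, mean_ab, adax_idx, abax_idx = _tissue_means(cfg, rng)

    reps = {}
    for tissue, mean in ((ADAXIAL, mean_ad), (ABAXIAL, mean_ab)):
        scale = cfg.bulk_library_size / mean.sum()
        for r in range(1, cfg.n_bulk_replicates + 1):
            reps[f"{tissue}_{r}"] = _nb_draw(rng, mean * scale, cfg.nb_dispersion)
    rep_counts = pd.DataFrame(reps, index=pd.Index(gene_ids, name="gene_id"))

    cpm_cols = {}
    for tissue in (ADAXIAL, ABAXIAL):
        cols = [c for c in rep_counts.columns if c.startswith(tissue)]
        cpm_cols[tissue] = np.column_stack(
            [cpm(rep_counts[c].to_numpy()) for c in cols]
        ).mean(axis=1)
    ref = TissueReference(
        t1=ADAXIAL,
        t2=ABAXIAL,
        cpm=pd.DataFrame(cpm_cols, index=rep_counts.index),
        replicate_counts=rep_counts,
    )
    planted = {ADAXIAL: gene_ids[adax_idx], ABAXIAL: gene_ids[abax_idx]}
    return ref, planted


def _population_profile(
    cfg: SimConfig, pop: PopulationSpec, ref: TissueReference, is_mito: np.ndarray
) -> np.ndarray:
    """Relative expression profile (sums to 1 over non-mito genes)."""
    ad = ref.cpm[ADAXIAL].to_numpy(dtype=float)
    ab = ref.cpm[ABAXIAL].to_numpy(dtype=float)
    ad = ad / ad.sum()
    ab = ab / ab.sum()
    if pop.identity == ADAXIAL:
        prof = ad
    elif pop.identity == ABAXIAL:
        prof = ab
    else:
        prof = pop.blend * ad + (1.0 - pop.blend) * ab
    prof = prof.copy()
    prof[is_mito] = 0.0
    return prof / prof.sum()


def _centroids(n: int, radius: float = 6.0) -> np.ndarray:
    """Deterministic, well-separated 3-D points (golden-spiral on a sphere)."""
    i = np.arange(n, dtype=float)
    if n == 1:
        return np.zeros((1, 3))
    z = 1.0 - 2.0 * i / (n - 1) if n > 1 else np.zeros(1)
    z = np.clip(z, -1.0, 1.0)
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def expected_abundance(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic cell counts per (population, sample, replicate)."""
    rows = []
    for pop in cfg.populations:
        for sample in cfg.samples:
            n = int(round(pop.n_cells * pop.factor(sample)))
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {"population": pop.name, "sample": sample,
                     "replicate": rep, "n_cells": n}
                )
    return pd.DataFrame(rows)


def simulate_cells(
    cfg: SimConfig, ref: TissueReference
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw single cells from population profiles derived from the reference.

    Returns the gene x cell count matrix, the per-cell metadata table
    (barcode, sample, replicate, cluster, emb1..emb3) and the ground
    truth. Population sizes per sample are deterministic rounded products
    ``n_cells * depletion_factor``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    gene_ids, is_mito = _gene_ids(cfg)
    if not np.array_equal(gene_ids, ref.cpm.index.to_numpy()):
        raise ValueError("reference was generated with a different gene universe")

    abundance = expected_abundance(cfg)
    centroids = _centroids(len(cfg.populations))
    profiles = {
        pop.name: _population_profile(cfg, pop, ref, is_mito)
        for pop in cfg.populations
    }
    pop_by_name = {pop.name: pop for pop in cfg.populations}

    blocks, meta_rows, truth_rows = [], [], []
    counter = 0
    lo, hi = cfg.mito_fraction_range
    n_mito = int(is_mito.sum())
    for _, row in abundance.iterrows():
        pop = pop_by_name[row["population"]]
        n = int(row["n_cells"])
        if n == 0:
            continue
        prof = profiles[pop.name]
        libs = rng.lognormal(
            mean=np.log(cfg.mean_library_size), sigma=cfg.library_size_sigma, size=n
        )
        mito_frac = rng.uniform(lo, hi, size=n)
        # genes x cells mean matrix for this block
        mean = prof[:, None] * (libs * (1.0 - mito_frac))[None, :]
        mean[is_mito, :] = (libs * mito_frac)[None, :] / n_mito
        blocks.append(_nb_draw(rng, mean, cfg.nb_dispersion))
        centroid = centroids[list(pop_by_name).index(pop.name)]
        coords = centroid[None, :] + rng.normal(0.0, cfg.embedding_noise_sd, (n, 3))
        for i in range(n):
            barcode = f"CELL{counter:06d}"
            counter += 1
            meta_rows.append(
                {"barcode": barcode, "sample": row["sample"],
                 "replicate": int(row["replicate"]), "cluster": pop.cluster,
                 "emb1": coords[i, 0], "emb2": coords[i, 1], "emb3": coords[i, 2]}
            )
            truth_rows.append(
                {"barcode": barcode, "identity": pop.identity,
                 "population": pop.name, "cluster": pop.cluster}
            )

    import scipy.sparse as sp

    counts = sp.csr_matrix(np.concatenate(blocks, axis=1)) if blocks else sp.csr_matrix(
        (cfg.n_genes, 0), dtype=np.int64
    )
    meta = pd.DataFrame(meta_rows)
    matrix = CountMatrix(
        gene_ids, meta["barcode"].to_numpy(), counts, gene_names=gene_ids
    )
    truth = GroundTruth(
        cells=pd.DataFrame(truth_rows), abundance=abundance, markers={}
    )
    return matrix, meta, truth


def simulate_experiment(cfg: SimConfig):
    """Bulk reference + single cells in one call.

    Returns ``(reference, matrix, metadata, truth)`` with the planted
    bulk markers recorded in ``truth.markers``.
    """
    ref, planted = generate_bulk_reference(cfg)
    matrix, meta, truth = simulate_cells(cfg, ref)
    truth.markers = planted
    return ref, matrix, meta, truth


def write_fixture(
    matrix: CountMatrix,
    table: pd.DataFrame,
    truth: GroundTruth | None,
    out_dir: str | os.PathLike,
) -> None:
    """Write the matrix directory plus metadata and ground-truth sidecars."""
    if len(table) != matrix.n_cells:
        raise ValueError("metadata table and matrix disagree on cell count")
    write_matrix(matrix, out_dir)
    table.to_csv(os.path.join(out_dir, METADATA_FILE), sep="\t", index=False)
    if truth is not None:
        truth.cells.to_csv(os.path.join(out_dir, TRUTH_FILE), sep="\t", index=False)
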