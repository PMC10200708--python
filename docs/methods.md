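# Methods

This note documents the models and procedures implemented in `apexmap`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Setting

The package targets a two-part analysis of droplet scRNA-seq data from
two genotype samples (two replicates each), interpreted against a bulk
RNA-seq reference of two opposing tissue identities (called *adaxial*
and *abaxial* throughout, after the top/bottom domains of a leaf
primordium, though nothing in the code is specific to that system):

1. per-cell tissue-identity classification (ICI scoring), and
2. detection of genotype-depleted or -enriched cell states
   (sample-associated relative likelihood).

Supporting stages — matrix I/O, barcode QC, marker selection, rank-sum
differential expression and hypergeometric overlap tests — surround the
two core analyses. Read alignment, normalization-model fitting
(sctransform), clustering and embedding computation are out of scope:
cluster labels and embedding coordinates are inputs.

## Quality control

A cell barcode is removed when it has *fewer than* `min_genes_detected`
genes with nonzero counts (default 3,000), *more than* `max_umi` total
transcripts (default 100,000), or a mitochondrial UMI fraction *strictly
greater than* `max_mito_fraction` (default 0.01). All three comparisons
are strict, so boundary cells (exactly 3,000 genes, exactly 100,000
UMIs, exactly 1% mito) are retained. Mitochondrial genes are recognized
by gene-name prefix (default `MT-`), and mito fractions are computed on
raw counts before any gene filtering. The defaults describe a deeply
sequenced plant-protoplast experiment; on the 2,000-gene synthetic data
the gene floor must be scaled down (the shipped demo config uses 200).

The "1% mitochondrial" rule is implemented as a fraction of UMIs (not of
reads); read-level information is not available downstream of a count
matrix.

## Marker selection

The per-gene specificity score

    s_g = (CPM_t1 − CPM_t2) / (CPM_t1 + CPM_t2)

is a bounded, antisymmetric contrast of replicate-averaged bulk CPM.
Markers are genes with log2 fold change strictly greater than 2
(symmetric for the second tissue) at Benjamini–Hochberg FDR < 0.05.
The DE table may come from any external tool (edgeR output is the
expected use); the built-in `simple_bulk_de` is a deliberately plain
stand-in — per-replicate CPM, log2 ratio of replicate means with a 0.5
pseudocount, and a two-sided Welch t-test on log2(CPM + 0.5) — chosen so
the pipeline is self-contained without reproducing any particular DE
framework's internals. Genes selected by the DE table but absent from
the CPM reference, or whose specificity sign disagrees with the DE
direction, are dropped, so each tissue's marker set carries positive
markers only (s_g > 0).

## Index of cell identity

For a cell with expression e_g and a tissue's marker set M:

    ICI = (mean of e_g·s_g over expressed markers) × (|expressed| / |M|)

The printed form of this statistic in the literature is ambiguous about
its normalizers; the reading above multiplies the mean weighted
expression over *expressed* markers by the *fraction of markers
expressed*, which algebraically reduces to Σ e_g·s_g / |M| because
unexpressed markers contribute zero to the sum. An alternative reading
that divides both factors by |M| (and therefore penalizes dropout
quadratically) is available via `IciParams(formula="alternative")`.
ICI = 0 when no marker is expressed; e_g defaults to per-cell
library-size-normalized expression (target 10⁴, no log), with raw
counts available by config.

**Null and significance.** For each of `n_permutations` (default 1,000)
rounds, a uniform random gene set of size |M| is drawn per tissue from
the matrix's gene universe; each drawn gene is weighted by the
specificity score it would have as a marker of that tissue (genes
without reference information get s = 0), and the ICI of every cell is
computed. Null values are pooled across cells by default (per-cell
nulls via `pooled_null=False`), and a cell is significant for a tissue
when its ICI lies strictly above the 95th percentile of that tissue's
null. The percentile is configurable; 95 corresponds to a permutation
p < 0.05 upper-tail test. Cells significant for exactly one tissue take
that identity; for both, "mixed"; for neither, "none" ("none" can be
merged into "mixed" by config, for three-way reporting).

Because the ICI is linear in the expression scale, uniformly rescaling
e multiplies experimental and null ICI alike, so significance calls are
scale-free (a property the tests assert).

**Why pooled rather than per-cell nulls.** A per-cell null for the
*opposite* tissue is shifted strongly negative (the cell's own highly
expressed markers carry negative s for the other tissue), so any
positive cross-tissue ICI would be declared significant and every pure
cell would come out "mixed". The pooled null keeps the two tissues'
thresholds on a common, predominantly positive scale.

**Marker density matters.** The linearity of the ICI means a pure
cell's cross-tissue ICI is its own-tissue ICI times 2^(−marker_effect)
in expectation, while the pooled null level scales with the marker
density |M|/G of the gene universe. Discriminating pure from mixed
cells therefore requires |M|/G to exceed roughly 2^(−marker_effect).
This is a property of the method, not of the implementation, and it
drives the synthetic defaults below.

## Sample-associated relative likelihood

The graph stage is a simplified reimplementation of
graph-signal-processing density estimators (MELD-style): instead of a
Chebyshev-approximated spectral filter with an alpha-decay kernel, it
uses a closed-form Tikhonov filter on a Gaussian-adaptive kNN graph.
The contract is the same — low-pass filtering of sample indicators over
the cell–cell graph — but the bandwidth parameter β is **not**
numerically interchangeable with the original tool's β; optima found on
real data with that tool do not transfer. Accordingly, all guarantees
here are property-based (calibration, limits, planted-signal recovery),
not value-matching.

* **Graph.** kNN (Euclidean) over per-cell embedding coordinates (3-D
  by default, mirroring pipelines that feed 3-D UMAP coordinates to the
  perturbation analysis; an expression-derived matrix, after the
  ≥10-transcript gene filter and per-cell + square-root normalization,
  can be used as coordinates instead). Weights
  w_ij = exp(−d²_ij/(σ_i σ_j)) with σ_i the distance to the knn-th
  neighbour (a binary kernel is available); union symmetrization
  W ← max(W, Wᵀ); no self-loops; distance ties broken by index;
  coincident points get σ clamped to machine epsilon.
* **Smoothing.** density = (I + β·L_sym)⁻¹·indicator, solved by sparse
  LU and clipped at zero; β = 0 returns the indicator exactly, and as
  β → ∞ the density collapses onto the Laplacian nullspace (the
  degree-weighted constant), a limit the tests check against an
  eigendecomposition oracle.
* **Likelihood.** Each (genotype, replicate) sample's density vector is
  normalized to sum 1 (removing sample-size effects exactly), then the
  focal likelihood is ρ_f/(ρ_f + ρ_o). The quotient is evaluated on the
  larger density and complemented for the other, so swapping the focal
  sample maps ℓ → 1 − ℓ bit-exactly. One graph is built over all cells;
  each replicate's pair of indicators is filtered independently, every
  cell receives a likelihood per replicate, and the replicate-averaged
  likelihood is reported alongside.
* **Classification.** Per replicate, cells with likelihood strictly
  below μ − 2σ are "depleted", strictly above μ + 2σ "enriched", else
  "unaffected" (μ, σ over all cells of that replicate's likelihood;
  σ = 0 yields all-unaffected). Per-cluster fractions divide each
  category count by the number of that replicate's cells in the
  cluster, so fractions sum to 1 per (cluster, replicate).
* **Parameter search.** For each (knn, β) grid point, sample labels are
  permuted uniformly (shared permutations across grid points); because
  permuted labels carry no spatial structure, the ground-truth
  likelihood is the constant global focal-sample proportion, and the
  mean squared error of the computed likelihood against it, averaged
  over permutations, scores the grid point. Ties at the minimum go to
  the smallest knn, then the smallest β. knn values ≥ n are skipped
  with a warning.

Open choices resolved here: per-sample normalization is performed over
all cells (the densities already being computed per replicate), and the
MSE ground truth is the constant sample-proportion vector.

## Differential expression and enrichment

Rank-sum DE between two disjoint cell groups uses per-cell normalized
expression (target 10⁴) by default, no fold-change or expression floor,
and Bonferroni correction with m = genes tested. The two-sided p-value
is exact — full enumeration of group assignments, tie-aware, counting
assignments whose U statistic deviates at least as far from its null
mean — whenever the smaller group has ≤ 8 cells *and* the enumeration
stays within 20,000 assignments (8 vs 8 = 12,870 is the largest
both-small case); otherwise the tie-corrected normal approximation
(scipy) is used. The cap exists because "small group vs huge group"
contrasts make C(n₁+n₂, n₁) astronomically large even at n₁ = 3.

Hypergeometric overlap of sets A, B in universe N reports fold
enrichment k·N/(|A|·|B|), the one-sided tail P(X ≥ k), and a two-sided
p by the minimum-likelihood construction (sum of all outcome
probabilities no larger than the observed one); doubling-the-smaller-
tail is available by config. Identity-category enrichment of a cell
subset treats A = subset, B = cells of a category, N = all cells.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
with known ground truth; its defaults are the package's reference study
conditions.

* **Gene universe:** 2,000 genes, of which 10 are mitochondrial
  (`MT-` prefix). This is best thought of as the informative (highly
  variable) subset of a transcriptome, not a whole genome.
* **Bulk reference:** lognormal baseline expression (meanlog 1, sdlog
  1); 300 planted markers per tissue, multiplied/divided by
  2^(marker_effect/2) in the two tissues so the expected fold change is
  exactly 2^marker_effect (default marker_effect = 3, i.e. 8-fold);
  4 replicates per tissue of negative-binomial counts (dispersion 0.1,
  2 × 10⁶ counts per library). The 300-per-tissue marker density
  (15% of the universe) follows from the ICI marker-density requirement
  above combined with an 8-fold effect; real bulk contrasts of opposing
  tissue domains yield a few hundred markers, which is this density
  once restricted to an informative-gene universe.
* **Cells:** populations are defined by identity (adaxial / abaxial /
  mixed), cluster id, baseline size (150 per sample × replicate) and
  per-sample depletion factors. Profiles are proportional to the
  corresponding tissue's bulk CPM (mixed = 50:50 blend, weight
  configurable); per-cell library sizes are lognormal around 5,000
  UMIs; counts are NB with shared dispersion 0.1. Mitochondrial genes
  contribute a per-cell fraction drawn uniformly from (0.002, 0.008) —
  realistic for clean protoplasts and below the 1% QC cutoff.
  Population sizes per sample are deterministic rounded products
  `n_cells × depletion`, not multinomial draws, so depletion-recovery
  expectations are exact.
* **Embedding:** population centroids are placed deterministically on a
  radius-6 sphere (golden-spiral spacing) and cells scatter around
  their centroid with isotropic Gaussian noise (sd 0.6), giving
  well-separated clusters. Coordinates are simulated latents, not
  computed from the counts, because the likelihood analysis takes
  embedding coordinates as input.
* **Determinism:** a single integer seed drives everything;
  fixed seed ⇒ bit-identical matrices, coordinates and truth tables.

What the generator does **not** emulate: doublets, ambient RNA, batch
chemistry, read-level effects, overlapping or non-convex cluster
geometry, genome-scale gene counts, and any dependence of the embedding
on the counts. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed model, not performance on real
data — in particular, identity recovery on real tissue will degrade
with marker sparsity and embedding distortion.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems chosen
to keep the full run in the low minutes on one CPU: 1,800-cell identity
recovery with a 1,000-permutation null, 500-cell calibration, five
2,160-cell depletion replicates, 30-node spectral-oracle graphs, and
complete enumeration oracles for universes ≤ 12 (hypergeometric) and
group sizes ≤ 8 (rank-sum). Other numerics: CPM requires a positive
library total; per-cell normalization targets the median cell total
when no target is given and refuses zero-total cells; the permutation
p reported for a cell is the fraction of null values ≥ its ICI; all
percentile/cutoff comparisons are strict as documented; BH adjustment
is the standard step-up with monotonicity enforcement capped at 1
(via statsmodels).

## Known limitations

* Two tissues and two samples per replicate only (by design).
* The Tikhonov smoother's β is method-specific; compare likelihood maps
  across methods by their categories, not by β values.
* The pooled ICI null assumes the two tissues' marker sets have
  comparable size and specificity mass; grossly asymmetric sets shift
  the shared thresholds.
* `simple_bulk_de` with 2 replicates is underpowered (Welch df ≈ 2);
  4+ replicates or an external DE table are recommended.
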