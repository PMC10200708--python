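# apexmap

Cell-identity scoring and sample-perturbation mapping for two-tissue
single-cell RNA-seq experiments.

`apexmap` reimplements, as a tested and reusable library + CLI, the
computational core of a common experimental design in plant development:
a droplet scRNA-seq comparison of two genotypes (e.g. a wild-type shoot
apex against a patterning mutant), interpreted against a bulk RNA-seq
reference of two opposing tissue identities (e.g. the adaxial/top and
abaxial/bottom domains of a leaf primordium). It answers two questions:

1. **Which tissue identity does each cell carry?** Per-cell *index of
   cell identity* (ICI) scoring against bulk-derived marker genes, with
   permutation-based significance, classifying cells as *adaxial*,
   *abaxial*, *mixed* (significant for both) or *none*.
2. **Which cell states are depleted or enriched in one genotype?** A
   graph-smoothed, sample-associated relative likelihood per cell,
   with a ±2 s.d. cutoff yielding *depleted / unaffected / enriched*
   calls and per-cluster, per-replicate category fractions.

Everything is exercisable on synthetic data with known ground truth: the
package ships a negative-binomial simulator of the full two-genotype,
two-replicate design (planted markers, blended "mixed" populations,
controlled population depletion, mitochondrial fractions, latent 3-D
embedding coordinates).

## The statistics

**Specificity score.** For gene *g* with replicate-averaged bulk
expression CPM₁, CPM₂ in the two tissues,

    s_g = (CPM₁ − CPM₂) / (CPM₁ + CPM₂)  ∈ [−1, 1].

**Markers** are genes with |log₂ fold change| > 2 at BH FDR < 0.05
(external DE tables, e.g. from edgeR, are accepted verbatim; a simple
Welch-on-log-CPM test is built in so no external run is needed).

**ICI.** For a cell with expression e_g and a tissue's positive marker
set M (all s_g > 0),

    ICI = (mean of e_g·s_g over expressed markers) × (fraction of M expressed)
        = Σ_{g∈M} e_g·s_g / |M|.

Significance is assessed against a null built from 1,000 random gene
sets of size |M|, each drawn gene weighted by the specificity score it
would have as a marker; ICI values strictly above the null's 95th
percentile are significant.

**Sample likelihood.** A kNN graph over per-cell embedding coordinates
with adaptive Gaussian weights w_ij = exp(−d²_ij/(σ_i σ_j)); each
(sample, replicate) indicator is low-pass filtered by the Tikhonov
smoother x = (I + β·L_sym)⁻¹·1_sample, densities are normalized per
sample, and the focal-sample likelihood is ρ_f/(ρ_f + ρ_o). Graph
parameters (knn, β) can be chosen by a permuted-label MSE search.

**Enrichment.** Wilcoxon rank-sum DE between cell groups (exact by
enumeration for small groups, Bonferroni-corrected), and hypergeometric
overlap tests with fold enrichment k·N/(|A|·|B|).

## Worked example

```python
import pandas as pd
import apexmap as am

cfg = am.SimConfig(seed=1)                       # 2,000 genes, 3 populations,
ref, matrix, meta, truth = am.simulate_experiment(cfg)  # 2 genotypes x 2 reps

rc = ref.replicate_counts
de = am.simple_bulk_de(rc[[c for c in rc.columns if c.startswith("adaxial")]],
                       rc[[c for c in rc.columns if c.startswith("abaxial")]])
sets = am.select_markers(ref, de)
print({t: len(s) for t, s in sets.items()})

result = am.ici_pipeline(matrix, sets, ref,
                         am.IciParams(seed=31, n_permutations=1000))
print(pd.crosstab(result.table.merge(truth.cells, on="barcode")["identity"],
                  result.table.merge(truth.cells, on="barcode")["category"]))
```

prints

```
{'adaxial': 298, 'abaxial': 297}
category  abaxial  adaxial  mixed
identity
abaxial       600        0      0
adaxial         0      600      0
mixed           0        0    600
```

i.e. of the 600 planted markers, 595 are recovered from the bulk
replicates, and every pure adaxial/abaxial cell and every 50:50-blend
cell is assigned its true identity class (the blend cells are
significant for *both* tissues, hence "mixed"). The genotype comparison:

```python
res = am.sample_likelihood_analysis(meta, focal="mut",
                                    params=am.GraphParams(knn=8, beta=10.0))
clusters = pd.Series(meta["cluster"].to_numpy(), index=meta["barcode"]).to_dict()
print(am.cluster_fractions(res, clusters).round(3).to_string(index=False))
```

```
 cluster  replicate  n_cells  frac_depleted  frac_unaffected  frac_enriched
       0          1      300          0.000            0.987          0.013
       0          2      300          0.060            0.930          0.010
       1          1      300          0.017            0.957          0.027
       1          2      300          0.023            0.937          0.040
       2          1      300          0.033            0.907          0.060
       2          2      300          0.000            0.993          0.007
```

With no planted depletion the likelihood hovers around 0.5 and nearly
all cells are "unaffected" in every cluster and replicate; planting a
depletion factor (e.g. `PopulationSpec(..., depletion={"mut": 0.2})`)
concentrates the "depleted" calls in that population.

## Command line

Each stage is also a subcommand of the `apexmap` console script:
`simulate`, `qc`, `markers`, `ici`, `likelihood`, `likelihood-search`,
`de`, `overlap`, and `run` (the full pipeline from a YAML config; see
`examples/demo.yaml`, which finishes in well under a minute). `run`
writes every stage artifact as TSV plus a `manifest.json` recording the
package version, seeds, per-stage parameters and row counts; re-running
a config reproduces all artifacts bit-identically.

```sh
apexmap run --config examples/demo.yaml
```

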