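# Small end-to-end demonstration run: simulate a two-genotype shoot-apex
# experiment with a half-depleted mixed-identity population, then run QC,
# marker selection, ICI identity assignment, the sample-likelihood
# analysis and a rank-sum DE contrast.
out_dir: demo_output
seed: 7
stages: [simulate, qc, markers, ici, likelihood, de]
simulate:
  populations:
    - {name: adaxial_epidermis, identity: adaxial, cluster: 0, n_cells: 60}
    - {name: abaxial_epidermis, identity: abaxial, cluster: 1, n_cells: 60}
    - {name: rim, identity: mixed, cluster: 2, n_cells: 60,
       depletion: {mut: 0.5}}
# thresholds scaled to the 2,000-gene synthetic universe
qc: {min_genes: 200, max_umi: 100000, max_mito: 0.05}
markers: {log2fc_min: 2.0, fdr_max: 0.05}
ici: {n_permutations: 500, percentile: 95.0}
likelihood: {focal: mut, knn: 8, beta: 10.0}
de: {group_genes: [GENE00000, GENE00001], background_n: 200}
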