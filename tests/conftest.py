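import numpy as np
import pytest
import scipy.sparse as sp

import apexmap as am


@pytest.fixture(scope="session")
def default_experiment():
    """One synthetic experiment at generator defaults (seed fixed)."""
    cfg = am.SimConfig(seed=1)
    ref, matrix, meta, truth = am.simulate_experiment(cfg)
    return cfg, ref, matrix, meta, truth


@pytest.fixture(scope="session")
def marker_sets(default_experiment):
    """Marker sets selected from the default experiment's bulk reference."""
    _, ref, *_ = default_experiment
    rc = ref.replicate_counts
    de = am.simple_bulk_de(
        rc[[c for c in rc.columns if c.startswith(ref.t1)]],
        rc[[c for c in rc.columns if c.startswith(ref.t2)]],
    )
    return am.select_markers(ref, de)


def toy_matrix(dense, genes=None, cells=None, gene_names=None):
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    cells = cells or [f"C{j}" for j in range(n_cells)]
    return am.CountMatrix(
        np.array(genes, dtype=object),
        np.array(cells, dtype=object),
        sp.csr_matrix(dense),
        gene_names=np.array(gene_names, dtype=object) if gene_names else None,
    )
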