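import numpy as np
import pytest
import scipy.sparse as sp

import agemyo as am
from agemyo.io_qc import CountMatrix


def toy_matrix(dense, genes=None, cells=None) -> CountMatrix:
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{j}" for j in range(dense.shape[1])]
    return CountMatrix(np.array(genes, dtype=object), np.array(cells, dtype=object),
                       sp.csr_matrix(dense))


@pytest.fixture(scope="session")
def small_atlas():
    """Mixed-population atlas at desk scale (shared, read-only)."""
    cfg = am.SimConfig(n_samples_per_group=3, n_cells_per_sample=400, n_genes=600,
                       seed=123)
    matrix, cell_meta, sample_meta, truth = am.generate_atlas(cfg)
    return cfg, matrix, cell_meta, sample_meta, truth


@pytest.fixture(scope="session")
def myo_atlas():
    """Myonuclei-only atlas with hybrids, for fibre-typing tests."""
    cfg = am.SimConfig(
        n_samples_per_group=3,
        n_cells_per_sample=500,
        n_genes=800,
        cell_type_props={"type_I_myonuclei": 0.45, "type_II_myonuclei": 0.55},
        age_effects={},
        default_dispersion=0.3,
        marker_effect=4.0,
        hybrid_frac=0.10,
        seed=2024,
    )
    matrix, cell_meta, sample_meta, truth = am.generate_atlas(cfg)
    nm = am.normalize_log1p(matrix)
    return cfg, matrix, nm, cell_meta, sample_meta, truth
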