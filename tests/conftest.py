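import numpy as np
import pandas as pd
import pytest

from glioconnect.core_data import CountMatrix, NormalizedMatrix, lognormalize
from glioconnect.synthetic import ScSimConfig, simulate_sc_experiment


@pytest.fixture(scope="session")
def planted_experiment():
    """Sorted single-cell simulation with a clear planted effect."""
    cfg = ScSimConfig(cells_per_group=120, n_genes=600, effect_size=3.0, seed=11)
    cm, truth = simulate_sc_experiment(cfg)
    return cm, truth


@pytest.fixture(scope="session")
def planted_nm(planted_experiment):
    cm, truth = planted_experiment
    return lognormalize(cm), truth


@pytest.fixture(scope="session")
def null_nm():
    """No planted signal: effect size 1 (pure NB noise)."""
    cfg = ScSimConfig(cells_per_group=120, n_genes=500, effect_size=1.0, seed=23)
    cm, _ = simulate_sc_experiment(cfg)
    return lognormalize(cm)


def make_norm_matrix(values, gene_ids=None, cell_ids=None, cell_meta=None):
    """Build a NormalizedMatrix straight from a dense array (tests only)."""
    values = np.asarray(values, dtype=float)
    g = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    c = cell_ids or [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(g, c, values, cell_meta=cell_meta)
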