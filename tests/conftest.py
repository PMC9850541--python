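import numpy as np
import pytest

from scvuln.core_io import ExpressionMatrix
from scvuln.preprocess import normalize
from scvuln.synthetic import SimSpec, make_profiles, simulate_counts


def make_matrix(values, layer="norm", gene_prefix="G", cell_prefix="C"):
    """Build an ExpressionMatrix from a 2-D array (genes x cells)."""
    values = np.asarray(values, dtype=float)
    kw = {layer: values}
    return ExpressionMatrix(
        gene_ids=[f"{gene_prefix}{i}" for i in range(values.shape[0])],
        cell_ids=[f"{cell_prefix}{j}" for j in range(values.shape[1])],
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated dataset shared by fast tests: (spec, matrix, truth)."""
    spec = SimSpec(n_genes=600, n_cells=500, marker_genes_per_class=25,
                   risk_set_size=30, seed=42)
    profiles = make_profiles(spec)
    matrix, truth = simulate_counts(profiles, spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def sim_small_norm(sim_small):
    _, matrix, _ = sim_small
    return normalize(matrix)
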