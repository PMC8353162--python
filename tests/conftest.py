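import math

import numpy as np
import pandas as pd
import pytest

from sctube.counts_io import CountMatrix
from sctube.knowledge import default_knowledge_matrix
from sctube.scoring import NormalizedMatrix
from sctube.simulate import SimulationParams, StageComposition, simulate_counts


@pytest.fixture(scope="session")
def km():
    return default_knowledge_matrix()


def uniform_composition(km, label="CS12", n_cells=640, sex="female"):
    props = {t: 1.0 / len(km.types) for t in km.types}
    s = sum(props.values())
    props = {k: v / s for k, v in props.items()}
    return StageComposition(label, props, n_cells=n_cells, sex=sex)


@pytest.fixture(scope="session")
def noise_free_params():
    # Poisson limit, no off expression: the exactly-recoverable regime
    return SimulationParams(
        mu_on=50.0, mu_off=0.0, dispersion=math.inf, mito_frac_mean=0.05, seed=101
    )


@pytest.fixture(scope="session")
def noise_free_dataset(km, noise_free_params):
    comp = uniform_composition(km, n_cells=960)
    return simulate_counts(km, comp, noise_free_params)


@pytest.fixture(scope="session")
def noisy_dataset(km):
    comp = uniform_composition(km, n_cells=1600, sex="male")
    return simulate_counts(km, comp, SimulationParams(seed=202))


@pytest.fixture()
def tiny_counts():
    """Hand-sized 4 genes x 3 cells matrix for arithmetic checks."""
    import scipy.sparse as sp

    counts = sp.csr_matrix(
        np.array([[3, 0, 0], [1, 2, 0], [0, 5, 0], [1, 0, 0]], dtype=np.int64)
    )
    return CountMatrix(
        counts=counts,
        genes=pd.Index(["geneA", "geneB", "geneC", "MT-1"]),
        cells=pd.Index(["c1", "c2", "c3"]),
        cell_meta=pd.DataFrame(
            {"sample": ["s1", "s1", "s2"], "stage": ["CS12", "CS12", "CS14"]},
            index=["c1", "c2", "c3"],
        ),
    )


def make_nm(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(values=values, genes=pd.Index(genes), cells=pd.Index(cells))
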