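import warnings

import numpy as np
import pytest

from snmosaic import simulate as sim


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_config():
    return sim.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Two het + two WT females, one timepoint: the minimal mosaic cohort."""
    cfg = sim.SimulationConfig(
        seed=11, cohort_layout=[("F", "het_female", "P30", 2),
                                ("F", "wt_female", "P30", 2)],
        cells_per_animal=60, n_genes=300, n_cell_types=4)
    animals, cells = sim.simulate_cohort(cfg)
    X, genes, meta, truth = sim.simulate_counts(animals, cells, cfg)
    return cfg, animals, X, genes, meta, truth


@pytest.fixture(scope="session")
def mini_reference_input():
    seq, pos = sim.default_gene_sequence()
    return seq, pos


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
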