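import numpy as np
import pytest

from utr3evo import clade_divergence as cd
from utr3evo import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.SimulationConfig(seed=1234, n_genes=40)


@pytest.fixture(scope="session")
def default_tree(default_config):
    tree, painting = sd.make_default_tree(default_config)
    return tree, painting


@pytest.fixture(scope="session")
def bm_model(default_tree):
    tree, painting = default_tree
    return cd.TwoRegimeBM(tree, painting)


@pytest.fixture(scope="session")
def small_genomes(default_config):
    """Genomes for 40 genes under 2x focal rate, with planted truth."""
    cfg = default_config
    tree, painting = sd.make_default_tree(cfg)
    traits = sd.simulate_traits(
        tree, painting, 2.0, 1.0, cfg.root_length, cfg.n_genes, cfg.seed
    )
    lengths = sd.floor_lengths(traits, cfg.min_utr3)
    return lengths, sd.build_genomes(lengths, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
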