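import numpy as np
import pytest

from lncgraph.config import RunConfig
from lncgraph.synthetic import PlantedWorld, simulate_world


@pytest.fixture(scope="session")
def study_world() -> PlantedWorld:
    """The standard planted world: 60x40, 4 blocks, 10% label noise."""
    return PlantedWorld(seed=1)


@pytest.fixture(scope="session")
def study_bundle(study_world):
    return simulate_world(study_world)


@pytest.fixture(scope="session")
def tiny_world() -> PlantedWorld:
    """A small, fast world for pipeline-level tests."""
    return PlantedWorld(
        n_lncrna=20,
        n_disease=16,
        n_blocks=2,
        partner_pool_sizes={v: 20 for v in
                            ("lncrna_mrna", "lncrna_rbp", "lncrna_protein",
                             "disease_metabolite", "disease_circrna")},
        noise_flip_prob=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_world):
    return simulate_world(tiny_world)


@pytest.fixture
def fast_config() -> RunConfig:
    """Down-scaled training settings for smoke-level runs."""
    cfg = RunConfig(seed=7)
    cfg.train.epochs = 30
    cfg.train.patience = 30
    cfg.dae.epochs = 100
    cfg.evaluation.k_folds = 3
    return cfg


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
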