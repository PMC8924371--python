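import numpy as np
import pytest

from acidscreen import screenz, simdata

ACID = 6.63
PHYS = 7.4


def power_config(seed: int = 11) -> simdata.ScreenSimConfig:
    """Planted-signal benchmark: 5% acid-essential genes with a 0.7
    growth-rate multiplier at the highly acidic condition only."""
    effect = {k: dict(v) for k, v in simdata.DEFAULT_FITNESS_EFFECT.items()}
    effect["acid_essential"] = {7.4: 1.0, 6.9: 1.0, 6.63: 0.7}
    return simdata.ScreenSimConfig(n_genes=2000, guides_per_gene=4,
                                   depth=500.0, n_replicates=2,
                                   fitness_effect=effect, seed=seed)


def null_config(seed: int, n_genes: int = 2000) -> simdata.ScreenSimConfig:
    """All-neutral screen: every knockout fitness-neutral everywhere."""
    return simdata.ScreenSimConfig(n_genes=n_genes, guides_per_gene=4,
                                   depth=500.0, n_replicates=2,
                                   class_fractions={"neutral": 1.0},
                                   seed=seed)


@pytest.fixture(scope="session")
def power_screen():
    cfg = power_config()
    matrix, truth = simdata.simulate_screen(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def power_scores(power_screen):
    _, matrix, truth = power_screen
    scores = screenz.score_contrast(matrix, treated_ph=ACID, control_ph=PHYS)
    return scores, truth


@pytest.fixture(scope="session")
def null_screen():
    cfg = null_config(seed=7, n_genes=200)
    matrix, truth = simdata.simulate_screen(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def ph_levels():
    return simdata.bicarb_ph_levels()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
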