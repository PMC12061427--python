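import numpy as np
import pytest

from scplacer import (
    MapperConfig,
    run_pipeline,
    simulate_layers,
    simulate_toy,
)


@pytest.fixture(scope="session")
def toy():
    return simulate_toy(n=500, seed=1)


@pytest.fixture(scope="session")
def toy_run(toy):
    """Toy dataset trained with itself as the spatial reference."""
    return run_pipeline(
        [toy.slice()],
        toy.expression(),
        do_lognorm=False,
        seed=1,
        config=MapperConfig(seed=1),
    )


@pytest.fixture(scope="session")
def laminar():
    return simulate_layers(n_layers=5, cells_per_layer=200, marker_strength=2.0, seed=0)


@pytest.fixture(scope="session")
def laminar_run(laminar):
    return run_pipeline([laminar.st], laminar.sc_expr, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
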