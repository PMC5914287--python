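import pytest

from dasypop import GridSpec, WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """Full-size synthetic world under default study conditions."""
    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def small_world():
    """Fast world for smoke tests: 2 divisions, 4 decades, 60x60 grid."""
    cfg = WorldConfig(
        grid=GridSpec(60, 60),
        n_divisions=2,
        counties_per_division=4,
        decades=[1970, 1980, 1990, 2000],
        seed=11,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noise_free_world():
    """World whose urban footprints sit exactly on the scaling curve."""
    cfg = WorldConfig(scaling_noise_sd=0.0, seed=3)
    return generate_world(cfg)
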