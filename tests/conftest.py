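import pytest

from spikecap import presets
from spikecap.design import ReadAnatomy, TargetGene
from spikecap.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def target():
    return presets.nc886_target()


@pytest.fixture(scope="session")
def design(target):
    return presets.nc886_design(target)


@pytest.fixture(scope="session")
def anatomy():
    return presets.chromium_5p_anatomy()


@pytest.fixture(scope="session")
def clean_sim(design, target, anatomy):
    """Small error-free, contaminant-free run: every pair is a true capture."""
    cfg = SimConfig(
        n_cells_per_population=5,
        population_means=(8.0, 3.0, 0.0),
        nonspecific_fraction=0.0,
        reads_per_molecule=2.0,
        error_rate=0.0,
        seed=11,
    )
    return simulate_run(cfg, design, target, anatomy)


@pytest.fixture(scope="session")
def noisy_sim(design, target, anatomy):
    """Moderate-contamination run with sequencing errors for end-to-end tests."""
    cfg = SimConfig(
        n_cells_per_population=20,
        population_means=(15.0, 4.0, 0.0),
        nonspecific_fraction=0.8,
        reads_per_molecule=3.0,
        error_rate=0.005,
        seed=7,
    )
    return simulate_run(cfg, design, target, anatomy)
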