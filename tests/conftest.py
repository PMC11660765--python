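import numpy as np
import pytest

import kmereg as km


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_unit_spectra(rng, n, n_bins=8, resolution=0.5, f0=2.0):
    """n random unit-mass spectra on a small shared grid."""
    grid = km.FrequencyGrid(f0 + resolution * np.arange(n_bins), resolution)
    W = rng.dirichlet(np.ones(n_bins), size=n)
    return grid, [km.ChannelSpectrum(grid, w) for w in W]


@pytest.fixture(scope="session")
def small_cohort():
    """Compact 3-site cohort (72 subjects, 2 channels) for protocol tests."""
    cfg = km.SynthConfig(
        channels=("Pz", "O1"),
        sites=(
            km.SiteSpec("A", 24, "truncnorm", age_mean=30.0, age_sd=15.0),
            km.SiteSpec("B", 24, "truncnorm", age_mean=50.0, age_sd=15.0),
            km.SiteSpec("C", 24, "truncnorm", age_mean=65.0, age_sd=15.0),
        ),
    )
    cohort, _ = km.simulate_cohort(cfg, seed=42)
    return cohort


@pytest.fixture(scope="session")
def montage_cohort():
    """Tiny cohort carrying the full 19-channel 10/20 montage."""
    cfg = km.SynthConfig(
        sites=(
            km.SiteSpec("A", 6, "uniform", age_min=10, age_max=40),
            km.SiteSpec("B", 6, "uniform", age_min=40, age_max=80),
        )
    )
    cohort, _ = km.simulate_cohort(cfg, seed=7)
    return cohort
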