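import pytest

from cgscreen.synth import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A 120-strain noisy screen with ground truth, shared across tests."""
    cfg = SimConfig(
        n_strains=120, frac_sensitive=0.15, frac_resistant=0.1, noise_cv=0.1, seed=42
    )
    growth, truth, layouts = simulate_screen(cfg)
    return cfg, growth, truth, layouts


@pytest.fixture(scope="session")
def clean_screen():
    """A noise-free screen for exact invariant checks."""
    cfg = SimConfig(
        n_strains=60, frac_sensitive=0.2, frac_resistant=0.1, noise_cv=0.0, seed=5
    )
    growth, truth, layouts = simulate_screen(cfg)
    return cfg, growth, truth, layouts
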