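import numpy as np
import pytest
from hypothesis import settings

from mirgrad.simulate import SimulationDesign, simulate_precursors

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def precursors():
    """A small fixed precursor reference shared across tests."""
    return simulate_precursors(20, seed=42)


@pytest.fixture
def null_design():
    """All-null three-tissue design factory (no gradient miRNAs)."""

    def make(n_mirnas=2000, seed=0, **kwargs):
        return SimulationDesign(
            n_mirnas=n_mirnas,
            n_gradient_up=0,
            n_gradient_down=0,
            baseline_mean=100.0,
            seed=seed,
            **kwargs,
        )

    return make


@pytest.fixture
def gradient_design():
    """Design with planted 4-fold gradients, as in recovery checks."""

    def make(seed=0, n_mirnas=200, n_up=10, n_down=10, **kwargs):
        return SimulationDesign(
            n_mirnas=n_mirnas,
            n_gradient_up=n_up,
            n_gradient_down=n_down,
            baseline_mean=100.0,
            gradient_step=4.0,
            seed=seed,
            **kwargs,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
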