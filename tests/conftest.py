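import numpy as np
import pytest

from burststage import simulate as sim
from burststage.trace import IntensityTrace


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh, deterministic stream
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_population():
    """Default-calibration population, 50 cells per stage."""
    return sim.simulate_population(n_cells_per_stage=50, seed=11)


@pytest.fixture(scope="session")
def large_population():
    """Default-calibration population large enough for stage-level statistics."""
    return sim.simulate_population(n_cells_per_stage=300, seed=11)


@pytest.fixture(scope="session")
def separated_population():
    """Well-separated regimes (no within-regime amplitude spread), 600 cells."""
    return sim.simulate_population(sim.well_separated_profiles(), n_cells_per_stage=100, seed=11)


def random_piecewise_trace(rng, n_samples=25, dt=2.5, lo=-100.0, hi=1300.0, cell_id="cell"):
    """A random piecewise-linear trace on a uniform grid."""
    t = np.arange(n_samples) * dt
    y = rng.uniform(lo, hi, size=n_samples)
    return IntensityTrace(cell_id, t, y)


@pytest.fixture(scope="session")
def noiseless_render():
    return sim.render_stack(sim.StackSpec(spot_amplitude=0.0, noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def snr5_render():
    """Seeded fixture with (cytoplasm - nucleus) / noise_sd = 5."""
    return sim.render_stack(sim.StackSpec(noise_sd=50.0), seed=42)
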