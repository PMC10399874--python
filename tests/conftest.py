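import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from ffskit.simulate import (
    SimConfig,
    simulate_kymograph,
    simulate_membrane_trace,
    simulate_nb_stack,
)


@pytest.fixture(scope="session")
def small_stack():
    """Compact compound-Poisson N&B stack (monomer, lambda=0.5/dwell, n=5)."""
    cfg = SimConfig(seed=101, subunits=1, n_particles_mean=5.0,
                    height=64, width=64, n_frames=100)
    return cfg, simulate_nb_stack(cfg)


@pytest.fixture(scope="session")
def membrane_setup():
    """One simulated membrane trace + kymograph at the default sFCS geometry."""
    cfg = SimConfig(
        seed=71, geometry="membrane2d", n_particles_mean=10.0,
        molecular_brightness=3000.0, diffusion_coefficient=1.0,
        waist_w0=0.2, background_rate=1000.0,
    )
    trace = simulate_membrane_trace(cfg, duration=80_000 * cfg.line_time)
    kymo = simulate_kymograph(trace, cfg)
    return cfg, trace, kymo
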