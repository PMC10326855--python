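import numpy as np
import pytest

from xtalkin import core, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def kinetic_laws():
    """Power laws with magnitudes typical of glycine/water at 25 degC."""
    return {
        "growth": core.PowerLawFit(
            prefactor=3000.0, exponent=2.86, rate_kind="growth"
        ),
        "secondary": core.PowerLawFit(
            prefactor=2e7, exponent=3.5, rate_kind="secondary_nucleation"
        ),
        "primary": core.PowerLawFit(
            prefactor=2.5, exponent=3.0, rate_kind="primary_nucleation"
        ),
    }


@pytest.fixture(scope="session")
def small_suite(kinetic_laws):
    """A compact noisy workflow suite shared by pipeline-level tests."""
    cfg = simulate.SimulationConfig(seed=7, noise=True)
    return simulate.simulate_workflow_suite(
        kinetic_laws["growth"],
        kinetic_laws["secondary"],
        kinetic_laws["primary"],
        [1.08, 1.10, 1.12, 1.14, 1.16, 1.18],
        cfg,
        n_vials=25,
        n_seeded=3,
        offset_size_um=150.0,
    )
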