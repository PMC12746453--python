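"""Shared fixtures: models, ground states, Wigner ensembles, EOE runs.

Everything is generated programmatically at session start; the expensive
NaI artifacts (grid ground state, 10k-sample ensemble, electron-only runs)
are session-scoped so the full suite builds them once.
"""

import numpy as np
import pytest

from eoexcite import eod, models, qdgrid, sampling, select, workflow


@pytest.fixture(scope="session")
def nai():
    return models.nai_model()


@pytest.fixture(scope="session")
def harmonic():
    # omega ~ 1300 cm^-1, 3 eV gap, unit dipole; uncoupled, undisplaced
    return models.make_harmonic_fixture(
        omega=0.006, gap=0.11, tdm=1.0, seed=7, mass=2000.0, displacement=0.0
    )


@pytest.fixture(scope="session")
def harmonic_displaced():
    return models.make_harmonic_fixture(omega=0.006, gap=0.11, tdm=1.0, seed=11)


@pytest.fixture(scope="session")
def nai_ground(nai):
    wf = qdgrid.imaginary_time_ground_state(nai)
    assert wf.energy is not None
    return wf


@pytest.fixture(scope="session")
def harmonic_ground(harmonic):
    grid = qdgrid.make_grid(*harmonic.domain, n=512)
    return qdgrid.imaginary_time_ground_state(harmonic, grid=grid, tol=1e-14)


@pytest.fixture(scope="session")
def nai_wigner(nai, nai_ground):
    return sampling.wigner_distribution(nai_ground, mass=nai.reduced_mass)


@pytest.fixture(scope="session")
def nai_samples(nai_wigner):
    """The study ensemble: 10,000 Wigner samples of the NaI ground state."""
    return sampling.draw_samples(nai_wigner, 10_000, seed=1)


@pytest.fixture(scope="session")
def pulse_low20():
    return workflow.study_pulse("low", 20.0)


@pytest.fixture(scope="session")
def eoe_low20(nai, nai_samples, pulse_low20):
    """Electron-only traces for the low-energy 20 fs pulse."""
    return eod.run_ensemble(nai_samples, nai, pulse_low20)


@pytest.fixture(scope="session")
def eoe_low100(nai, nai_samples):
    return eod.run_ensemble(nai_samples, nai, workflow.study_pulse("low", 100.0))


@pytest.fixture(scope="session")
def renorm_low20(eoe_low20):
    return select.renormalize(eoe_low20)


@pytest.fixture(scope="session")
def selection_low20(renorm_low20):
    return select.select_initial_conditions(renorm_low20, seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
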