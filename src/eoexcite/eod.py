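"""Electron-only dynamics: the frozen-nuclei electronic TDSE under a laser.

For each initial condition the nuclei are held fixed and the electronic
coefficients are propagated in the MCH-like basis (adiabatic energies plus
any constant coupling plus the dipole--field term in one Hermitian matrix)
by a time-ordered product of short-time exponentials, with the Hamiltonian
evaluated at the mid-point of every step.  Only every ``stride``-th step is
stored, which quantizes the stored time grid (and hence the selectable
start times) to ``stride * dt``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .models import DiabaticModel, ElectronicSnapshot, adiabatize
from .pulses import FieldTable, LaserPulse
from .units import fs_to_au

__all__ = [
    "PopulationTrace",
    "EnsemblePopulations",
    "EODConfig",
    "propagate_electrons",
    "randomize_polarizations",
    "run_ensemble",
]


@dataclasses.dataclass
class PopulationTrace:
    """Stride-decimated electronic history of one frozen-nuclei simulation."""

    geometry_id: int
    times: np.ndarray                 # (n_stored,), au
    populations: np.ndarray           # (n_stored, n_states)
    coefficients: np.ndarray | None   # (n_stored, n_states) complex, optional
    initial_state: int
    polarization: np.ndarray

    @property
    def n_states(self) -> int:
        return self.populations.shape[1]

    @property
    def dt_stored(self) -> float:
        return float(self.times[1] - self.times[0])


def _build_h0(snapshot: ElectronicSnapshot, include_coupling=True):
    n = snapshot.n_states
    h0 = np.diag(snapshot.energies).astype(complex)
    if include_coupling and snapshot.coupling is not None:
        h0 = h0 + snapshot.coupling
    return h0


def _dipole_matrix(
    snapshot: ElectronicSnapshot,
    include_static: bool,
    include_excited_tdm: bool,
):
    """(n, n, 3) dipole matrix with the optional simplifications applied."""
    mu = snapshot.tdm.copy()
    for i in range(snapshot.n_states):
        mu[i, i] = 0.0
    if include_excited_tdm is False:
        keep = np.zeros_like(mu)
        keep[0, :] = mu[0, :]
        keep[:, 0] = mu[:, 0]
        mu = keep
    if include_static and snapshot.static_dipoles is not None:
        for i in range(snapshot.n_states):
            mu[i, i] = snapshot.static_dipoles[i]
    return mu


def propagate_electrons(
    snapshot: ElectronicSnapshot,
    field: FieldTable,
    beta: int = 0,
    stride: int = 8,
    include_static: bool = False,
    include_excited_tdm: bool = True,
    store_coefficients: bool = True,
) -> PopulationTrace:
    """Propagate the electronic TDSE for one frozen geometry.

    The coefficients start as ``c_alpha(0) = delta_{beta alpha}`` at the
    first table time.  Per step the Hamiltonian
    ``H(t) = diag(E) + coupling - mu . E(t)`` is evaluated at the step
    midpoint (linear interpolation of the tabulated field) and the
    coefficients are advanced by ``expm(-i H dt)``.  Every ``stride``-th
    step is stored, the initial point included.
    """
    dt = field.dt
    if dt <= 0:
        raise ValueError("field table must advance in time")
    h0 = _build_h0(snapshot)
    if not np.allclose(h0, h0.conj().T):
        raise ValueError("electronic Hamiltonian must be Hermitian")
    mu = _dipole_matrix(snapshot, include_static, include_excited_tdm)
    emid = field.midpoint_field()

    n = snapshot.n_states
    c = np.zeros(n, dtype=complex)
    c[beta] = 1.0
    stored_t = [field.times[0]]
    stored_c = [c.copy()]
    for j in range(emid.shape[0]):
        h = h0 - np.einsum("abx,x->ab", mu, emid[j])
        c = scipy.linalg.expm(-1j * h * dt) @ c
        if (j + 1) % stride == 0:
            stored_t.append(field.times[j + 1])
            stored_c.append(c.copy())
    coeff = np.array(stored_c)
    return PopulationTrace(
        geometry_id=snapshot.geometry_id,
        times=np.array(stored_t),
        populations=np.abs(coeff) ** 2,
        coefficients=coeff if store_coefficients else None,
        initial_state=beta,
        polarization=np.array([np.nan, np.nan, np.nan]),
    )


def randomize_polarizations(n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. unit 3-vectors uniform on the sphere (Gaussian trick)."""
    if n <= 0:
        raise ValueError("need a positive number of directions")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Vectorized two-state ensemble driver
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EODConfig:
    """Run parameters of the electron-only stage.

    Defaults reproduce the study conditions: 0.0625 fs step, every eighth
    step written out (stored times on a 0.5 fs grid), dynamics started in
    the ground state, molecular axes aligned with the lab frame (no
    orientational averaging) unless ``randomize_orientation`` is set.
    """

    dt_fs: float = 0.0625
    stride: int = 8
    beta: int = 0
    cutoff: float = 1e-8
    randomize_orientation: bool = False
    orientation_seed: int = 0

    @property
    def dt(self) -> float:
        return fs_to_au(self.dt_fs)


@dataclasses.dataclass
class EnsemblePopulations:
    """Population traces of a whole ensemble, stored as one array."""

    times: np.ndarray                 # (n_stored,), au
    populations: np.ndarray           # (n_k, n_stored, n_states)
    initial_state: int
    geometry_ids: np.ndarray
    orientations: np.ndarray          # (n_k, 3) molecular axis directions

    @property
    def n_traces(self) -> int:
        return self.populations.shape[0]

    def trace(self, k: int) -> PopulationTrace:
        return PopulationTrace(
            geometry_id=int(self.geometry_ids[k]),
            times=self.times,
            populations=self.populations[k],
            coefficients=None,
            initial_state=self.initial_state,
            polarization=self.orientations[k],
        )


def propagate_two_level_ensemble(de, mu_eff, field_mid, dt, stride):
    """Closed-form stepping of many independent two-level systems.

    ``de``/``mu_eff`` are per-trace gaps and effective couplings, and
    ``field_mid`` the signed scalar field at the step midpoints.  The step
    propagator exp(-i H dt) for H = [[0, -mu E], [-mu E, de]] is evaluated
    via its Pauli decomposition and applied vectorized over traces.
    Returns populations (n_traces, n_steps//stride + 1, 2).
    """
    de = np.asarray(de, dtype=float)
    n_k = de.size
    c0 = np.ones(n_k, dtype=complex)
    c1 = np.zeros(n_k, dtype=complex)
    n_steps = len(field_mid)
    pops = np.empty((n_k, n_steps // stride + 1, 2))
    pops[:, 0, 0] = 1.0
    pops[:, 0, 1] = 0.0
    half_gap = 0.5 * de
    phase_mean = np.exp(-1j * half_gap * dt)
    js = 0
    for j in range(n_steps):
        v = -mu_eff * field_mid[j]
        w = np.sqrt(half_gap**2 + v * v)
        th = w * dt
        sinc = np.where(w > 0, np.sin(th) / np.where(w > 0, w, 1.0), dt)
        cos = np.cos(th)
        # H = mean*I + (-half_gap)*sigma_z + v*sigma_x (states ordered 0,1)
        u00 = phase_mean * (cos + 1j * sinc * half_gap)
        u11 = phase_mean * (cos - 1j * sinc * half_gap)
        u01 = phase_mean * (-1j * sinc * v)
        c0, c1 = u00 * c0 + u01 * c1, u01 * c0 + u11 * c1
        if (j + 1) % stride == 0:
            js += 1
            pops[:, js, 0] = np.abs(c0) ** 2
            pops[:, js, 1] = np.abs(c1) ** 2
    return pops


def run_ensemble(
    samples,
    model: DiabaticModel,
    pulse: LaserPulse,
    config: EODConfig | None = None,
) -> EnsemblePopulations:
    """Electron-only dynamics for every sample of a two-state model.

    One snapshot per sample is taken at the sampled geometry and reused
    unchanged at every step.  The two-level step propagator is evaluated in
    closed form (Pauli decomposition of the Hermitian 2x2 exponential) and
    vectorized over the ensemble, which makes 10,000 traces a matter of
    seconds.  Deterministic for fixed configuration (randomness enters only
    through the optional orientation sampling, which is seeded).
    """
    config = config or EODConfig()
    if config.beta != 0:
        raise NotImplementedError("the vectorized driver starts from the ground state")
    r = np.array([s.r for s in samples])
    energies, _, tdm_ad = adiabatize(model, r)
    de = energies[:, 1] - energies[:, 0]          # (n_k,)
    mu01 = tdm_ad[:, 0, 1]                        # signed projection on the axis

    table = pulse.sample(config.dt, cutoff=config.cutoff, block=config.stride)
    scal = table.field @ pulse.polarization       # signed scalar field
    smid = 0.5 * (scal[:-1] + scal[1:])

    n_k = r.size
    if config.randomize_orientation:
        axes = randomize_polarizations(n_k, config.orientation_seed)
    else:
        axes = np.tile(model.axis, (n_k, 1))
    # effective coupling strength: mu vector along the molecular axis,
    # projected on the field polarization direction
    geom = axes @ pulse.polarization              # cos(angle) per trace
    mu_eff = mu01 * geom

    pops = propagate_two_level_ensemble(de, mu_eff, smid, config.dt, config.stride)
    return EnsemblePopulations(
        times=table.times[:: config.stride],
        populations=pops,
        initial_state=0,
        geometry_ids=np.array([s.index for s in samples]),
        orientations=axes,
    )
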