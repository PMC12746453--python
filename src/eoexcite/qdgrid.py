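"""Grid-based quantum dynamics reference for the two-state models.

Exact (numerically converged) wavepacket dynamics on a uniform 1D grid:
the vibrational ground state by imaginary-time propagation, real-time
dynamics by the second-order split-operator method with the kinetic
propagator applied spectrally and the potential -- including the
dipole--field coupling -- applied pointwise in the diabatic representation.
This module is the benchmark against which the surface-hopping ensembles
are judged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .models import DiabaticModel, adiabatize
from .observables import EnsembleObservables
from .pulses import FieldTable

__all__ = [
    "GridWavefunction",
    "QDTrajectory",
    "make_grid",
    "imaginary_time_ground_state",
    "propagate",
    "observables",
]


@dataclasses.dataclass
class GridWavefunction:
    """Complex two-state amplitudes psi[state, point] on a uniform R grid."""

    grid: np.ndarray
    psi: np.ndarray
    time: float = 0.0
    energy: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.psi = np.asarray(self.psi, dtype=complex)
        if self.psi.shape != (2, self.grid.size):
            raise ValueError("psi must have shape (2, n_grid)")

    @property
    def dr(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def norm(self) -> float:
        return float(np.sum(np.abs(self.psi) ** 2) * self.dr)

    def density(self) -> np.ndarray:
        return np.sum(np.abs(self.psi) ** 2, axis=0)

    def normalized(self) -> "GridWavefunction":
        return dataclasses.replace(self, psi=self.psi / np.sqrt(self.norm()))


def make_grid(rmin: float = 3.0, rmax: float = 40.0, n: int = 1024) -> np.ndarray:
    """Uniform spatial grid; defaults match the NaI reference setup."""
    return np.linspace(rmin, rmax, n)


def _kinetic_phase(grid, mass, dt):
    k = 2.0 * np.pi * np.fft.fftfreq(grid.size, d=grid[1] - grid[0])
    return np.exp(-1j * k**2 / (2.0 * mass) * dt)


def _pot_half_step_real(vmat, dt):
    """exp(-i M dt/2) for pointwise real-symmetric 2x2 matrices ``vmat``.

    Returns the four components (p00, p01, p11) of the complex symmetric
    propagator, evaluated in closed form via the Pauli decomposition.
    """
    a = vmat[..., 0, 0]
    b = vmat[..., 1, 1]
    c = vmat[..., 0, 1]
    mean = 0.5 * (a + b)
    half = 0.5 * (a - b)
    w = np.sqrt(half**2 + c**2)
    th = w * (dt / 2.0)
    sinc = np.where(w > 0, np.sin(th) / np.where(w > 0, w, 1.0), dt / 2.0)
    phase = np.exp(-1j * mean * (dt / 2.0))
    p00 = phase * (np.cos(th) - 1j * sinc * half)
    p11 = phase * (np.cos(th) + 1j * sinc * half)
    p01 = phase * (-1j * sinc * c)
    return p00, p01, p11


def _apply_pot(psi, p00, p01, p11):
    out = np.empty_like(psi)
    out[0] = p00 * psi[0] + p01 * psi[1]
    out[1] = p01 * psi[0] + p11 * psi[1]
    return out


def _mean_energy(psi, grid, mass, vmat):
    dr = grid[1] - grid[0]
    pk = np.fft.fft(psi, axis=1)
    k = 2.0 * np.pi * np.fft.fftfreq(grid.size, d=dr)
    t = np.sum(k**2 / (2.0 * mass) * np.abs(pk) ** 2) / np.sum(np.abs(pk) ** 2)
    dens0 = np.abs(psi[0]) ** 2
    dens1 = np.abs(psi[1]) ** 2
    coh = 2.0 * np.real(np.conj(psi[0]) * psi[1])
    v = np.sum(
        vmat[..., 0, 0] * dens0 + vmat[..., 1, 1] * dens1 + vmat[..., 0, 1] * coh
    ) * dr
    return float(t + v)


def imaginary_time_ground_state(
    model: DiabaticModel,
    grid: np.ndarray | None = None,
    tol: float = 1e-12,
    dtau: float = 10.0,
    max_steps: int = 200_000,
    check_every: int = 50,
) -> GridWavefunction:
    """Lowest vibrational state of the lower adiabatic surface.

    Imaginary-time split-operator relaxation of the full two-state diabatic
    Hamiltonian, started from a Gaussian at the minimum of the lower
    adiabat.  Converged when the energy change between checks (``check_every``
    steps apart) drops below ``tol`` hartree per step; the imaginary step is
    then annealed (halved twice, reconverging each time) to remove the
    Trotter bias of the finite step from the relaxed state.  The converged
    energy is stored on the returned wavefunction.
    """
    if grid is None:
        grid = make_grid(*model.domain)
    model.check_domain(grid[[0, -1]])
    vmat = model.v(grid)
    energies, _, _ = adiabatize(model, grid)
    i0 = int(np.argmin(energies[:, 0]))
    dr = grid[1] - grid[0]

    psi = np.zeros((2, grid.size), dtype=complex)
    width = max(10 * dr, 0.05 * (grid[-1] - grid[0]))
    psi[0] = np.exp(-((grid - grid[i0]) ** 2) / (2.0 * width**2))

    a, b, c = vmat[..., 0, 0], vmat[..., 1, 1], vmat[..., 0, 1]
    mean, halfd = 0.5 * (a + b), 0.5 * (a - b)
    w = np.sqrt(halfd**2 + c**2)

    e_new = np.inf
    for dt_im in (dtau, dtau / 2.0, dtau / 4.0):
        tfac = np.abs(_kinetic_phase(grid, model.reduced_mass, -1j * dt_im))
        ch = np.cosh(w * dt_im / 2.0)
        sh = np.where(w > 0, np.sinh(w * dt_im / 2.0) / np.where(w > 0, w, 1.0),
                      dt_im / 2.0)
        damp = np.exp(-mean * dt_im / 2.0)
        q00 = damp * (ch - sh * halfd)
        q11 = damp * (ch + sh * halfd)
        q01 = damp * (-sh * c)

        e_old = np.inf
        converged = False
        for it in range(max_steps):
            psi = _apply_pot(psi, q00, q01, q11)
            psi = np.fft.ifft(np.fft.fft(psi, axis=1) * tfac, axis=1)
            psi = _apply_pot(psi, q00, q01, q11)
            psi /= np.sqrt(np.sum(np.abs(psi) ** 2) * dr)
            if (it + 1) % check_every == 0:
                e_new = _mean_energy(psi, grid, model.reduced_mass, vmat)
                if abs(e_new - e_old) / check_every < tol:
                    converged = True
                    break
                e_old = e_new
        if not converged:
            raise RuntimeError("imaginary-time relaxation did not converge")
    return GridWavefunction(grid=grid, psi=psi, time=0.0, energy=e_new)


@dataclasses.dataclass
class QDTrajectory:
    """Stride-decimated history of a grid propagation."""

    grid: np.ndarray
    times: np.ndarray           # (n_stored,)
    psi: np.ndarray             # (n_stored, 2, n_grid) complex
    mass: float

    def frame(self, i: int) -> GridWavefunction:
        return GridWavefunction(grid=self.grid, psi=self.psi[i], time=self.times[i])


def propagate(
    wf: GridWavefunction,
    model: DiabaticModel,
    pulse: FieldTable | None,
    dt: float,
    t_end: float,
    stride: int = 5,
    edge_threshold: float = 1e-6,
) -> QDTrajectory:
    """Real-time split-operator propagation from ``wf.time`` to ``t_end``.

    The laser enters in the diabatic representation through the dipole term
    ``-mu(R) * (axis . E(t))`` inside the potential half-steps, with the
    field evaluated at the half-step midpoints.  Every ``stride``-th step is
    stored (including the initial state).  A warning is emitted if density
    accumulates at the grid edges (no absorbing boundary is used).
    """
    grid = wf.grid
    mass = model.reduced_mass
    vmat = model.v(grid)
    mumat = model.mu(grid)
    tkin = _kinetic_phase(grid, mass, dt)

    n_steps = int(round((t_end - wf.time) / dt))
    if n_steps < 0:
        raise ValueError("t_end must not precede the wavefunction time")
    if pulse is not None:
        e_of_t = lambda t: np.interp(t, pulse.times, pulse.field @ model.axis,
                                     left=0.0, right=0.0)
    else:
        e_of_t = None

    psi = wf.psi.copy()
    stored_t = [wf.time]
    stored_psi = [psi.copy()]
    edge_warned = False
    # field-free propagator is time-independent: precompute
    if e_of_t is None:
        p00, p01, p11 = _pot_half_step_real(vmat, dt)
    t = wf.time
    for step in range(n_steps):
        if e_of_t is not None:
            s = e_of_t(t + 0.25 * dt)
            s2 = e_of_t(t + 0.75 * dt)
            m1 = vmat - mumat * s
            m2 = vmat - mumat * s2
            a00, a01, a11 = _pot_half_step_real(m1, dt)
            b00, b01, b11 = _pot_half_step_real(m2, dt)
            psi = _apply_pot(psi, a00, a01, a11)
            psi = np.fft.ifft(np.fft.fft(psi, axis=1) * tkin, axis=1)
            psi = _apply_pot(psi, b00, b01, b11)
        else:
            psi = _apply_pot(psi, p00, p01, p11)
            psi = np.fft.ifft(np.fft.fft(psi, axis=1) * tkin, axis=1)
            psi = _apply_pot(psi, p00, p01, p11)
        t += dt
        if (step + 1) % stride == 0:
            stored_t.append(t)
            stored_psi.append(psi.copy())
            if not edge_warned:
                dens = np.sum(np.abs(psi[:, [0, 1, -2, -1]]) ** 2)
                if dens * (grid[1] - grid[0]) > edge_threshold:
                    warnings.warn(
                        "wavepacket density reached the grid edge; "
                        "results may suffer boundary reflections"
                    )
                    edge_warned = True
    return QDTrajectory(
        grid=grid, times=np.array(stored_t), psi=np.array(stored_psi), mass=mass
    )


def observables(
    traj: QDTrajectory, model: DiabaticModel, state: str | int = "S1"
) -> EnsembleObservables:
    """<R> and <dR> over the density projected on one adiabatic state.

    ``state`` is ``'S0'``/``'S1'`` (adiabatic index 0/1), ``'total'`` for
    the full density.  The diabatic amplitudes are rotated pointwise to the
    adiabatic basis before projecting.  Times with zero projected norm are
    flagged invalid (nan values, ``valid=False``), never silently averaged.
    """
    grid = traj.grid
    dr = grid[1] - grid[0]
    if state == "total":
        dens = np.sum(np.abs(traj.psi) ** 2, axis=1)
    else:
        idx = {"S0": 0, "S1": 1}.get(state, state)
        _, u, _ = adiabatize(model, grid)   # (n_grid, 2, 2)
        # psi_ad[alpha] = sum_dia U[dia, alpha] * psi[dia]
        col = u[:, :, idx]                  # (n_grid, 2)
        psi_ad = np.einsum("gd,tdg->tg", col, traj.psi)
        dens = np.abs(psi_ad) ** 2

    pop = dens.sum(axis=1) * dr
    valid = pop > 1e-12
    r_mean = np.full(pop.shape, np.nan)
    r_std = np.full(pop.shape, np.nan)
    w = dens[valid] * dr / pop[valid, None]
    r_mean[valid] = (w * grid).sum(axis=1)
    r2 = (w * grid**2).sum(axis=1)
    r_std[valid] = np.sqrt(np.maximum(r2 - r_mean[valid] ** 2, 0.0))
    return EnsembleObservables(
        times=traj.times,
        r_mean=r_mean,
        r_std=r_std,
        population=pop,
        valid=valid,
        label=f"qd:{state}",
    )
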