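"""Wigner phase-space sampling and the stick-spectrum absorption model.

The vibrational ground state from the grid module is Wigner-transformed
numerically; positions and momenta for the trajectory ensemble are drawn
from the (clipped-nonnegative) discretized distribution.  The absorption
spectrum is the oscillator-strength-weighted sum of Gaussians over the
sampled vertical excitation energies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .models import DiabaticModel, adiabatize
from .qdgrid import GridWavefunction
from .units import HARTREE_EV

__all__ = [
    "WignerSample",
    "WignerDistribution",
    "wigner_distribution",
    "draw_samples",
    "absorption_spectrum",
    "vertical_data",
]


@dataclasses.dataclass
class WignerSample:
    """One phase-space point: position (bohr), velocity (au), unit weight."""

    index: int
    r: float
    v: float
    weight: float = 1.0


@dataclasses.dataclass
class WignerDistribution:
    """W(R, P) on a uniform (R, P) grid, with the clipped negative mass."""

    r: np.ndarray
    p: np.ndarray
    w: np.ndarray                  # (n_r, n_p), clipped to >= 0
    w_raw: np.ndarray              # unclipped transform
    clipped_mass: float
    mass: float

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def dp(self) -> float:
        return float(self.p[1] - self.p[0])

    def position_marginal(self) -> np.ndarray:
        return self.w_raw.sum(axis=1) * self.dp

    def momentum_marginal(self) -> np.ndarray:
        return self.w_raw.sum(axis=0) * self.dr


def wigner_distribution(
    wf: GridWavefunction, mass: float | None = None, support_tol: float = 1e-12
) -> WignerDistribution:
    """Numerical Wigner transform of a single-surface nuclear wavefunction.

    W(R, P) = (1/pi) Int dy psi*(R+y) psi(R-y) exp(2 i P y).

    ``wf`` must be normalized and essentially single-state: if more than
    1e-6 of the population sits on the minor electronic component, the state
    is vibronically mixed and no single nuclear Wigner function exists, so a
    ``ValueError`` is raised.  The transform is evaluated on the subgrid
    where the density exceeds ``support_tol`` of its maximum (zero-padded),
    which keeps the (R, P) matrix small.
    """
    pops = np.sum(np.abs(wf.psi) ** 2, axis=1) * wf.dr
    minor = pops.min() / pops.sum()
    if minor > 1e-6:
        raise ValueError(
            "wavefunction has significant amplitude on both electronic "
            "states; Wigner sampling requires a single nuclear state"
        )
    psi = wf.psi[int(np.argmax(pops))]
    psi = psi / np.sqrt(np.sum(np.abs(psi) ** 2) * wf.dr)

    dens = np.abs(psi) ** 2
    keep = np.nonzero(dens > support_tol * dens.max())[0]
    lo, hi = keep[0], keep[-1] + 1
    width = hi - lo
    pad = width  # room for the +/- y correlation lags
    lo2, hi2 = max(0, lo - pad), min(psi.size, hi + pad)
    sub = np.zeros(hi2 - lo2, dtype=complex)
    sub[:] = psi[lo2:hi2]
    r_sub = wf.grid[lo2:hi2]
    n = sub.size

    # correlation matrix A[i, j] = psi*(x_i + y_j) psi(x_i - y_j)
    j = np.arange(-(n // 2), n - n // 2)
    ii = np.arange(n)
    ip = ii[:, None] + j[None, :]
    im = ii[:, None] - j[None, :]
    ok = (ip >= 0) & (ip < n) & (im >= 0) & (im < n)
    a = np.zeros((n, j.size), dtype=complex)
    a[ok] = np.conj(sub[ip[ok]]) * sub[im[ok]]

    # transform over the lag index: sum_j A_ij exp(2 i p y_j), y_j = j * dr.
    # The momentum grid p_l = pi l / (n_j dr) makes the discrete marginals
    # exact: sum_l exp(2 i p_l y_j) = n_j * delta_{j0}.
    dr = wf.dr
    p_grid = np.fft.fftshift(np.pi * np.fft.fftfreq(j.size, d=dr))
    w_raw = (dr / np.pi) * np.real(a @ np.exp(2j * np.outer(j * dr, p_grid)))

    clipped = np.clip(w_raw, 0.0, None)
    dp = p_grid[1] - p_grid[0]
    clipped_mass = float(np.sum(np.clip(-w_raw, 0.0, None)) * dr * dp)
    return WignerDistribution(
        r=r_sub,
        p=p_grid,
        w=clipped,
        w_raw=w_raw,
        clipped_mass=clipped_mass,
        mass=mass if mass is not None else float("nan"),
    )


def draw_samples(
    dist: WignerDistribution, n: int, seed: int, mass: float | None = None
) -> list[WignerSample]:
    """Draw ``n`` i.i.d. phase-space samples from the clipped distribution.

    Grid cells are chosen categorically with probability proportional to the
    clipped Wigner value, then jittered uniformly within the cell.  Momenta
    are converted to velocities ``v = P / m`` at sampling time.  Reproducible
    for a given ``seed``.
    """
    if n <= 0:
        raise ValueError("sample count must be positive")
    m = mass if mass is not None else dist.mass
    if not np.isfinite(m) or m <= 0:
        raise ValueError("a positive nuclear mass is required for velocities")
    w = dist.w.ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("Wigner distribution has no positive mass")
    rng = np.random.default_rng(seed)
    flat = rng.choice(w.size, size=n, p=w / total)
    ir, ipp = np.unravel_index(flat, dist.w.shape)
    r = dist.r[ir] + (rng.random(n) - 0.5) * dist.dr
    p = dist.p[ipp] + (rng.random(n) - 0.5) * dist.dp
    return [
        WignerSample(index=k, r=float(r[k]), v=float(p[k] / m)) for k in range(n)
    ]


def vertical_data(samples, model: DiabaticModel):
    """Vectorized single-point data for a sample list.

    Returns ``(r, de, mu01)``: positions (bohr), adiabatic excitation
    energies S0->S1 (hartree) and adiabatic transition dipole magnitudes
    (au, projected on the molecular axis).
    """
    r = np.array([s.r for s in samples])
    energies, _, tdm_ad = adiabatize(model, r)
    de = energies[..., 1] - energies[..., 0]
    mu01 = np.abs(tdm_ad[..., 0, 1])
    return r, de, mu01


def absorption_spectrum(
    samples,
    model: DiabaticModel,
    fwhm_ev: float = 0.1,
    energies_ev: np.ndarray | None = None,
):
    """Gaussian-convolved absorption spectrum from an ensemble of samples.

    Each sample contributes a Gaussian of the stated FWHM centered at its
    vertical excitation energy, weighted by its oscillator strength
    ``f = (2/3) dE |mu01|^2``; the curve is normalized to unit maximum, so
    a global rescaling of the transition dipole cancels.
    Returns ``(energies_ev, intensity)``.
    """
    _, de, mu01 = vertical_data(samples, model)
    de_ev = de * HARTREE_EV
    fosc = (2.0 / 3.0) * de * mu01**2
    if energies_ev is None:
        lo = de_ev.min() - 5 * fwhm_ev
        hi = de_ev.max() + 5 * fwhm_ev
        energies_ev = np.linspace(lo, hi, 2000)
    sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    diff = energies_ev[:, None] - de_ev[None, :]
    spec = np.sum(fosc[None, :] * np.exp(-(diff**2) / (2.0 * sigma**2)), axis=1)
    if spec.max() > 0:
        spec = spec / spec.max()
    return energies_ev, spec
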