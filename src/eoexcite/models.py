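"""Analytic two-state diabatic molecular models.

The module provides the diabatic potential/dipole models that feed every
other stage of the package: the NaI alkali-halide model (an ionic and a
covalent diabat with a localized coupling at the avoided crossing, in the
classic Faist--Levine parameterization) and displaced-harmonic test
fixtures with closed-form vibrational ground states.

A :class:`DiabaticModel` is a thin container around callables ``V(R)`` and
``mu(R)`` returning 2x2 symmetric matrices in atomic units (hartree, bohr).
:func:`adiabatize` diagonalizes the electronic Hamiltonian at a geometry and
rotates the dipole matrix along; :func:`snapshot` packages the result as the
per-geometry electronic data consumed by the electron-only propagator.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .units import (
    AMU_ME,
    BOHR_ANGSTROM,
    HARTREE_EV,
    amu_to_au,
    angstrom_to_bohr,
    ev_to_au,
)

__all__ = [
    "DiabaticModel",
    "ElectronicSnapshot",
    "adiabatize",
    "snapshot",
    "oscillator_strength",
    "nai_model",
    "NAI_DEFAULT_PARAMS",
    "make_harmonic_fixture",
    "load_model",
    "save_model_params",
]


@dataclasses.dataclass
class DiabaticModel:
    """Two-state diabatic model on a single internuclear coordinate.

    Attributes
    ----------
    label : str
        Human-readable name.
    reduced_mass : float
        Nuclear reduced mass in electron masses (atomic units).
    v : callable
        ``v(R) -> (..., 2, 2)`` real symmetric diabatic potential matrix in
        hartree for ``R`` in bohr (scalar or array).
    mu : callable
        ``mu(R) -> (..., 2, 2)`` symmetric diabatic electric-dipole matrix
        projected on the molecular axis, in atomic units.
    domain : tuple
        ``(rmin, rmax)`` validity range in bohr.
    axis : ndarray
        Unit 3-vector of the molecular axis used to promote the projected
        dipole matrix to laboratory-frame vectors.
    meta : dict
        Free-form metadata (parameter sets, closed-form reference values).
    """

    label: str
    reduced_mass: float
    v: Callable[[np.ndarray], np.ndarray]
    mu: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.reduced_mass <= 0:
            raise ValueError("reduced mass must be positive")

    def check_domain(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r < self.domain[0]) or np.any(r > self.domain[1]):
            raise ValueError(
                f"geometry outside model domain {self.domain} bohr"
            )
        return r


@dataclasses.dataclass
class ElectronicSnapshot:
    """Per-geometry electronic data in the adiabatic (MCH-like) basis.

    ``energies`` are sorted ascending adiabatic energies (hartree), ``tdm``
    is the (n, n, 3) matrix of transition-dipole 3-vectors (Hermitian as a
    matrix of vectors), ``static_dipoles`` the optional (n, 3) permanent
    dipoles, and ``coupling`` an optional constant Hermitian off-diagonal
    coupling matrix (e.g. spin--orbit).
    """

    energies: np.ndarray
    tdm: np.ndarray
    static_dipoles: np.ndarray | None = None
    coupling: np.ndarray | None = None
    geometry_id: int = -1

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("snapshot energies must be sorted ascending")
        self.tdm = np.asarray(self.tdm, dtype=float)
        if not np.allclose(self.tdm, np.swapaxes(self.tdm, 0, 1)):
            raise ValueError("transition-dipole matrix must be Hermitian")
        if self.coupling is not None:
            self.coupling = np.asarray(self.coupling)
            if not np.allclose(self.coupling, self.coupling.conj().T):
                raise ValueError("coupling matrix must be Hermitian")

    @property
    def n_states(self) -> int:
        return self.energies.size


def _fix_eigenvector_signs(u: np.ndarray) -> np.ndarray:
    """Fix the sign of each eigenvector column.

    Convention: the largest-magnitude component is made positive; on exact
    ties the component with the lowest diabat index decides (``argmax``
    returns the first maximal entry).
    """
    idx = np.argmax(np.abs(u), axis=-2)
    picked = np.take_along_axis(u, idx[..., None, :], axis=-2)[..., 0, :]
    sign = np.where(picked < 0, -1.0, 1.0)
    return u * sign[..., None, :]


def adiabatize(model: DiabaticModel, r):
    """Diagonalize the diabatic Hamiltonian at geometry ``r``.

    Returns ``(energies, u, tdm_ad)`` where ``u`` is the orthogonal
    diabatic-to-adiabatic transform with sign-fixed columns such that
    ``u.T @ V(r) @ u`` is diagonal ascending, and
    ``tdm_ad = u.T @ mu(r) @ u``.
    Works on scalars or arrays of geometries (leading axes broadcast).
    """
    r = model.check_domain(r)
    v = model.v(r)
    energies, u = np.linalg.eigh(v)
    u = _fix_eigenvector_signs(u)
    mu_d = model.mu(r)
    tdm_ad = np.swapaxes(u, -1, -2) @ mu_d @ u
    return energies, u, tdm_ad


def snapshot(model: DiabaticModel, r, geometry_id: int = -1) -> ElectronicSnapshot:
    """Single-point electronic calculation at geometry ``r`` (scalar)."""
    energies, _, tdm_ad = adiabatize(model, float(r))
    tdm_vec = tdm_ad[..., None] * model.axis
    return ElectronicSnapshot(
        energies=energies,
        tdm=tdm_vec,
        static_dipoles=np.diagonal(tdm_ad)[:, None] * model.axis,
        geometry_id=geometry_id,
    )


def oscillator_strength(snap: ElectronicSnapshot, i: int = 0, j: int = 1) -> float:
    """Oscillator strength f = (2/3) dE |mu_ij|^2 in atomic units."""
    de = snap.energies[j] - snap.energies[i]
    mu2 = float(np.sum(snap.tdm[i, j] ** 2))
    return (2.0 / 3.0) * de * mu2


# ---------------------------------------------------------------------------
# NaI model (Faist--Levine ionic/covalent diabats, localized coupling)
# ---------------------------------------------------------------------------

#: Literature default parameters for the NaI diabatic model.  Values are kept
#: in their customary units (eV, Angstrom) and converted on evaluation; the
#: ionic diabat is a Rittner-type curve (Born--Mayer repulsion, Coulomb
#: attraction, induction and dispersion terms, offset by the difference of
#: the Na ionization potential and the I electron affinity), the covalent
#: diabat a repulsive exponential, the coupling a Gaussian at the crossing.
NAI_DEFAULT_PARAMS = {
    "covalent": {"a1_ev": 0.813, "beta1_inv_angstrom": 4.08, "r0_angstrom": 2.67},
    "ionic": {
        "a2_ev": 2760.0,
        "b2_ev8_angstrom": 2.398,
        "rho_angstrom": 0.3489,
        "c2_ev_angstrom6": 11.3,
        "lambda_plus_angstrom3": 0.408,
        "lambda_minus_angstrom3": 6.431,
        "delta_e0_ev": 2.075,
    },
    "coupling": {
        "a12_ev": 0.055,
        "beta12_inv_angstrom2": 0.6931,
        "rx_angstrom": 6.93,
    },
    "masses_amu": {"na": 22.98976928, "i": 126.90447},
    "tdm_au": 0.05,
    "domain_bohr": [3.0, 40.0],
}

_E2_EV_ANGSTROM = 14.399645  # e^2 / (4 pi eps0)


def nai_model(
    params: dict | None = None,
    tdm: float | None = None,
    include_static_dipoles: bool = False,
) -> DiabaticModel:
    """Construct the NaI two-state diabatic model.

    State 0 is the ionic diabat (lower in the Franck--Condon region), state 1
    the covalent diabat (asymptotically lower).  A constant diabatic
    transition dipole moment ``tdm`` couples them radiatively; permanent
    dipoles are zero unless ``include_static_dipoles`` is set, in which case
    the ionic diabat carries the charge-separation dipole ``-R``.
    """
    p = params or NAI_DEFAULT_PARAMS
    cov, ion, cpl = p["covalent"], p["ionic"], p["coupling"]
    mu12 = float(p.get("tdm_au", 0.05) if tdm is None else tdm)
    rmin, rmax = p.get("domain_bohr", (3.0, 40.0))

    a1, b1, r0 = cov["a1_ev"], cov["beta1_inv_angstrom"], cov["r0_angstrom"]
    a2, b2 = ion["a2_ev"], ion["b2_ev8_angstrom"]
    rho, c2 = ion["rho_angstrom"], ion["c2_ev_angstrom6"]
    lp, lm = ion["lambda_plus_angstrom3"], ion["lambda_minus_angstrom3"]
    de0 = ion["delta_e0_ev"]
    a12, b12, rx = cpl["a12_ev"], cpl["beta12_inv_angstrom2"], cpl["rx_angstrom"]

    def v(r):
        r = np.asarray(r, dtype=float)
        ra = r * BOHR_ANGSTROM
        v_ion = (
            (a2 + (b2 / ra) ** 8) * np.exp(-ra / rho)
            - _E2_EV_ANGSTROM / ra
            - _E2_EV_ANGSTROM * (lp + lm) / (2.0 * ra**4)
            - c2 / ra**6
            - 2.0 * _E2_EV_ANGSTROM * lp * lm / ra**7
            + de0
        )
        v_cov = a1 * np.exp(-b1 * (ra - r0))
        v12 = a12 * np.exp(-b12 * (ra - rx) ** 2)
        out = np.empty(r.shape + (2, 2))
        out[..., 0, 0] = v_ion
        out[..., 1, 1] = v_cov
        out[..., 0, 1] = out[..., 1, 0] = v12
        return out / HARTREE_EV

    def mu(r):
        r = np.asarray(r, dtype=float)
        out = np.zeros(r.shape + (2, 2))
        out[..., 0, 1] = out[..., 1, 0] = mu12
        if include_static_dipoles:
            out[..., 0, 0] = -r
        return out

    m_na, m_i = p["masses_amu"]["na"], p["masses_amu"]["i"]
    mass = amu_to_au(m_na * m_i / (m_na + m_i))
    return DiabaticModel(
        label="NaI",
        reduced_mass=mass,
        v=v,
        mu=mu,
        domain=(float(rmin), float(rmax)),
        meta={"params": p, "tdm_au": mu12},
    )


def diabatic_crossing_radius(model: DiabaticModel, lo=None, hi=None) -> float:
    """Locate the radius where the two diabats cross (V11 = V22)."""
    from scipy.optimize import brentq

    lo = model.domain[0] if lo is None else lo
    hi = model.domain[1] if hi is None else hi

    def diff(r):
        vm = model.v(r)
        return vm[..., 0, 0] - vm[..., 1, 1]

    grid = np.linspace(lo, hi, 2048)
    d = diff(grid)
    sgn = np.sign(d)
    idx = np.nonzero(np.diff(sgn) != 0)[0]
    if idx.size == 0:
        raise ValueError("no diabatic crossing found in range")
    i = idx[0]
    return brentq(diff, grid[i], grid[i + 1])


# ---------------------------------------------------------------------------
# Harmonic test fixture
# ---------------------------------------------------------------------------


def make_harmonic_fixture(
    omega: float,
    gap: float,
    tdm: float,
    seed: int,
    mass: float = 2000.0,
    r_center: float = 10.0,
    displacement: float | None = None,
    coupling: float = 0.0,
) -> DiabaticModel:
    """Two harmonic diabats with a constant transition dipole.

    ``omega`` (hartree), ``gap`` (hartree) and ``tdm`` (au) must be positive.
    The upper diabat is displaced by ``displacement`` bohr; when not given it
    is drawn once from the seeded generator (uniform on [0, sigma_R]), so the
    same seed always returns the same model.  Closed-form reference values
    for the lower-state ground vibrational level are stored in ``meta``:
    energy ``omega/2`` above the minimum, position width
    ``sigma_r = sqrt(1/(2 m omega))`` and momentum width
    ``sigma_p = sqrt(m omega / 2)`` (so ``sigma_r * sigma_p = 1/2``).
    """
    if omega <= 0 or gap <= 0 or tdm <= 0:
        raise ValueError("omega, gap and tdm must be positive")
    rng = np.random.default_rng(seed)
    sigma_r = np.sqrt(1.0 / (2.0 * mass * omega))
    if displacement is None:
        displacement = float(rng.uniform(0.0, sigma_r))

    k_force = mass * omega**2

    def v(r):
        r = np.asarray(r, dtype=float)
        out = np.empty(r.shape + (2, 2))
        out[..., 0, 0] = 0.5 * k_force * (r - r_center) ** 2
        out[..., 1, 1] = gap + 0.5 * k_force * (r - r_center - displacement) ** 2
        out[..., 0, 1] = out[..., 1, 0] = coupling
        return out

    def mu(r):
        r = np.asarray(r, dtype=float)
        out = np.zeros(r.shape + (2, 2))
        out[..., 0, 1] = out[..., 1, 0] = tdm
        return out

    span = max(12.0 * sigma_r, abs(displacement) + 10.0 * sigma_r)
    return DiabaticModel(
        label="harmonic-fixture",
        reduced_mass=mass,
        v=v,
        mu=mu,
        domain=(r_center - span, r_center + span),
        meta={
            "omega": omega,
            "gap": gap,
            "tdm": tdm,
            "r_center": r_center,
            "displacement": displacement,
            "zero_point_energy": 0.5 * omega,
            "sigma_r": sigma_r,
            "sigma_p": np.sqrt(mass * omega / 2.0),
        },
    )


# ---------------------------------------------------------------------------
# Parameter-file plumbing
# ---------------------------------------------------------------------------


def save_model_params(path, params: dict | None = None) -> None:
    """Write a NaI parameter file (YAML key--value text, explicit units)."""
    with open(path, "w") as fh:
        fh.write("# eoexcite model parameter file v1\n")
        fh.write("# units are encoded in the key names (ev, angstrom, amu, au)\n")
        yaml.safe_dump(
            {"form": "nai", **(params or NAI_DEFAULT_PARAMS)}, fh, sort_keys=False
        )


def load_model(path) -> DiabaticModel:
    """Load a model from a parameter file written by :func:`save_model_params`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    form = data.pop("form", "nai")
    if form != "nai":
        raise ValueError(f"unknown model form {form!r}")
    return nai_model(params=data)
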