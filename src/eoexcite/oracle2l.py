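"""Closed-form coherently driven two-level model.

First-order perturbation theory plus the rotating-wave approximation for a
Gaussian pulse ``E(t) = E0 exp(-t^2 / 2 tau^2) cos(w0 t)`` acting on a
two-level system with transition dipole ``mu`` and detuning
``Omega = w0 - w_transition`` give the upper-state coefficient

    c(t) = -sqrt(2 pi) i (mu E0 tau / 4) exp(-tau^2 Omega^2 / 2)
           * (1 + erf(t / (sqrt(2) tau) - i tau Omega / sqrt(2)))

(atomic units, hbar = 1).  The time derivative of ``|c|^2`` is the
excitation-rate distribution over time and detuning whose clamped-positive
mass forms the teardrop-shaped region against which the stochastic
selection is validated.  All complex error functions are evaluated through
the Faddeeva function ``w(z)``, absorbing the Gaussian prefactors so no
intermediate overflows occur at large ``tau |Omega|``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import wofz

__all__ = [
    "TwoLevelParams",
    "upper_coefficient",
    "excitation_rate",
    "final_population",
    "probability_region",
    "from_pulse",
]


@dataclasses.dataclass
class TwoLevelParams:
    """mu, E0 in au; tau in atomic time units; detuning Omega in hartree."""

    mu: float
    e0: float
    tau: float
    detuning: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def amplitude(self) -> float:
        """sqrt(2 pi) mu E0 tau / 4, the peak coefficient scale."""
        return np.sqrt(2.0 * np.pi) * self.mu * self.e0 * self.tau / 4.0

    @property
    def is_weak_field(self) -> bool:
        """True when the predicted asymptotic population stays below 1%."""
        return final_population(dataclasses.replace(self, detuning=0.0)) <= 0.01


def from_pulse(pulse, mu: float, transition_energy: float) -> TwoLevelParams:
    """Two-level parameters matching a package pulse and a transition."""
    return TwoLevelParams(
        mu=mu, e0=pulse.e0, tau=pulse.tau,
        detuning=pulse.omega0 - transition_energy,
    )


def _erfc_term(p: TwoLevelParams, t):
    """exp(-tau^2 Omega^2 / 2) * (1 + erf(t/sqrt(2)tau - i tau Omega/sqrt(2))),

    computed as exp(-t^2/2tau^2 + i t Omega) * w(-i z0) with
    z0 = t/(sqrt(2) tau) - i tau Omega / sqrt(2).

    For t > 0 the argument of w falls in the lower half-plane where w
    explodes, so the reflection w(z) = 2 exp(-z^2) - w(-z) is applied
    analytically; the reflected term collapses to the asymptotic value
    2 exp(-tau^2 Omega^2 / 2) and the remainder keeps w in the upper
    half-plane, where it is bounded.  Stable for all t and detunings.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x = t / (np.sqrt(2.0) * p.tau)
    c_s = p.tau * p.detuning / np.sqrt(2.0)
    pre = np.exp(-(x**2) + 1j * t * p.detuning)
    out = np.empty(t.shape, dtype=complex)
    early = x <= 0.0
    out[early] = pre[early] * wofz(-c_s - 1j * x[early])
    out[~early] = (
        2.0 * np.exp(-(p.tau**2) * p.detuning**2 / 2.0)
        - pre[~early] * wofz(c_s + 1j * x[~early])
    )
    return out if out.size > 1 else out[0]


def upper_coefficient(p: TwoLevelParams, t):
    """Closed-form upper-state coefficient c(t); broadcasts over ``t``."""
    return -1j * p.amplitude * _erfc_term(p, t)


def final_population(p: TwoLevelParams) -> float:
    """|c(+inf)|^2 = 2 pi (mu E0 tau / 4)^2 * 4 * exp(-tau^2 Omega^2)."""
    return float(
        4.0 * p.amplitude**2 * np.exp(-(p.tau**2) * p.detuning**2)
    )


def excitation_rate(p: TwoLevelParams, t):
    """d|c|^2/dt at time ``t``; may be negative (transient back-transfer).

    rate = sqrt(2 pi) mu^2 E0^2 tau / 4 * exp(-t^2/2tau^2 - tau^2 Omega^2/2)
    rate = sqrt(2 pi) mu^2 E0^2 tau / 4 * exp(-t^2/2tau^2 - tau^2 Omega^2/2)
           * Re[exp(-i t Omega) (1 + erf(...))],

    which is the exact time derivative of ``|upper_coefficient|^2`` (the
    phase factor must be the conjugate of the one generated by
    differentiating the error function, so that the rate integrates to the
    asymptotic population *and* matches the transient pointwise).  The rate
    is even in the detuning.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    pref = np.sqrt(2.0 * np.pi) * p.mu**2 * p.e0**2 * p.tau / 4.0
    x = t / (np.sqrt(2.0) * p.tau)
    c_s = p.tau * p.detuning / np.sqrt(2.0)
    bracket = np.empty(t.shape, dtype=complex)
    early = x <= 0.0
    bracket[early] = np.exp(-2.0 * x[early] ** 2) * wofz(-c_s - 1j * x[early])
    # lower-half-plane reflection, as in the coefficient evaluation
    bracket[~early] = 2.0 * np.exp(
        -(x[~early] ** 2) - c_s**2 - 1j * t[~early] * p.detuning
    ) - np.exp(-2.0 * x[~early] ** 2) * wofz(c_s + 1j * x[~early])
    out = pref * np.real(bracket)
    return out if out.size > 1 else out[0]


def probability_region(
    level: float,
    t_over_tau: np.ndarray | None = None,
    tau_omega: np.ndarray | None = None,
):
    """Smallest region of (t/tau, tau*Omega) holding ``level`` of the rate mass.

    The clamped-positive excitation rate is evaluated in reduced coordinates
    (where its shape is parameter-free) on a rectangular grid; cells are
    accumulated in order of decreasing rate until the requested mass
    fraction is reached.  Returns ``(t_over_tau, tau_omega, mask, rate)``
    where ``mask[i, j]`` marks grid cells inside the region.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    if t_over_tau is None:
        t_over_tau = np.linspace(-5.0, 8.0, 261)
    if tau_omega is None:
        tau_omega = np.linspace(-4.0, 4.0, 201)
    p_unit = TwoLevelParams(mu=1.0, e0=1.0, tau=1.0, detuning=0.0)
    rate = np.empty((t_over_tau.size, tau_omega.size))
    for j, om in enumerate(tau_omega):
        pj = dataclasses.replace(p_unit, detuning=float(om))
        rate[:, j] = excitation_rate(pj, t_over_tau)
    pos = np.clip(rate, 0.0, None)
    order = np.argsort(pos.ravel())[::-1]
    csum = np.cumsum(pos.ravel()[order])
    total = csum[-1]
    n_in = int(np.searchsorted(csum, level * total)) + 1
    mask = np.zeros(pos.size, dtype=bool)
    mask[order[:n_in]] = True
    return t_over_tau, tau_omega, mask.reshape(pos.shape), rate


def region_contains(t_over_tau_pts, tau_omega_pts, region) -> np.ndarray:
    """Membership of scattered points in a :func:`probability_region` mask."""
    tt, om, mask, _ = region
    it = np.clip(np.searchsorted(tt, t_over_tau_pts) - 1, 0, tt.size - 2)
    io = np.clip(np.searchsorted(om, tau_omega_pts) - 1, 0, om.size - 2)
    inside_box = (
        (t_over_tau_pts >= tt[0]) & (t_over_tau_pts <= tt[-1])
        & (tau_omega_pts >= om[0]) & (tau_omega_pts <= om[-1])
    )
    return inside_box & mask[it, io]
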