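"""Field-free 1D trajectory surface hopping on the adiabatic surfaces.

Nuclei follow velocity-Verlet dynamics on the active adiabatic surface;
the electronic coefficients are propagated in the global diabatic frame
(the 1D analytic models provide an exact diabatic basis, so the
local-diabatization overlaps between consecutive adiabatic frames are the
analytic rotation matrices and the propagation is manifestly independent of
adiabatic sign conventions).  Hops are decided once per nuclear step from
global-flux (GFSH) probabilities; accepted hops rescale the velocity along
itself to conserve total energy, frustrated hops leave it untouched.  An
energy-based decoherence correction damps inactive amplitudes each step.

The swarm driver is vectorized over trajectories; :func:`step` exposes the
same kernel for a single trajectory.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .models import DiabaticModel, adiabatize
from .observables import EnsembleObservables
from .units import fs_to_au

__all__ = [
    "TSHState",
    "TSHOptions",
    "TrajectoryEnsemble",
    "step",
    "run_swarm",
    "time_shifted_observables",
    "total_energy",
]


@dataclasses.dataclass
class TSHState:
    """Single-trajectory state; coefficients are adiabatic."""

    r: float
    v: float
    active: int
    coefficients: np.ndarray
    time: float = 0.0


@dataclasses.dataclass
class TSHOptions:
    """Numerical knobs of the hopping driver.

    ``decoherence_c`` is the energy-based decoherence parameter (hartree);
    ``decoherence_order`` applies the damping after or before the hop
    decision.  Frustrated hops never reverse the velocity.
    """

    n_substeps: int = 25
    decoherence_c: float = 0.1
    decoherence_order: str = "after_hop"   # "after_hop" | "before_hop" | "off"
    fd_step: float = 1e-3                  # bohr, force finite difference


def total_energy(r, v, active, model: DiabaticModel):
    """Kinetic plus active-surface potential energy (hartree)."""
    energies, _, _ = adiabatize(model, r)
    e_act = np.take_along_axis(
        np.atleast_2d(energies), np.atleast_1d(active)[:, None], axis=1
    )[:, 0]
    ke = 0.5 * model.reduced_mass * np.asarray(v) ** 2
    out = ke + e_act
    return float(out[0]) if np.isscalar(r) or np.ndim(r) == 0 else out


# ---------------------------------------------------------------------------
# vectorized kernel
# ---------------------------------------------------------------------------


def _adiabatic(model, r):
    e, u, _ = adiabatize(model, r)
    return e, u


def _forces(model, r, active, h):
    ep, _, _ = adiabatize(model, r + h)
    em, _, _ = adiabatize(model, r - h)
    de = (ep - em) / (2.0 * h)
    rows = np.arange(r.size)
    return -de[rows, active]


def _el_substeps(model, c_dia, r_from, r_to, dt_sub, n_sub):
    """Propagate diabatic coefficients along a linear R(t) path."""
    c0 = c_dia[:, 0]
    c1 = c_dia[:, 1]
    for i in range(n_sub):
        frac = (i + 0.5) / n_sub
        rm = r_from + frac * (r_to - r_from)
        vm = model.v(rm)
        a = vm[..., 0, 0]
        b = vm[..., 1, 1]
        cpl = vm[..., 0, 1]
        mean = 0.5 * (a + b)
        half = 0.5 * (a - b)
        w = np.sqrt(half**2 + cpl**2)
        th = w * dt_sub
        sinc = np.where(w > 0, np.sin(th) / np.where(w > 0, w, 1.0), dt_sub)
        ph = np.exp(-1j * mean * dt_sub)
        u00 = ph * (np.cos(th) - 1j * sinc * half)
        u11 = ph * (np.cos(th) + 1j * sinc * half)
        u01 = ph * (-1j * sinc * cpl)
        c0, c1 = u00 * c0 + u01 * c1, u01 * c0 + u11 * c1
    return np.stack([c0, c1], axis=1)


def _decohere(c_ad, active, energies, ke, dt, c_param):
    """Energy-based decoherence: damp inactive amplitudes, renormalize."""
    n, nst = c_ad.shape
    rows = np.arange(n)
    e_act = energies[rows, active]
    factor = np.ones_like(energies)
    for s in range(nst):
        gap = np.abs(energies[:, s] - e_act)
        tau = np.where(gap > 0, (1.0 + c_param / np.maximum(ke, 1e-12)) /
                       np.where(gap > 0, gap, 1.0), np.inf)
        factor[:, s] = np.where(s == active, 1.0, np.exp(-dt / tau))
    c_new = c_ad * factor
    p_act = np.abs(c_new[rows, active]) ** 2
    p_rest = np.sum(np.abs(c_new) ** 2, axis=1) - p_act
    scale = np.where(p_act > 0, np.sqrt(np.clip(1.0 - p_rest, 0.0, None) /
                                        np.where(p_act > 0, p_act, 1.0)), 1.0)
    c_new[rows, active] *= scale
    return c_new


def _gfsh_step(p_prev, p_next, active):
    rows = np.arange(p_prev.shape[0])
    dp = p_next - p_prev
    gain = np.clip(dp, 0.0, None)
    denom = gain.sum(axis=1)
    pa_prev = p_prev[rows, active]
    pa_next = p_next[rows, active]
    leave = np.where(pa_prev > 0,
                     np.clip(1.0 - pa_next / np.where(pa_prev > 0, pa_prev, 1.0),
                             0.0, 1.0), 0.0)
    split = gain / np.where(denom > 0, denom, 1.0)[:, None]
    split[denom <= 0] = 0.0
    probs = leave[:, None] * split
    probs[rows, active] = 0.0
    return probs


def _swarm_step(model, opt, dt, r, v, active, c_dia, e_t, u_t, rdraw, alive,
                frustrated_counter):
    """Advance alive trajectories one nuclear step in place.

    Returns updated (e, u) caches and a hop record list
    ``(index, from, to, frustrated)``.
    """
    m = model.reduced_mass
    idx = np.nonzero(alive)[0]
    if idx.size == 0:
        return e_t, u_t, []
    h = opt.fd_step
    rows = idx

    f1 = _forces(model, r[rows], active[rows], h)
    a1 = f1 / m
    r_new = r[rows] + v[rows] * dt + 0.5 * a1 * dt**2

    # trajectories leaving the model domain terminate (dissociation / wall)
    lo, hi = model.domain
    inside = (r_new > lo + 2 * h) & (r_new < hi - 2 * h)
    dead_now = rows[~inside]
    alive[dead_now] = False
    rows = rows[inside]
    if rows.size == 0:
        return e_t, u_t, []
    r_new = r_new[inside]
    a1 = a1[inside]

    f2 = _forces(model, r_new, active[rows], h)
    v_new = v[rows] + 0.5 * (a1 + f2 / m) * dt

    # electronic propagation along the linear nuclear path
    c_new = _el_substeps(model, c_dia[rows], r[rows], r_new,
                         dt / opt.n_substeps, opt.n_substeps)
    e_new, u_new = _adiabatic(model, r_new)

    # adiabatic populations before/after for the flux probabilities
    c_ad_prev = np.einsum("kda,kd->ka", u_t[rows], c_dia[rows])
    c_ad_new = np.einsum("kda,kd->ka", u_new, c_new)
    p_prev = np.abs(c_ad_prev) ** 2
    p_next = np.abs(c_ad_new) ** 2

    act = active[rows]
    ke = 0.5 * m * v_new**2

    if opt.decoherence_order == "before_hop":
        c_ad_new = _decohere(c_ad_new, act, e_new, ke, dt, opt.decoherence_c)
        p_next = np.abs(c_ad_new) ** 2

    probs = _gfsh_step(p_prev, p_next, act)
    cum = np.cumsum(probs, axis=1)
    below = rdraw[rows, None] <= cum
    target = np.argmax(below, axis=1)
    hopped = below.any(axis=1)

    hops = []
    sub = np.arange(rows.size)
    for i in sub[hopped]:
        de_hop = e_new[i, target[i]] - e_new[i, act[i]]
        if ke[i] >= de_hop:
            direction = 1.0 if v_new[i] >= 0 else -1.0
            v_new[i] = direction * np.sqrt(2.0 * (ke[i] - de_hop) / m)
            hops.append((int(rows[i]), int(act[i]), int(target[i]), False))
            act[i] = target[i]
            ke[i] = 0.5 * m * v_new[i] ** 2
        else:
            frustrated_counter[rows[i]] += 1
            hops.append((int(rows[i]), int(act[i]), int(target[i]), True))

    if opt.decoherence_order == "after_hop":
        c_ad_new = _decohere(c_ad_new, act, e_new, ke, dt, opt.decoherence_c)

    c_new = np.einsum("kda,ka->kd", u_new, c_ad_new)

    r[rows] = r_new
    v[rows] = v_new
    active[rows] = act
    c_dia[rows] = c_new
    e_t[rows] = e_new
    u_t[rows] = u_new
    return e_t, u_t, hops


def step(
    state: TSHState,
    model: DiabaticModel,
    dt: float,
    n_substeps: int = 25,
    seed_stream: np.random.Generator | None = None,
    options: TSHOptions | None = None,
) -> TSHState:
    """Advance a single trajectory by one nuclear time step (au)."""
    if dt <= 0 or n_substeps < 1:
        raise ValueError("dt must be positive and n_substeps >= 1")
    opt = options or TSHOptions()
    opt = dataclasses.replace(opt, n_substeps=n_substeps)
    rng = seed_stream or np.random.default_rng(0)

    r = np.array([state.r], dtype=float)
    v = np.array([state.v], dtype=float)
    active = np.array([state.active], dtype=int)
    e_t, u_t = _adiabatic(model, r)
    c_ad = np.asarray(state.coefficients, dtype=complex)[None, :]
    c_dia = np.einsum("kda,ka->kd", u_t, c_ad)
    alive = np.array([True])
    frustrated = np.zeros(1, dtype=int)
    rdraw = np.array([1.0 - rng.random()])
    _swarm_step(model, opt, dt, r, v, active, c_dia, e_t, u_t, rdraw, alive,
                frustrated)
    if not alive[0]:
        raise RuntimeError("trajectory left the model domain")
    e_t, u_t = _adiabatic(model, r)
    c_ad = np.einsum("kda,kd->ka", u_t, c_dia)
    return TSHState(
        r=float(r[0]), v=float(v[0]), active=int(active[0]),
        coefficients=c_ad[0], time=state.time + dt,
    )


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Recorded swarm: arrays indexed (trajectory, recorded step)."""

    times: np.ndarray
    r: np.ndarray
    v: np.ndarray
    active: np.ndarray
    populations: np.ndarray        # adiabatic |c|^2, (n_k, n_t, 2)
    alive: np.ndarray              # bool mask, False once a trajectory exited
    geometry_ids: np.ndarray
    hops: list
    frustrated: np.ndarray
    dt: float

    @property
    def n_traj(self) -> int:
        return self.r.shape[0]


def run_swarm(
    selection,
    samples,
    model: DiabaticModel,
    dt_fs: float = 0.5,
    t_end_fs: float = 1600.0,
    seed: int = 0,
    options: TSHOptions | None = None,
    max_trajectories: int | None = None,
) -> TrajectoryEnsemble:
    """Propagate one field-free trajectory per accepted initial condition.

    Accepted entries of ``selection`` are matched to their phase-space
    samples by geometry id; trajectory ``k`` starts at ``(R_k, v_k)`` in its
    selected state with coefficients ``c_alpha(0) = delta``.  Per-trajectory
    hopping randomness is keyed by ``(seed, geometry_id)``, so a trajectory
    is bitwise reproducible regardless of which ensemble it is run in.
    """
    opt = options or TSHOptions()
    dt = fs_to_au(dt_fs)
    n_steps = int(round(fs_to_au(t_end_fs) / dt))
    by_id = {s.index: s for s in samples}
    accepted = [s for s in selection if s.accepted]
    if max_trajectories is not None:
        accepted = accepted[:max_trajectories]
    n_k = len(accepted)
    times = dt * np.arange(n_steps + 1)
    if n_k == 0:
        empty = np.empty((0, n_steps + 1))
        return TrajectoryEnsemble(
            times=times, r=empty, v=empty.copy(),
            active=np.empty((0, n_steps + 1), dtype=int),
            populations=np.empty((0, n_steps + 1, 2)),
            alive=np.empty((0, n_steps + 1), dtype=bool),
            geometry_ids=np.empty(0, dtype=int), hops=[],
            frustrated=np.empty(0, dtype=int), dt=dt,
        )

    r = np.array([by_id[s.geometry_id].r for s in accepted])
    v = np.array([by_id[s.geometry_id].v for s in accepted])
    active = np.array([s.state for s in accepted], dtype=int)
    gids = np.array([s.geometry_id for s in accepted])

    e_t, u_t = _adiabatic(model, r)
    c_dia = np.take_along_axis(u_t, active[:, None, None], axis=2)[:, :, 0].astype(
        complex
    )
    alive = np.ones(n_k, dtype=bool)
    frustrated = np.zeros(n_k, dtype=int)

    rmat = np.empty((n_k, n_steps))
    for i, g in enumerate(gids):
        rng = np.random.default_rng(np.random.SeedSequence((seed, int(g))))
        rmat[i] = 1.0 - rng.random(n_steps)

    rec_r = np.empty((n_k, n_steps + 1))
    rec_v = np.empty((n_k, n_steps + 1))
    rec_active = np.empty((n_k, n_steps + 1), dtype=int)
    rec_pop = np.empty((n_k, n_steps + 1, 2))
    rec_alive = np.empty((n_k, n_steps + 1), dtype=bool)
    all_hops = []

    def record(j):
        rec_r[:, j] = r
        rec_v[:, j] = v
        rec_active[:, j] = active
        c_ad = np.einsum("kda,kd->ka", u_t, c_dia)
        rec_pop[:, j] = np.abs(c_ad) ** 2
        rec_alive[:, j] = alive

    record(0)
    for j in range(n_steps):
        e_t, u_t, hops = _swarm_step(
            model, opt, dt, r, v, active, c_dia, e_t, u_t, rmat[:, j], alive,
            frustrated,
        )
        all_hops.extend([(times[j + 1],) + h for h in hops])
        record(j + 1)
    return TrajectoryEnsemble(
        times=times, r=rec_r, v=rec_v, active=rec_active, populations=rec_pop,
        alive=rec_alive, geometry_ids=gids, hops=all_hops, frustrated=frustrated,
        dt=dt,
    )


def time_shifted_observables(
    ensemble: TrajectoryEnsemble,
    selection=None,
    state: int = 1,
    bin_fs: float | None = None,
) -> EnsembleObservables:
    """Ensemble observables with each trajectory shifted by its start time.

    Trajectory ``k`` contributes at ``t + t'_k``; the output grid is the
    recording grid extended to cover all shifts (``bin_fs`` may coarsen it,
    but must be a multiple of the recording step, as must every ``t'_k``).
    At each output time, ``<R>`` and ``<dR>`` run over the alive
    trajectories whose active state equals ``state``; the reported
    population is the fraction of contributing trajectories in that state.
    """
    dt = ensemble.dt
    if bin_fs is None:
        every = 1
    else:
        ratio = fs_to_au(bin_fs) / dt
        if abs(ratio - round(ratio)) > 1e-8 or round(ratio) < 1:
            raise ValueError("bin must be a multiple of the recording step")
        every = int(round(ratio))

    if selection is None:
        shifts_t = np.zeros(ensemble.n_traj)
    else:
        by_id = {s.geometry_id: s for s in selection if s.accepted}
        shifts_t = np.array(
            [by_id[g].t_start for g in ensemble.geometry_ids]
        )
    steps = shifts_t / dt
    if np.max(np.abs(steps - np.round(steps)), initial=0.0) > 1e-6:
        raise ValueError("start times must be multiples of the recording step")
    shifts = np.round(steps).astype(int)

    n_k, n_t = ensemble.r.shape
    lo = int(shifts.min(initial=0))
    hi = int(shifts.max(initial=0)) + n_t - 1
    n_out = hi - lo + 1
    cnt_state = np.zeros(n_out)
    cnt_alive = np.zeros(n_out)
    s_r = np.zeros(n_out)
    s_r2 = np.zeros(n_out)
    for k in range(n_k):
        o = shifts[k] - lo
        sel = ensemble.alive[k] & (ensemble.active[k] == state)
        cnt_alive[o:o + n_t] += ensemble.alive[k]
        cnt_state[o:o + n_t] += sel
        s_r[o:o + n_t] += np.where(sel, ensemble.r[k], 0.0)
        s_r2[o:o + n_t] += np.where(sel, ensemble.r[k] ** 2, 0.0)

    times = dt * np.arange(lo, hi + 1)
    valid = cnt_state > 0
    r_mean = np.full(n_out, np.nan)
    r_std = np.full(n_out, np.nan)
    r_mean[valid] = s_r[valid] / cnt_state[valid]
    var = s_r2[valid] / cnt_state[valid] - r_mean[valid] ** 2
    r_std[valid] = np.sqrt(np.clip(var, 0.0, None))
    pop = np.divide(cnt_state, cnt_alive, out=np.zeros(n_out),
                    where=cnt_alive > 0)
    obs = EnsembleObservables(
        times=times[::every], r_mean=r_mean[::every], r_std=r_std[::every],
        population=pop[::every], valid=valid[::every],
        label=f"tsh:S{state}",
    )
    return obs
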