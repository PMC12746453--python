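"""Initial-state and start-time selection: the heart of the EOE scheme.

Given frozen-nuclei population traces, the total leave-probability of the
initial state is accumulated per trace; its global maximum over the
ensemble, P_max, renormalizes all excited-state populations.  Global-flux
surface hopping (GFSH) probabilities computed from the renormalized
populations are then swept stochastically through every stored step of
every trace; the state of the *last* hop and its time become the initial
electronic state and the start time of the subsequent field-free
surface-hopping trajectory.  Traces without hops, or whose last hop returns
to the initial state (transient off-resonance population), are rejected.

The module also implements the conventional "vertical" window selection
for comparison.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .eod import EnsemblePopulations, PopulationTrace
from .models import DiabaticModel, adiabatize
from .units import HARTREE_EV, fs_to_au

__all__ = [
    "SelectionResult",
    "RenormalizedEnsemble",
    "leave_probability",
    "total_probability",
    "renormalize",
    "gfsh_probabilities",
    "renormalized_gfsh",
    "select_initial_conditions",
    "vertical_select",
]


@dataclasses.dataclass
class SelectionResult:
    """Outcome of the stochastic selection for one initial condition."""

    geometry_id: int
    accepted: bool
    state: int | None = None          # alpha_k(0)
    t_start: float | None = None      # au, relative to the stored time origin
    hop_history: list = dataclasses.field(default_factory=list)
    p_tot: float = 0.0

    def __post_init__(self):
        if self.accepted and (self.state is None or self.t_start is None):
            raise ValueError("accepted results need a state and a start time")
        if not self.accepted and (self.state is not None or self.t_start is not None):
            raise ValueError("rejected results carry no state or start time")


def _pops_of(trace) -> np.ndarray:
    if isinstance(trace, PopulationTrace):
        return trace.populations
    return np.asarray(trace)


def leave_probability(trace, t_index: int, beta: int | None = None) -> float:
    """Per-step probability to leave the initial state between stored steps.

    ``P(t) = max(0, 1 - |c_beta(t+dt)|^2 / |c_beta(t)|^2)``.
    """
    pops = _pops_of(trace)
    b = trace.initial_state if isinstance(trace, PopulationTrace) and beta is None \
        else (beta or 0)
    prev = pops[t_index, b]
    nxt = pops[t_index + 1, b]
    if prev <= 0.0:
        raise ZeroDivisionError(
            "initial-state population vanished; leave probability undefined"
        )
    return float(max(0.0, 1.0 - nxt / prev))


def total_probability(trace, beta: int | None = None) -> float:
    """Total leave probability P_tot = 1 - prod_t min(1, ratio).

    For a monotonically decaying initial-state population this telescopes to
    the final excited population; transient revivals are blocked by the min,
    so population that returns still counts as having left once.
    """
    pops = _pops_of(trace)
    b = trace.initial_state if isinstance(trace, PopulationTrace) and beta is None \
        else (beta or 0)
    pb = pops[:, b]
    ratios = np.minimum(1.0, pb[1:] / pb[:-1])
    return float(1.0 - np.prod(ratios))


@dataclasses.dataclass
class RenormalizedEnsemble:
    """Renormalized populations of an ensemble, plus P_max bookkeeping."""

    times: np.ndarray
    populations: np.ndarray           # (n_k, n_t, n_states), renormalized
    raw_populations: np.ndarray
    p_tot: np.ndarray                 # (n_k,)
    p_max: float
    beta: int
    geometry_ids: np.ndarray


def renormalize(traces) -> RenormalizedEnsemble:
    """Apply the P_max renormalization to an ensemble of traces.

    Accepts a list of :class:`PopulationTrace` or an
    :class:`EnsemblePopulations`.  Excited-state populations are scaled by
    ``1 / P_max``; the initial-state population is rebuilt as one minus
    their sum, so per-step population differences of *all* states scale
    exactly by ``1 / P_max``.  Raises if no trace transfers any population
    (``P_max = 0``: nothing is selectable).
    """
    if isinstance(traces, EnsemblePopulations):
        pops = traces.populations
        times = traces.times
        beta = traces.initial_state
        gids = traces.geometry_ids
    else:
        traces = list(traces)
        if not traces:
            raise ValueError("need at least one trace")
        beta = traces[0].initial_state
        times = traces[0].times
        pops = np.stack([t.populations for t in traces])
        gids = np.array([t.geometry_id for t in traces])

    pb = pops[:, :, beta]
    ratios = np.minimum(1.0, pb[:, 1:] / pb[:, :-1])
    p_tot = 1.0 - np.prod(ratios, axis=1)
    p_max = float(p_tot.max())
    if p_max <= 0.0:
        raise ValueError(
            "no initial condition transferred population: "
            "no selectable initial conditions (P_max = 0)"
        )
    renorm = pops / p_max
    # closed form of the rescaled initial-state population; algebraically
    # identical to one-minus-the-excited-sum but keeps the per-step
    # difference scaling exact to machine precision even when the raw norm
    # carries propagator roundoff
    renorm[:, :, beta] = (pops[:, :, beta] - (1.0 - p_max)) / p_max
    return RenormalizedEnsemble(
        times=times,
        populations=renorm,
        raw_populations=pops,
        p_tot=p_tot,
        p_max=p_max,
        beta=beta,
        geometry_ids=gids,
    )


def gfsh_probabilities(pops_prev, pops_next, active: int) -> np.ndarray:
    """Global-flux surface-hopping probabilities for one step.

    ``P_active->alpha = (1 - p_act(t+dt)/p_act(t)) *
    dp_alpha / sum_gamma max(0, dp_gamma)`` with the active-active entry and
    all negative probabilities set to zero.  Broadcasts over leading axes.
    """
    prev = np.asarray(pops_prev, dtype=float)
    nxt = np.asarray(pops_next, dtype=float)
    dp = nxt - prev
    gain = np.clip(dp, 0.0, None)
    denom = gain.sum(axis=-1, keepdims=True)
    p_act_prev = prev[..., active]
    p_act_next = nxt[..., active]
    with np.errstate(divide="ignore", invalid="ignore"):
        leave = np.where(
            p_act_prev > 0.0,
            np.clip(1.0 - p_act_next / np.where(p_act_prev > 0, p_act_prev, 1.0),
                    0.0, 1.0),
            0.0,
        )
        split = np.where(denom > 0.0, gain / np.where(denom > 0, denom, 1.0), 0.0)
    probs = leave[..., None] * split
    probs[..., active] = 0.0
    return probs


def renormalized_gfsh(
    ensemble: RenormalizedEnsemble, k: int, active: int, t_index: int
) -> np.ndarray:
    """GFSH probabilities at one stored step of one renormalized trace.

    For ``active == beta`` this is the renormalized prescription (the
    prefactor uses the renormalized initial-state population, i.e. the raw
    population shifted by ``1 - P_max``); for any other active state the
    ``1/P_max`` factors cancel and the plain flux formula on the raw
    populations is recovered.
    """
    pops = ensemble.populations[k]
    return gfsh_probabilities(pops[t_index], pops[t_index + 1], active)


def _hop_index(probs: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized cumulative-interval draw: returns target state or -1."""
    cum = np.cumsum(probs, axis=-1)
    below = r[:, None] <= cum
    target = np.argmax(below, axis=-1)
    hopped = below.any(axis=-1)
    return np.where(hopped, target, -1)


def select_initial_conditions(
    ensemble: RenormalizedEnsemble,
    seed: int,
    tsh_dt_fs: float = 0.5,
    t_origin: float = 0.0,
    multi_hop_warn_fraction: float = 0.01,
) -> list[SelectionResult]:
    """Stochastic assignment of initial state and start time per trace.

    Each trace is swept once over all stored steps.  One uniform random
    number ``r in (0, 1]`` is drawn per stored step from a generator keyed
    by ``(seed, k)`` (so every initial condition owns an independent,
    reproducible stream, drawn even at steps with all-zero probabilities to
    keep the stream stable).  Hops follow the cumulative-interval rule;
    after a hop the probabilities for the remaining steps are those for
    leaving the new active state.  The last hop determines the accepted
    state and start time; a last hop back to the initial state, or no hop
    at all, rejects the trace.  Start times are reported relative to
    ``t_origin`` (pulse center) and are multiples of the stored step, which
    must be commensurate with the nuclear time step ``tsh_dt_fs``.
    """
    times = ensemble.times
    dt_stored = times[1] - times[0]
    tsh_dt = fs_to_au(tsh_dt_fs)
    n_per = dt_stored / tsh_dt
    if abs(n_per - round(n_per)) > 1e-8 or round(n_per) < 1:
        raise ValueError(
            "stored trace spacing must be an integer multiple of the TSH step"
        )
    shifted = (times - t_origin) / tsh_dt
    if np.max(np.abs(shifted - np.round(shifted))) > 1e-8:
        raise ValueError("stored times do not fall on the TSH time grid")

    pops = ensemble.populations
    n_k, n_t, n_states = pops.shape
    beta = ensemble.beta

    rmat = np.empty((n_k, n_t - 1))
    for k in range(n_k):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
        rmat[k] = 1.0 - rng.random(n_t - 1)   # uniform on (0, 1]

    active = np.full(n_k, beta, dtype=int)
    last_state = np.full(n_k, -1, dtype=int)
    last_time = np.full(n_k, np.nan)
    n_hops = np.zeros(n_k, dtype=int)
    histories: list[list] = [[] for _ in range(n_k)]

    rows = np.arange(n_k)
    for t in range(n_t - 1):
        prev = pops[:, t, :]
        nxt = pops[:, t + 1, :]
        dp = nxt - prev
        gain = np.clip(dp, 0.0, None)
        denom = gain.sum(axis=1)
        p_prev = prev[rows, active]
        p_next = nxt[rows, active]
        safe_prev = np.where(p_prev > 0, p_prev, 1.0)
        leave = np.where(p_prev > 0, np.clip(1.0 - p_next / safe_prev, 0.0, 1.0), 0.0)
        split = gain / np.where(denom > 0, denom, 1.0)[:, None]
        split[denom <= 0] = 0.0
        probs = leave[:, None] * split
        probs[rows, active] = 0.0
        target = _hop_index(probs, rmat[:, t])
        hop = target >= 0
        if np.any(hop):
            t_hop = times[t + 1] - t_origin
            for k in np.nonzero(hop)[0]:
                histories[k].append((float(t_hop), int(active[k]), int(target[k])))
            active[hop] = target[hop]
            last_state[hop] = target[hop]
            last_time[hop] = times[t + 1] - t_origin
            n_hops[hop] += 1

    many = float(np.mean(n_hops >= 3))
    if many > multi_hop_warn_fraction:
        warnings.warn(
            f"{100 * many:.1f}% of traces performed three or more hops; "
            "the frozen-nuclei picture may be strained"
        )

    results = []
    for k in range(n_k):
        accepted = last_state[k] >= 0 and last_state[k] != beta
        results.append(
            SelectionResult(
                geometry_id=int(ensemble.geometry_ids[k]),
                accepted=bool(accepted),
                state=int(last_state[k]) if accepted else None,
                t_start=float(last_time[k]) if accepted else None,
                hop_history=histories[k],
                p_tot=float(ensemble.p_tot[k]),
            )
        )
    return results


def vertical_select(
    samples,
    model: DiabaticModel,
    window_ev: tuple[float, float],
    mode: str = "intensity",
    seed: int = 0,
) -> list[SelectionResult]:
    """Sudden ("vertical") window selection, for comparison with EOE.

    Excitation probabilities are ``f_osc / dE^2`` (``mode='intensity'``,
    constant spectral intensity) or ``f_osc / dE`` (``mode='flux'``,
    constant photon flux), computed only for transitions inside the energy
    window and normalized to the largest in-window probability of the whole
    set.  Acceptance is decided per sample with a generator keyed by
    ``(seed, k)``; accepted conditions start at t' = 0.
    """
    if mode not in ("intensity", "flux"):
        raise ValueError("mode must be 'intensity' or 'flux'")
    lo, hi = window_ev
    r = np.array([s.r for s in samples])
    energies, _, tdm_ad = adiabatize(model, r)
    de = energies[:, 1] - energies[:, 0]
    mu2 = tdm_ad[:, 0, 1] ** 2
    fosc = (2.0 / 3.0) * de * mu2
    de_ev = de * HARTREE_EV
    in_window = (de_ev >= lo) & (de_ev <= hi)

    power = 2.0 if mode == "intensity" else 1.0
    prob = np.where(in_window, fosc / de**power, 0.0)
    pmax = prob.max()
    results = []
    if pmax <= 0.0:
        return [
            SelectionResult(geometry_id=s.index, accepted=False) for s in samples
        ]
    prob = prob / pmax
    for k, s in enumerate(samples):
        rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
        u = rng.random()
        if in_window[k] and u < prob[k]:
            results.append(
                SelectionResult(
                    geometry_id=s.index, accepted=True, state=1, t_start=0.0,
                    p_tot=float(prob[k]),
                )
            )
        else:
            results.append(
                SelectionResult(
                    geometry_id=s.index, accepted=False, p_tot=float(prob[k])
                )
            )
    return results
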