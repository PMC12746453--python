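"""End-to-end orchestration of the excitation-scheme study.

Chains the stages -- ground-state relaxation, Wigner sampling,
electron-only dynamics, renormalized selection, surface hopping, and the
grid quantum-dynamics reference -- behind a single configuration object,
so that the desk-scale study (three pulse energies x three durations plus
the vertical-window comparisons) is reproducible from named seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import eod, qdgrid, sampling, select, tsh1d
from .models import DiabaticModel, nai_model
from .pulses import LaserPulse, from_intensity_fwhm
from .units import fs_to_au

__all__ = ["RunConfig", "ground_state_samples", "run_eoe", "run_vertical",
           "run_qd_reference", "run_tsh"]

#: Central energies (eV) of the study pulses.
STUDY_ENERGIES_EV = {"low": 3.68, "mid": 3.89, "high": 4.15}
#: Intensity FWHMs (fs) of the study pulses.
STUDY_DURATIONS_FS = (20.0, 100.0, 500.0)
#: Vertical selection windows (eV) used for comparison.
STUDY_WINDOWS_EV = {
    "low": (3.65, 3.71), "mid": (3.86, 3.92), "high": (4.12, 4.18),
}


@dataclasses.dataclass
class RunConfig:
    """Seeds, step sizes and ensemble size of one pipeline run."""

    n_samples: int = 10_000
    sampling_seed: int = 1
    selection_seed: int = 2
    tsh_seed: int = 3
    dt_eod_fs: float = 0.0625
    eod_stride: int = 8
    dt_tsh_fs: float = 0.5
    dt_qd_fs: float = 0.1
    scheme: str = "eoe"                  # "eoe" | "vertical"
    window_ev: tuple | None = None

    def __post_init__(self):
        if min(self.dt_eod_fs, self.dt_tsh_fs, self.dt_qd_fs) <= 0:
            raise ValueError("all time steps must be positive")
        stored = self.eod_stride * self.dt_eod_fs
        ratio = stored / self.dt_tsh_fs
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                "eod stride * dt_eod must be a multiple of dt_tsh so that "
                "start times land on the nuclear time grid"
            )


def study_pulse(energy: str | float, duration_fs: float, e0: float = 0.001) -> LaserPulse:
    """One of the study pulses (center shifted to t = 0, axis-polarized)."""
    ev = STUDY_ENERGIES_EV.get(energy, energy)
    return from_intensity_fwhm(duration_fs, omega0_ev=float(ev), e0=e0)


def ground_state_samples(
    model: DiabaticModel | None = None,
    config: RunConfig | None = None,
    grid: np.ndarray | None = None,
):
    """Relax the vibrational ground state and draw the Wigner ensemble.

    Returns ``(model, ground_wf, samples)``; all later stages reuse this
    one set of initial geometries/velocities.
    """
    model = model or nai_model()
    config = config or RunConfig()
    wf = qdgrid.imaginary_time_ground_state(model, grid=grid)
    dist = sampling.wigner_distribution(wf, mass=model.reduced_mass)
    samples = sampling.draw_samples(dist, config.n_samples, config.sampling_seed)
    return model, wf, samples


def run_eoe(samples, model, pulse: LaserPulse, config: RunConfig | None = None):
    """Electron-only dynamics + renormalized selection for one pulse.

    Returns ``(selection, renormalized_ensemble)``.
    """
    config = config or RunConfig()
    ens = eod.run_ensemble(
        samples, model, pulse,
        eod.EODConfig(dt_fs=config.dt_eod_fs, stride=config.eod_stride),
    )
    renorm = select.renormalize(ens)
    sel = select.select_initial_conditions(
        renorm, seed=config.selection_seed, tsh_dt_fs=config.dt_tsh_fs,
        t_origin=pulse.t_c,
    )
    return sel, renorm


def run_vertical(samples, model, window_ev, config: RunConfig | None = None):
    config = config or RunConfig()
    return select.vertical_select(
        samples, model, window_ev, seed=config.selection_seed
    )


def run_qd_reference(
    model, wf, pulse: LaserPulse, t_end_fs: float,
    config: RunConfig | None = None, grid_points: int | None = None,
    dt_fs: float | None = None,
):
    """Grid quantum dynamics driven by the explicit pulse, from ``wf``."""
    config = config or RunConfig()
    dt = fs_to_au(dt_fs if dt_fs is not None else config.dt_qd_fs)
    table = pulse.sample(dt, block=1)
    wf0 = dataclasses.replace(wf, time=float(table.times[0]))
    stride = max(1, int(round(fs_to_au(1.0) / dt)))
    return qdgrid.propagate(
        wf0, model, table, dt=dt, t_end=fs_to_au(t_end_fs), stride=stride
    )


def run_tsh(
    selection, samples, model, t_end_fs: float,
    config: RunConfig | None = None, max_trajectories: int | None = None,
):
    config = config or RunConfig()
    ens = tsh1d.run_swarm(
        selection, samples, model, dt_fs=config.dt_tsh_fs, t_end_fs=t_end_fs,
        seed=config.tsh_seed, max_trajectories=max_trajectories,
    )
    obs = tsh1d.time_shifted_observables(ens, selection)
    return ens, obs
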