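"""1D trajectory surface hopping: integrator, hopping, shifted averages."""

import numpy as np
import pytest

from eoexcite import tsh1d
from eoexcite.models import make_harmonic_fixture
from eoexcite.select import SelectionResult
from eoexcite.sampling import WignerSample
from eoexcite.tsh1d import (
    TSHOptions,
    TSHState,
    run_swarm,
    step,
    time_shifted_observables,
    total_energy,
)
from eoexcite.units import fs_to_au


def _selection(states_times):
    return [
        SelectionResult(geometry_id=k, accepted=True, state=s,
                        t_start=fs_to_au(t))
        for k, (s, t) in enumerate(states_times)
    ]


class TestStep:
    def test_uncoupled_surfaces_no_hops(self, harmonic):
        # zero diabatic coupling: pure vibration on the excited surface
        st = TSHState(r=10.3, v=0.0, active=1,
                      coefficients=np.array([0.0, 1.0], dtype=complex))
        rng = np.random.default_rng(0)
        for _ in range(200):
            st = step(st, harmonic, fs_to_au(0.5), seed_stream=rng)
        assert st.active == 1
        assert abs(st.coefficients[1]) ** 2 == pytest.approx(1.0, abs=1e-8)
        # bound harmonic motion stays near the upper minimum
        assert abs(st.r - (10.0 + harmonic.meta["displacement"])) < 0.5

    def test_rejects_bad_arguments(self, harmonic):
        st = TSHState(r=10.0, v=0.0, active=0,
                      coefficients=np.array([1.0, 0.0], dtype=complex))
        with pytest.raises(ValueError):
            step(st, harmonic, -1.0)

    def test_energy_drift_bound(self, nai, nai_samples):
        # field-free excited trajectory: total energy drifts < 1e-5 hartree
        # over 2000 fs between hops (re-baselined at each accepted hop)
        sel = _selection([(1, 0.0)])
        samples = [WignerSample(index=0, r=nai_samples[0].r, v=nai_samples[0].v)]
        ens = run_swarm(sel, samples, nai, t_end_fs=2000.0, seed=3)
        e = 0.5 * nai.reduced_mass * ens.v[0] ** 2
        from eoexcite.models import adiabatize
        pot, _, _ = adiabatize(nai, np.clip(ens.r[0], *nai.domain))
        rows = np.arange(ens.r.shape[1])
        e_tot = e + pot[rows, ens.active[0]]
        hop_steps = [int(round(h[0] / ens.dt)) for h in ens.hops]
        bounds = sorted({0, *hop_steps, ens.r.shape[1]})
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = e_tot[a:b][ens.alive[0][a:b]]
            if seg.size > 1:
                assert np.max(np.abs(seg - seg[0])) < 1e-5

    def test_electronic_propagation_matches_reference_integrator(self, nai):
        # same nuclear path, fine-step reference TDSE on the coefficients
        from scipy.integrate import solve_ivp

        dt = fs_to_au(0.5)
        r0, v0 = 5.0, 3e-4
        st = TSHState(r=r0, v=v0, active=1,
                      coefficients=np.array([0.0, 1.0], dtype=complex))
        # deterministic no-hop stream (probabilities are ~0 far from crossing)
        rng = np.random.default_rng(1)
        path = [st.r]
        for _ in range(40):
            st = step(st, nai, dt, seed_stream=rng)
            path.append(st.r)
        path = np.array(path)

        def rhs(t, y):
            c = y[:2] + 1j * y[2:]
            r = np.interp(t, dt * np.arange(path.size), path)
            h = nai.v(r)
            dc = -1j * (h @ c)
            return np.concatenate([dc.real, dc.imag])

        _, u0 = tsh1d._adiabatic(nai, np.array([r0]))
        c0 = u0[0][:, 1].astype(complex)
        sol = solve_ivp(rhs, (0, 40 * dt), np.concatenate([c0.real, c0.imag]),
                        rtol=1e-11, atol=1e-12, dense_output=True)
        c_ref = sol.y[:2, -1] + 1j * sol.y[2:, -1]
        _, u1 = tsh1d._adiabatic(nai, np.array([st.r]))
        c_ref_ad = u1[0].T @ c_ref
        # phases differ by the path discretization; populations must agree
        assert np.abs(np.abs(c_ref_ad) ** 2
                      - np.abs(st.coefficients) ** 2).max() < 1e-6


class TestRunSwarm:
    def test_empty_selection(self, nai, nai_samples):
        ens = run_swarm([], nai_samples[:5], nai, t_end_fs=5.0, seed=1)
        assert ens.n_traj == 0
        obs = time_shifted_observables(ens)
        assert not obs.valid.any()

    def test_identical_seeds_identical_hops(self, nai, nai_samples,
                                            selection_low20):
        kw = dict(t_end_fs=300.0, seed=3, max_trajectories=40)
        a = run_swarm(selection_low20, nai_samples, nai, **kw)
        b = run_swarm(selection_low20, nai_samples, nai, **kw)
        assert a.hops == b.hops
        assert np.array_equal(a.r, b.r)

    def test_seed_keyed_by_geometry_not_position(self, nai, nai_samples,
                                                 selection_low20):
        # a trajectory reproduces bitwise no matter which subset it runs in
        full = run_swarm(selection_low20, nai_samples, nai, t_end_fs=100.0,
                         seed=3, max_trajectories=12)
        acc = [s for s in selection_low20 if s.accepted][5:12]
        part = run_swarm(acc, nai_samples, nai, t_end_fs=100.0, seed=3)
        assert np.array_equal(full.r[5:12], part.r)

    def test_coefficient_norm_conserved(self, nai, nai_samples, selection_low20):
        ens = run_swarm(selection_low20, nai_samples, nai, t_end_fs=300.0,
                        seed=3, max_trajectories=30)
        norms = ens.populations.sum(axis=2)[ens.alive]
        assert np.max(np.abs(norms - 1.0)) < 1e-8

    def test_fewest_switches_consistency(self, nai, nai_samples,
                                         selection_low20):
        # without decoherence and before frustrated hops matter, the active-
        # state fraction tracks the mean electronic population
        opt = TSHOptions(decoherence_order="off")
        ens = run_swarm(selection_low20, nai_samples, nai, t_end_fs=400.0,
                        seed=3, max_trajectories=150, options=opt)
        assert ens.frustrated.sum() == 0
        frac = (ens.active == 1).mean(axis=0)
        pop = ens.populations[:, :, 1].mean(axis=0)
        n = ens.n_traj
        sigma = np.sqrt(np.maximum(pop * (1 - pop) / n, 1e-6))
        assert np.all(np.abs(frac - pop) < 5.0 * sigma + 0.02)

    def test_dissociating_trajectories_terminate_with_status(self, nai):
        # ground-state covalent channel: outward motion exits the domain
        sel = _selection([(1, 0.0)])
        samples = [WignerSample(index=0, r=5.0, v=0.0)]
        ens = run_swarm(sel, samples, nai, t_end_fs=2200.0, seed=11)
        if not ens.alive[0, -1]:
            exit_idx = np.argmin(ens.alive[0])
            assert ens.r[0, exit_idx - 1] > 30.0


class TestTimeShiftedObservables:
    @staticmethod
    def _synthetic_ensemble(shifts_fs, n_steps=400, dt_fs=0.5):
        """Identical sinusoidal 'trajectories' to shift against each other."""
        dt = fs_to_au(dt_fs)
        t = dt * np.arange(n_steps + 1)
        r = 10.0 + np.sin(2 * np.pi * t / fs_to_au(50.0))
        n = len(shifts_fs)
        return tsh1d.TrajectoryEnsemble(
            times=t,
            r=np.tile(r, (n, 1)),
            v=np.zeros((n, n_steps + 1)),
            active=np.ones((n, n_steps + 1), dtype=int),
            populations=np.tile([0.0, 1.0], (n, n_steps + 1, 1)),
            alive=np.ones((n, n_steps + 1), dtype=bool),
            geometry_ids=np.arange(n),
            hops=[], frustrated=np.zeros(n, dtype=int), dt=dt,
        )

    def test_zero_shifts_equal_unshifted(self):
        ens = self._synthetic_ensemble([0.0, 0.0])
        sel = _selection([(1, 0.0), (1, 0.0)])
        a = time_shifted_observables(ens, sel)
        b = time_shifted_observables(ens, None)
        assert np.allclose(a.r_mean[a.valid], b.r_mean[b.valid])

    def test_opposite_shifts_damp_oscillation(self):
        # +/- 10 fs shifts of identical 50 fs oscillations: the averaged
        # amplitude shrinks by cos(2 pi 10/50) relative to one trajectory
        ens = self._synthetic_ensemble([-10.0, 10.0])
        sel = _selection([(1, -10.0), (1, 10.0)])
        obs = time_shifted_observables(ens, sel)
        mid = obs.valid & (obs.times > fs_to_au(30)) & (obs.times < fs_to_au(170))
        amp = np.max(np.abs(obs.r_mean[mid] - 10.0))
        assert amp == pytest.approx(np.cos(2 * np.pi * 10.0 / 50.0), rel=1e-2)

    def test_incommensurate_bin_rejected(self):
        ens = self._synthetic_ensemble([0.0])
        with pytest.raises(ValueError, match="multiple"):
            time_shifted_observables(ens, None, bin_fs=0.7)

    def test_incommensurate_shift_rejected(self):
        ens = self._synthetic_ensemble([0.0])
        sel = _selection([(1, 0.13)])
        with pytest.raises(ValueError, match="multiples"):
            time_shifted_observables(ens, sel)

    def test_population_counts_active_fraction(self):
        ens = self._synthetic_ensemble([0.0, 0.0])
        ens.active[1, 200:] = 0  # one trajectory decays at step 200
        obs = time_shifted_observables(ens, None)
        assert obs.population[100] == 1.0
        assert obs.population[250] == 0.5
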