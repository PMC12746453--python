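"""Renormalization, flux probabilities and the stochastic selection."""

import numpy as np
import pytest

from eoexcite import select
from eoexcite.eod import EnsemblePopulations, PopulationTrace
from eoexcite.select import (
    gfsh_probabilities,
    leave_probability,
    renormalize,
    renormalized_gfsh,
    select_initial_conditions,
    total_probability,
    vertical_select,
)
from eoexcite.units import AUT_FS, fs_to_au


def _trace(populations, dt_fs=0.5):
    pops = np.asarray(populations, dtype=float)
    return PopulationTrace(
        geometry_id=0,
        times=np.arange(pops.shape[0]) * fs_to_au(dt_fs),
        populations=pops,
        coefficients=None,
        initial_state=0,
        polarization=np.array([0.0, 0.0, 1.0]),
    )


def _ensemble(list_of_pops, dt_fs=0.5):
    pops = np.asarray(list_of_pops, dtype=float)
    return EnsemblePopulations(
        times=np.arange(pops.shape[1]) * fs_to_au(dt_fs),
        populations=pops,
        initial_state=0,
        geometry_ids=np.arange(pops.shape[0]),
        orientations=np.tile([0.0, 0.0, 1.0], (pops.shape[0], 1)),
    )


def _random_traces(rng, n_k=40, n_t=60, scale=1e-3):
    """Weak-field-like random two-state traces (normalized rows)."""
    exc = scale * rng.random((n_k, n_t)) * np.linspace(0, 1, n_t)
    exc += 0.1 * scale * rng.standard_normal((n_k, n_t)) * scale
    exc = np.clip(exc, 0.0, 1.0)
    pops = np.stack([1.0 - exc, exc], axis=2)
    return pops


class TestLeaveAndTotalProbability:
    def test_constant_population_zero(self):
        tr = _trace([[1.0, 0.0]] * 5)
        assert leave_probability(tr, 2) == 0.0
        assert total_probability(tr) == 0.0

    def test_direct_arithmetic(self):
        tr = _trace([[1.0, 0.0], [0.998, 0.002], [0.002, 0.998]])
        assert leave_probability(tr, 0) == pytest.approx(0.002, rel=1e-12)
        assert leave_probability(tr, 1) == pytest.approx(1.0 - 0.002 / 0.998,
                                                         rel=1e-12)

    def test_growing_population_clamped(self):
        tr = _trace([[0.9, 0.1], [0.95, 0.05]])
        assert leave_probability(tr, 0) == 0.0

    def test_monotone_decay_telescopes(self):
        tr = _trace([[1.0, 0.0], [0.999, 0.001], [0.997, 0.003], [0.995, 0.005]])
        assert total_probability(tr) == pytest.approx(0.005, rel=1e-12)

    def test_revival_still_counts(self):
        tr = _trace([[1.0, 0.0], [0.99, 0.01], [1.0, 0.0]])
        assert total_probability(tr) == pytest.approx(0.01, rel=1e-12)

    def test_zero_population_raises(self):
        tr = _trace([[0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ZeroDivisionError):
            leave_probability(tr, 0)


class TestRenormalize:
    def test_max_trace_saturates(self):
        pops = [
            [[1.0, 0.0], [0.999, 0.001], [0.998, 0.002]],
            [[1.0, 0.0], [0.9995, 0.0005], [0.999, 0.001]],
        ]
        ren = renormalize(_ensemble(pops))
        assert ren.p_max == pytest.approx(0.002, rel=1e-12)
        # monotone decay: renormalized final excited population of the
        # maximal trace reaches one
        assert ren.populations[0, -1, 1] == pytest.approx(1.0, rel=1e-12)
        assert ren.populations[0, -1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_difference_scaling_identity(self, rng):
        # per-step differences of every state scale exactly by 1/P_max
        pops = _random_traces(rng)
        ren = renormalize(_ensemble(pops))
        lhs = np.diff(ren.populations, axis=1)
        rhs = np.diff(pops, axis=1) / ren.p_max
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_induction_inequality(self, rng):
        # 1 - P_max <= |c_beta(t)|^2 for every step of every trace
        pops = _random_traces(rng, n_k=100)
        ren = renormalize(_ensemble(pops))
        assert np.all(pops[:, :, 0] >= 1.0 - ren.p_max - 1e-12)

    def test_no_transfer_raises(self):
        pops = [[[1.0, 0.0]] * 4]
        with pytest.raises(ValueError, match="no selectable"):
            renormalize(_ensemble(pops))

    def test_accepts_trace_list(self, rng):
        pops = _random_traces(rng, n_k=3)
        traces = [_trace(pops[k]) for k in range(3)]
        ren = renormalize(traces)
        assert ren.p_max == renormalize(_ensemble(pops)).p_max


class TestGfsh:
    def test_two_state_flux(self):
        p = gfsh_probabilities([1.0, 0.0], [0.9, 0.1], active=0)
        assert p[1] == pytest.approx(0.1, rel=1e-12)
        assert p[0] == 0.0

    def test_unchanged_populations_zero(self):
        p = gfsh_probabilities([0.5, 0.5], [0.5, 0.5], active=0)
        assert np.all(p == 0.0)

    def test_three_state_flux_partition(self):
        p = gfsh_probabilities([1.0, 0.0, 0.0], [0.9, 0.075, 0.025], active=0)
        assert p[1] == pytest.approx(0.075, rel=1e-12)
        assert p[2] == pytest.approx(0.025, rel=1e-12)

    def test_negative_flux_zeroed(self):
        p = gfsh_probabilities([0.5, 0.3, 0.2], [0.4, 0.2, 0.4], active=0)
        assert p[1] == 0.0
        assert p[2] == pytest.approx(0.2, rel=1e-12)


class TestRenormalizedGfsh:
    def test_pmax_one_reduces_to_plain_gfsh(self):
        pops = [[[1.0, 0.0], [0.4, 0.6], [0.0, 1.0]]]
        ren = renormalize(_ensemble(pops))
        assert ren.p_max == pytest.approx(1.0)
        plain = gfsh_probabilities(pops[0][0], pops[0][1], active=0)
        assert np.allclose(renormalized_gfsh(ren, 0, 0, 0), plain, atol=1e-12)

    def test_enhancement_ratio_identity(self, rng):
        # P~ / P = |c_b|^2 / (|c_b|^2 - (1 - P_max)) wherever P > 0
        pops = _random_traces(rng, n_k=30)
        ens = _ensemble(pops)
        ren = renormalize(ens)
        for k in (0, 7, 19):
            for t in range(10, 40):
                plain = gfsh_probabilities(pops[k, t], pops[k, t + 1], active=0)
                tilde = renormalized_gfsh(ren, k, 0, t)
                if plain[1] > 1e-13:
                    expect = pops[k, t, 0] / (pops[k, t, 0] - (1.0 - ren.p_max))
                    assert tilde[1] / plain[1] == pytest.approx(expect, rel=1e-9)

    def test_probability_saturates_near_depletion(self):
        # as |c_b|^2 approaches 1 - P_max with ongoing decay, P~ -> 1
        pops = [
            [[1.0, 0.0], [0.9995, 0.0005], [0.999, 0.001]],
            [[1.0, 0.0], [0.99951, 0.00049], [0.99902, 0.00098]],
        ]
        ren = renormalize(_ensemble(pops))
        p_last = renormalized_gfsh(ren, 0, 0, 1)
        assert p_last[1] == pytest.approx(1.0, rel=1e-6)

    def test_excited_active_unaffected_by_renormalization(self, rng):
        pops = _random_traces(rng, n_k=5)
        ren = renormalize(_ensemble(pops))
        for t in (5, 25):
            raw = gfsh_probabilities(pops[2, t], pops[2, t + 1], active=1)
            til = renormalized_gfsh(ren, 2, 1, t)
            assert np.allclose(raw, til, atol=1e-12)


class TestSelection:
    def test_all_zero_probabilities_rejected(self):
        pops = [[[1.0, 0.0]] * 6, [[1.0, 0.0], [0.99, 0.01]] + [[0.99, 0.01]] * 4]
        ren = renormalize(_ensemble(pops))
        res = select_initial_conditions(ren, seed=1)
        assert not res[0].accepted
        assert res[0].hop_history == []

    def test_determinism(self, renorm_low20):
        a = select_initial_conditions(renorm_low20, seed=2)
        b = select_initial_conditions(renorm_low20, seed=2)
        assert all(
            (x.accepted == y.accepted and x.state == y.state
             and x.t_start == y.t_start) for x, y in zip(a, b)
        )

    def test_start_times_multiples_of_tsh_step(self, selection_low20):
        t = np.array([s.t_start for s in selection_low20 if s.accepted])
        steps = t / fs_to_au(0.5)
        assert np.max(np.abs(steps - np.round(steps))) < 1e-6

    def test_acceptance_matches_total_renormalized_probability(self, rng):
        # hop occurrence over many seeds ~ P_tot / P_max per trace
        decay = np.concatenate([np.ones(5), 1.0 - np.linspace(0, 4e-4, 45)])
        pops_a = np.stack([decay, 1.0 - decay], axis=1)
        decay_b = np.concatenate([np.ones(5), 1.0 - np.linspace(0, 2e-4, 45)])
        pops_b = np.stack([decay_b, 1.0 - decay_b], axis=1)
        ens = _ensemble([pops_a, pops_b])
        ren = renormalize(ens)
        expect = ren.p_tot / ren.p_max
        hits = np.zeros(2)
        n_rep = 400
        for s in range(n_rep):
            res = select_initial_conditions(ren, seed=1000 + s)
            hits += [len(r.hop_history) > 0 for r in res]
        frac = hits / n_rep
        for k in range(2):
            sig = np.sqrt(expect[k] * (1 - expect[k]) / n_rep)
            assert abs(frac[k] - expect[k]) < 4.0 * max(sig, 1e-3)

    def test_incommensurate_step_rejected(self, renorm_low20):
        with pytest.raises(ValueError, match="multiple"):
            select_initial_conditions(renorm_low20, seed=1, tsh_dt_fs=0.7)

    def test_off_resonance_rejected_by_second_hop(self, renorm_low20,
                                                  selection_low20):
        # transiently populated, later depopulated traces often end with a
        # hop back to the ground state -> rejection with two hops recorded
        back = [
            r for r in selection_low20
            if not r.accepted and len(r.hop_history) >= 2
            and r.hop_history[-1][2] == 0
        ]
        assert len(back) > 10
        accepted = sum(r.accepted for r in selection_low20)
        assert 0 < accepted < len(selection_low20)

    def test_each_condition_used_once(self, selection_low20):
        ids = [r.geometry_id for r in selection_low20]
        assert len(ids) == len(set(ids)) == 10_000


class TestTeardrop:
    def test_accepted_points_inside_oracle_region(self, nai, nai_samples,
                                                  pulse_low20, selection_low20):
        # accepted (detuning, start time) pairs concentrate in the 99%
        # probability region of the analytic two-level excitation rate
        from eoexcite.models import adiabatize
        from eoexcite.oracle2l import probability_region, region_contains

        r = np.array([s.r for s in nai_samples])
        e, _, _ = adiabatize(nai, r)
        de = e[:, 1] - e[:, 0]
        acc = [s for s in selection_low20 if s.accepted]
        idx = np.array([s.geometry_id for s in acc])
        t_red = np.array([s.t_start for s in acc]) / pulse_low20.tau
        om_red = (pulse_low20.omega0 - de[idx]) * pulse_low20.tau
        region = probability_region(0.99)
        inside = region_contains(t_red, om_red, region)
        assert inside.mean() >= 0.95


class TestVerticalSelect:
    def test_single_state_in_window_always_accepted(self, nai, nai_samples):
        one = [nai_samples[0]]
        res = vertical_select(one, nai, (0.0, 10.0), seed=3)
        assert res[0].accepted and res[0].t_start == 0.0 and res[0].state == 1

    def test_empty_window_selects_nothing(self, nai, nai_samples):
        res = vertical_select(nai_samples[:100], nai, (9.0, 9.1), seed=3)
        assert not any(r.accepted for r in res)

    def test_tdm_rescaling_leaves_selection_unchanged(self, nai, nai_samples):
        from eoexcite.models import nai_model

        scaled = nai_model(tdm=0.37)
        a = vertical_select(nai_samples[:2000], nai, (3.65, 3.71), seed=5)
        b = vertical_select(nai_samples[:2000], scaled, (3.65, 3.71), seed=5)
        assert [r.accepted for r in a] == [r.accepted for r in b]

    def test_flux_mode_differs(self, nai, nai_samples):
        a = vertical_select(nai_samples[:4000], nai, (3.6, 4.3), seed=5)
        b = vertical_select(nai_samples[:4000], nai, (3.6, 4.3), seed=5,
                            mode="flux")
        assert [r.accepted for r in a] != [r.accepted for r in b]

    def test_invalid_mode(self, nai, nai_samples):
        with pytest.raises(ValueError):
            vertical_select(nai_samples[:1], nai, (3.0, 4.0), mode="bogus")
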