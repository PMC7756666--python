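"""Refocusing engine: correction signal, objective, swarm, uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nosco.binding import BindingParameters
from nosco import core
from nosco.core import (
    PsoConfig,
    correction_signal,
    estimate_uncertainty,
    grid_search,
    nosco_objective,
    particle_swarm,
    pso_minimize,
    refocused_height,
)
from nosco.simulate import (
    make_scenario,
    simulate_nosco_dataset,
    simulate_reference_fid,
)


class TestCorrectionSignal:
    def test_identity_at_zero_csp(self, single_peak_problem):
        _, _, problem = single_peak_problem
        sc = correction_signal(BindingParameters(5.0, 0.0, 0.0), problem)
        assert np.allclose(sc, 1.0)

    @given(
        dn=st.floats(-60, 60),
        dh=st.floats(-60, 60),
        kd=st.floats(0.5, 500),
    )
    @settings(max_examples=30, deadline=None)
    def test_unit_modulus_everywhere(self, dn, dh, kd, single_peak_problem):
        _, _, problem = single_peak_problem
        sc = correction_signal(BindingParameters(kd, dn, dh), problem)
        assert np.allclose(np.abs(sc), 1.0, atol=1e-12)

    def test_truth_cancels_nonstationary_phase(self, single_peak_problem):
        scen, peak, problem = single_peak_problem
        truth = scen.binding[peak.label]
        corrected = problem.s_ns * correction_signal(truth, problem)
        ref = simulate_reference_fid([peak], scen.acq)
        assert np.allclose(corrected, ref, atol=1e-9 * np.abs(ref).max())

    def test_nonpositive_kd_rejected(self, single_peak_problem):
        _, _, problem = single_peak_problem
        with pytest.raises(ValueError):
            core.nosco_objective_batch(np.array([[1.0, 1.0, 0.0]]), problem)


class TestObjective:
    def test_zero_at_ground_truth(self, single_peak_problem):
        scen, peak, problem = single_peak_problem
        truth = scen.binding[peak.label]
        assert nosco_objective(truth, problem) <= 1e-6 * problem.s_p_height

    def test_stationary_peak_zero_at_zero_csp(self):
        scen = make_scenario("weak", seed=9, snr=np.inf)
        peak = scen.peaks[0]
        stationary = {peak.label: BindingParameters(9.0, 0.0, 0.0)}
        sp = type(peak)(peak.label, peak.nu_n0, peak.nu_h0, 0.0, 0.0,
                        peak.amplitude, peak.r2_n, peak.r2_h)
        data = simulate_nosco_dataset(
            [sp], scen.acq, scen.scheme, scen.schedule_set, stationary
        )
        ref = simulate_reference_fid([sp], scen.acq)
        problem = core.make_problem(
            data, ref, *scen.windows[peak.label], scen.bounds, window=None
        )
        obj = nosco_objective(BindingParameters(77.0, 0.0, 0.0), problem)
        assert obj <= 1e-6 * problem.s_p_height

    def test_nonnegative_and_wrong_params_positive(self, single_peak_problem):
        scen, peak, problem = single_peak_problem
        wrong = BindingParameters(50.0, -20.0, 10.0)
        assert nosco_objective(wrong, problem) > 0

    def test_batch_matches_scalar(self, single_peak_problem):
        _, _, problem = single_peak_problem
        pts = np.array([[10.0, -20.0, 3.0], [0.0, 0.0, 9.0], [25.0, -35.0, 9.0]])
        batch = core.nosco_objective_batch(pts, problem)
        for row, expect in zip(pts, batch):
            got = nosco_objective(BindingParameters(row[2], row[0], row[1]), problem)
            assert got == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_refocusing_beats_smeared_height(self, single_peak_problem):
        scen, peak, problem = single_peak_problem
        truth = scen.binding[peak.label]
        smeared = refocused_height(BindingParameters(100.0, 0.0, 0.0), problem)
        assert refocused_height(truth, problem) > smeared


class TestParticleSwarm:
    def test_quadratic_recovery(self):
        a = np.array([0.3, -1.2, 2.5])
        bounds = np.array([[-5.0, 5.0]] * 3)

        def fb(z):
            return np.sum((z - a) ** 2, axis=1)

        cfg = PsoConfig(n_particles=100, n_iterations=50, n_runs=1, seed=0)
        best, fval = particle_swarm(fb, bounds, cfg, np.random.default_rng(0))
        assert np.all(np.abs(best - a) < 1e-3 * 10.0)

    def test_best_never_worse_than_initial(self):
        bounds = np.array([[-1.0, 1.0]] * 2)

        def fb(z):
            return np.sum(z**2, axis=1)

        rng = np.random.default_rng(1)
        init = bounds[:, 0] + rng.uniform(size=(50, 2)) * 2.0
        f0 = fb(init).min()
        cfg = PsoConfig(n_particles=50, n_iterations=5, n_runs=1, seed=1)
        _, fval = particle_swarm(fb, bounds, cfg, np.random.default_rng(1))
        assert fval <= f0 + 1e-12

    def test_degenerate_bounds_warns_and_returns_point(self):
        bounds = np.array([[2.0, 2.0], [3.0, 3.0]])

        def fb(z):
            return np.sum(z**2, axis=1)

        cfg = PsoConfig(n_particles=10, n_iterations=2, n_runs=1)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            best, fval = particle_swarm(fb, bounds, cfg, np.random.default_rng(0))
        assert np.array_equal(best, [2.0, 3.0])

    def test_determinism(self, single_peak_problem):
        _, _, problem = single_peak_problem
        cfg = PsoConfig(n_particles=20, n_iterations=3, n_runs=2, seed=12)
        r1 = pso_minimize(problem, cfg)
        r2 = pso_minimize(problem, cfg)
        assert r1.best_params == r2.best_params
        assert r1.objective_value == r2.objective_value

    def test_noiseless_parameter_recovery(self, single_peak_problem):
        # the height-matching objective is exactly degenerate along a
        # K_D-amplitude trade-off valley when the reference peak sits off
        # the zero-filled grid (see docs), so even noiseless recovery is
        # only accurate to a few percent in the CSP amplitudes
        scen, peak, problem = single_peak_problem
        truth = scen.binding[peak.label]
        cfg = PsoConfig(seed=2)
        res = pso_minimize(problem, cfg)
        assert res.best_params.k_d == pytest.approx(truth.k_d, rel=0.2)
        assert res.best_params.delta_nu_n == pytest.approx(
            truth.delta_nu_n, rel=0.10
        )
        assert res.best_params.delta_nu_h == pytest.approx(
            truth.delta_nu_h, rel=0.10
        )

    def test_refocusing_inequality_at_optimum(self, single_peak_problem):
        scen, peak, problem = single_peak_problem
        cfg = PsoConfig(n_particles=60, n_iterations=10, n_runs=2, seed=3)
        res = pso_minimize(problem, cfg)
        smeared = refocused_height(BindingParameters(1e6, 0.0, 0.0), problem)
        assert res.refocused_height >= smeared


def tiny_problem():
    """16x16 single-peak problem for fast oracle comparison."""
    from nosco.binding import TitrationScheme
    from nosco.schedules import make_complementary_schedules
    from nosco.simulate import AcquisitionParams, PeakGroundTruth

    acq = AcquisitionParams(n1=16, n2=16, sw1=300.0, sw2=300.0, seed=6)
    scheme = TitrationScheme(x_values=[1.0, 4.0, 12.0, 32.0], c_p=0.5)
    ss = make_complementary_schedules(16, 4, seed=6, x_values=scheme.x_values)
    peak = PeakGroundTruth("p", 40.0, -50.0, 22.0, -30.0)
    binding = {"p": BindingParameters(9.0, 22.0, -30.0)}
    data = simulate_nosco_dataset([peak], acq, scheme, ss, binding)
    ref = simulate_reference_fid([peak], acq)
    bounds = np.array([[-50.0, 50.0], [-50.0, 50.0], [0.5, 500.0]])
    return core.make_problem(data, ref, (40.0, -50.0), (60.0, 60.0), bounds,
                             window=None)


class TestOracleEquivalence:
    def test_pso_at_least_as_good_as_coarse_grid(self):
        problem = tiny_problem()
        _, grid_best = grid_search(problem, n_points=(12, 12, 12))
        cfg = PsoConfig(n_particles=200, n_iterations=15, n_runs=3, seed=4)
        res = pso_minimize(problem, cfg)
        assert res.objective_value <= grid_best + 1e-9


class TestUncertainty:
    def test_repeats_deterministic(self, single_peak_problem):
        _, _, problem = single_peak_problem
        cfg = PsoConfig(n_particles=20, n_iterations=3, n_runs=1, seed=8)
        u1 = estimate_uncertainty(problem, cfg, n_repeats=3)
        u2 = estimate_uncertainty(problem, cfg, n_repeats=3)
        assert np.array_equal(u1.per_repeat, u2.per_repeat)

    def test_noiseless_repeat_spread_is_moderate(self, single_peak_problem):
        _, _, problem = single_peak_problem
        cfg = PsoConfig(n_particles=60, n_iterations=10, n_runs=2, seed=8)
        unc = estimate_uncertainty(problem, cfg, n_repeats=4)
        kd_mean, kd_std = unc.mean[2], unc.std[2]
        assert kd_std < 0.5 * kd_mean

    def test_needs_two_repeats(self, single_peak_problem):
        _, _, problem = single_peak_problem
        cfg = PsoConfig(n_particles=5, n_iterations=1, n_runs=1)
        with pytest.raises(ValueError):
            estimate_uncertainty(problem, cfg, n_repeats=1)
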