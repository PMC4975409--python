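"""Annealing fitter: error functional, proposal kernel, annealing core."""
import math

import numpy as np
import pytest

from atriafit import ModelParameters, default_parameters, error_components
from atriafit.annealing_fit import (
    FitConfig,
    anneal,
    anneal_core,
    default_bounds,
    derive_s2_list,
    propose,
    simulate_for_target,
)
from atriafit.restitution import MorphologyShape, RestitutionPoint, S1S2Result


def _fake_sim_from_target(target, apd_scale=1.0, morph_offset=0.0):
    """An S1S2Result that reproduces the target curves exactly (optionally
    scaled/offset), bypassing any simulation."""
    pts = [
        RestitutionPoint(DI=di, APD=apd * apd_scale, CV=cv, CL=di + apd)
        for (di, apd), (_, cv) in zip(target.apd_points, target.cv_di_points)
    ]
    grid = MorphologyShape.common_grid()
    v = np.clip(target.morphology.resample(grid) + morph_offset, 0.0, 1.05)
    shape = MorphologyShape(t=grid, v=v,
                            artifact_cutoff=target.morphology.artifact_cutoff)
    return S1S2Result(points=pts, morphologies={pts[-1].CL: shape},
                      upstroke_dt={}, s1_cl=500.0)


class TestErrorComponents:
    def test_identical_curves_have_zero_error(self, model_truth_patient):
        target = model_truth_patient.dataset
        eb = error_components(_fake_sim_from_target(target), target)
        assert eb.e_apd == pytest.approx(0.0, abs=1e-9)
        assert eb.e_cv == pytest.approx(0.0, abs=1e-9)
        assert eb.e_morph == pytest.approx(0.0, abs=1e-9)
        assert eb.total == pytest.approx(0.0, abs=1e-9)

    def test_ten_percent_apd_offset_scores_ten_percent(self, model_truth_patient):
        target = model_truth_patient.dataset
        eb = error_components(_fake_sim_from_target(target, apd_scale=1.1), target)
        assert eb.e_apd == pytest.approx(10.0, rel=1e-6)

    def test_constant_morphology_offset_scores_directly(self, model_truth_patient):
        target = model_truth_patient.dataset
        eb = error_components(
            _fake_sim_from_target(target, morph_offset=0.05), target
        )
        # 0.05 offset on the normalized grid = 5% absolute morphology error
        # (slightly less where clipping at 1 bites)
        assert eb.e_morph == pytest.approx(5.0, abs=0.5)

    def test_total_is_weighted_mean(self, model_truth_patient):
        target = model_truth_patient.dataset
        eb = error_components(
            _fake_sim_from_target(target, apd_scale=1.1), target,
            weights=(1.0, 3.0, 1.0, 0.0),
        )
        expected = (1 * eb.e_morph + 3 * eb.e_apd + 1 * eb.e_cv) / 5.0
        assert eb.total == pytest.approx(expected)

    def test_uncovered_target_points_are_penalized(self, model_truth_patient):
        target = model_truth_patient.dataset
        sim = _fake_sim_from_target(target)
        sim.points = sim.points[:2]  # drop coverage of the shortest DIs
        eb = error_components(sim, target, uncovered_penalty=100.0)
        assert eb.e_apd > 10.0


class TestPropose:
    def test_zero_temperature_limit_is_identity(self):
        p = default_parameters()
        out = propose(p, 1e-12, 1.0, default_bounds(p), np.random.default_rng(0))
        assert np.allclose(out.to_vector(), p.to_vector(), rtol=1e-9)

    def test_frozen_parameters_never_move(self):
        p = default_parameters()
        rng = np.random.default_rng(1)
        bounds = default_bounds(p)
        frozen = ("u_o", "u_u", "theta_v", "tau_si")
        for _ in range(1000):
            out = propose(p, 1.0, 1.0, bounds, rng, frozen=frozen)
            assert out.u_o == p.u_o
            assert out.u_u == p.u_u
            assert out.theta_v == p.theta_v
            assert out.tau_si == p.tau_si

    def test_results_respect_bounds(self):
        p = default_parameters()
        rng = np.random.default_rng(2)
        bounds = default_bounds(p)
        for _ in range(200):
            out = propose(p, 1.0, 1.0, bounds, rng, sigma=2.0)
            for name, (lo, hi) in bounds.items():
                assert lo - 1e-12 <= getattr(out, name) <= hi + 1e-12

    def test_log_perturbation_scale_matches_sigma(self):
        """Empirical s.d. of log-perturbations over 10^4 draws matches
        sigma * T/T0 within 5% (unclipped scale parameter)."""
        p = default_parameters()
        rng = np.random.default_rng(3)
        bounds = default_bounds(p)
        sigma, ratio = 0.2, 0.5
        logs = [
            math.log(
                propose(p, ratio, 1.0, bounds, rng, sigma=sigma).tau_s2 / p.tau_s2
            )
            for _ in range(10_000)
        ]
        assert np.std(logs) == pytest.approx(sigma * ratio, rel=0.05)


class TestAnnealCore:
    @staticmethod
    def _quad_setup(seed):
        x_star = np.array([0.3, 0.7])
        A = np.array([[2.0, 0.3], [0.3, 1.0]])

        def energy(x):
            d = x - x_star
            return float(d @ A @ d)

        def step(x, T, T0, rng):
            return np.clip(x + 0.3 * (T / T0) * rng.standard_normal(2), -2.0, 2.0)

        return x_star, energy, step

    def test_toy_quadratic_minimum_found_reliably(self):
        """On a 2-parameter quadratic surface the annealer lands within 1%
        of the analytic minimum (relative to the initial distance) in at
        least 95 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            x_star, energy, step = self._quad_setup(seed)
            x0 = np.array([1.5, -1.0])
            rng = np.random.default_rng(seed)
            best, E_best, _, _ = anneal_core(
                energy, x0, step, rng, n_iterations=50, cooling_factor=0.9,
                moves_per_iteration=20,
            )
            if np.linalg.norm(best - x_star) < 0.01 * np.linalg.norm(x0 - x_star):
                hits += 1
        assert hits >= 95

    def test_best_energy_monotone_over_iterations(self):
        for seed in (0, 1, 2):
            _, energy, step = self._quad_setup(seed)
            rng = np.random.default_rng(seed)
            _, _, trace, _ = anneal_core(
                energy, np.array([1.5, -1.0]), step, rng, n_iterations=30
            )
            bests = [r["E_best"] for r in trace]
            assert all(b <= a + 1e-12 for a, b in zip(bests, bests[1:]))

    def test_greedy_limit_reduces_to_hill_climbing(self):
        """With uphill acceptance forced to zero, the current energy at
        iteration ends equals the best-so-far energy."""
        _, energy, step = self._quad_setup(0)
        rng = np.random.default_rng(5)
        _, _, trace, _ = anneal_core(
            energy, np.array([1.5, -1.0]), step, rng, n_iterations=30,
            uphill_acceptance=0.0,
        )
        for rec in trace:
            assert rec["E_current"] == pytest.approx(rec["E_best"])

    def test_temperature_schedule_is_geometric(self):
        _, energy, step = self._quad_setup(0)
        rng = np.random.default_rng(6)
        _, _, trace, _ = anneal_core(
            energy, np.array([1.0, 1.0]), step, rng,
            n_iterations=50, cooling_factor=0.9, T0=10.0,
        )
        temps = [r["T"] for r in trace]
        assert len(temps) == 50
        assert np.allclose(temps, 10.0 * 0.9 ** np.arange(50))

    def test_failed_candidates_counted_not_accepted(self):
        def energy(x):
            return float("inf") if x[0] > 0.5 else float(x @ x)

        def step(x, T, T0, rng):
            return x + 0.5 * rng.standard_normal(2)

        rng = np.random.default_rng(7)
        best, E_best, _, stats = anneal_core(
            energy, np.array([0.0, 0.0]), step, rng, n_iterations=10
        )
        assert stats["n_failures"] > 0
        assert np.isfinite(E_best)


class TestModelFit:
    def test_s2_list_derived_from_target_dis(self, model_truth_patient):
        target = model_truth_patient.dataset
        s2 = derive_s2_list(target, 500.0)
        assert all(150.0 < x <= 500.0 for x in s2)
        assert len(s2) <= 8
        # the realized premature intervals bracket the target DIs
        assert max(s2) >= target.apd_points[:, 0].max()

    def test_truth_parameters_are_a_fixed_point(self, model_truth_patient,
                                                small_cable):
        """Starting the fit at the generating truth with zero noise keeps
        the error at its floor and returns the truth parameters."""
        gen = model_truth_patient
        cfg = FitConfig(
            n_iterations=2, moves_per_iteration=3,
            s2_list=tuple(p for p in gen.dataset.meta["s2_list"]), seed=0,
        )
        res = anneal(gen.dataset, gen.truth_params, cfg, small_cable)
        assert res.best_errors.e_apd < 0.5
        assert res.best_errors.e_cv < 0.5
        assert res.best_errors.total < 3.0
        # the truth was never displaced by a better candidate
        assert res.trace[-1]["E_best"] <= res.trace[0]["E_best"]

    def test_degenerate_parameter_sets_fit_equally_well(
        self, model_truth_patient, small_cable
    ):
        """Two parameter sets differing more than 2-fold in one parameter
        can produce statistically indistinguishable total errors: the fit
        problem is non-unique."""
        gen = model_truth_patient
        cfg = FitConfig(s2_list=tuple(gen.dataset.meta["s2_list"]))
        truth = gen.truth_params
        # tau_v2m controls reactivation far above the probed DI range
        alt = truth.replace(tau_v2m=truth.tau_v2m * 3.0)
        e1 = error_components(
            simulate_for_target(truth, gen.dataset, small_cable, cfg), gen.dataset
        ).total
        e2 = error_components(
            simulate_for_target(alt, gen.dataset, small_cable, cfg), gen.dataset
        ).total
        assert abs(e1 - e2) < 0.5
        assert alt.tau_v2m / truth.tau_v2m >= 2.0

    def test_fit_result_serializes(self, model_truth_patient, small_cable, tmp_path):
        import json

        gen = model_truth_patient
        cfg = FitConfig(n_iterations=1, moves_per_iteration=1,
                        s2_list=tuple(gen.dataset.meta["s2_list"]), seed=1)
        res = anneal(gen.dataset, gen.truth_params, cfg, small_cable)
        out = tmp_path / "fit.json"
        res.to_json(out)
        payload = json.loads(out.read_text())
        back = ModelParameters.from_dict(payload["best_params"])
        assert back == res.best_params
        assert payload["config"]["cooling_factor"] == 0.9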