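from itertools import groupby

import numpy as np
import pytest
from scipy import optimize as sp_optimize

from lnbench.metrics import TypeSigmas, ri
from lnbench.optimizer import (
    GSASchedule,
    ObjectiveSpec,
    ParameterSet,
    PARAMETER_NAMES,
    gsa_minimize,
    make_vector_objective,
    objective,
    parameterize,
    scale_params,
    simplex_minimize,
)
from lnbench.sparkle_surrogate import (
    SurrogatePotentialParams,
    SyntheticUniverseSpec,
    generate_universe,
    relax,
)
from lnbench.structures import pair_structures

SIGMAS = TypeSigmas({c: 0.1 for c in
                     ("Ln-O", "Ln-N", "Ln-C", "Ln-S", "Ln-P", "Ln-Cl", "Ln-Br", "Ln-Ln")},
                    5.0)


def small_universe(n=6, seed=11, sigma=0.0):
    truth = SurrogatePotentialParams()
    pairs = generate_universe(SyntheticUniverseSpec(
        n_complexes=n, noise_sigma=sigma, seed=seed,
        dinuclear_fraction=0.0, donor_count_range=(6, 9)), truth)
    structures = {p.experimental.id: p.experimental for p in pairs}
    return truth, structures


def make_spec(truth, structures, active=("alpha",), bounds=None):
    return ObjectiveSpec(
        structures=structures, training_ids=sorted(structures), sigmas=SIGMAS,
        backend=relax, base_params=truth, active=active,
        bounds=bounds or {"alpha": (0.9, 1.9), "a1": (0.6, 1.7), "c1": (1.2, 1.9)})


class TestParameterSet:
    def test_has_exactly_22_parameters(self):
        assert len(PARAMETER_NAMES) == 22

    def test_invalid_values_rejected(self):
        from lnbench.param_io_report import load_table1
        good = load_table1("Dy3+")
        with pytest.raises(ValueError):
            good.replace(zeta_s=-1.0)
        with pytest.raises(ValueError):
            good.replace(b1=0.0)
        with pytest.raises(ValueError):
            ParameterSet.from_dict("Dy3+", {"alpha": 1.0})


class TestObjective:
    def test_truth_params_give_near_zero_on_noise_free_data(self):
        truth, structures = small_universe()
        spec = make_spec(truth, structures)
        assert objective(truth, spec) < 1e-6

    def test_perturbing_alpha_increases_objective(self):
        truth, structures = small_universe()
        spec = make_spec(truth, structures)
        base = objective(truth, spec)
        for da in (-0.15, -0.05, 0.05, 0.15):
            assert objective(truth.replace(alpha=truth.alpha + da), spec) > base

    def test_equals_sum_of_independent_ri(self):
        truth, structures = small_universe(sigma=0.02)
        spec = make_spec(truth, structures)
        probe = truth.replace(alpha=1.25)
        total = objective(probe, spec)
        # oracle: recompute each term independently
        expected = 0.0
        for cid in sorted(structures):
            relaxed, ok = relax(structures[cid], probe)
            assert ok
            expected += ri(pair_structures(structures[cid], relaxed), SIGMAS).r_value
        assert total == pytest.approx(expected, rel=1e-9)

    def test_failing_backend_contributes_penalty(self):
        truth, structures = small_universe(n=2)

        calls = {"i": 0}

        def flaky(structure, params):
            calls["i"] += 1
            if calls["i"] == 1:
                raise RuntimeError("boom")
            return relax(structure, params)

        spec = make_spec(truth, structures)
        spec.backend = flaky
        assert objective(truth, spec) >= spec.penalty

    def test_all_backends_failing_raises(self):
        truth, structures = small_universe(n=2)
        spec = make_spec(truth, structures)
        spec.backend = lambda s, p: (_ for _ in ()).throw(RuntimeError())
        with pytest.raises(RuntimeError, match="every training complex"):
            objective(truth, spec)


class TestGSA:
    BOX = [(-5.0, 5.0), (-5.0, 5.0)]

    @staticmethod
    def quad(x):
        return float((x[0] - 0.3) ** 2 + 2.0 * (x[1] + 0.2) ** 2)

    @staticmethod
    def rastrigin(x):
        x = np.asarray(x)
        return float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))

    def test_convex_quadratic_found_to_1e3(self):
        for seed in (0, 1, 7):
            x, fx, _ = gsa_minimize(self.quad, self.BOX, seed=seed,
                                    schedule=GSASchedule(max_iter=2000))
            assert np.max(np.abs(x - np.array([0.3, -0.2]))) < 1e-3

    def test_rastrigin_5000_iterations(self):
        x, fx, _ = gsa_minimize(self.rastrigin, [(-5.12, 5.12)] * 2, seed=42,
                                schedule=GSASchedule(max_iter=5000))
        assert fx < 1.0

    def test_zero_iterations_returns_start(self):
        start = np.array([1.0, 1.5])
        x, fx, _ = gsa_minimize(self.quad, self.BOX, seed=0,
                                schedule=GSASchedule(max_iter=0), x0=start)
        assert np.array_equal(x, start)
        assert fx == self.quad(start)

    def test_bit_identical_for_same_seed(self):
        runs = [gsa_minimize(self.rastrigin, self.BOX, seed=5,
                             schedule=GSASchedule(max_iter=300)) for _ in range(2)]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]
        assert [r.objective for r in runs[0][2].records] == \
               [r.objective for r in runs[1][2].records]

    def test_greedy_acceptance_never_moves_uphill(self):
        x, fx, trace = gsa_minimize(self.rastrigin, self.BOX, seed=3,
                                    schedule=GSASchedule(qa=float("-inf"), max_iter=400))
        vals = [r.objective for r in trace.records]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_best_so_far_monotone_per_phase(self):
        _, _, trace = gsa_minimize(self.rastrigin, self.BOX, seed=9,
                                   schedule=GSASchedule(max_iter=500))
        for _, recs in groupby(trace.records, key=lambda r: r.phase):
            bests = [r.best for r in recs]
            assert all(b <= a for a, b in zip(bests, bests[1:]))

    def test_non_finite_start_raises(self):
        with pytest.raises(ValueError):
            gsa_minimize(lambda x: float("nan"), self.BOX, seed=0)

    def test_agrees_with_independent_annealer_on_quadratic(self):
        # cross-check against scipy's generalized-simulated-annealing
        ref = sp_optimize.dual_annealing(self.quad, self.BOX, seed=4, maxiter=200)
        x, fx, _ = gsa_minimize(self.quad, self.BOX, seed=4,
                                schedule=GSASchedule(max_iter=2000))
        assert abs(fx - ref.fun) < 1e-3


class TestSimplex:
    def test_parabola_from_one(self):
        x, fx, ok = simplex_minimize(lambda v: float(v[0] ** 2), np.array([1.0]))
        assert ok and abs(x[0]) < 1e-6

    def test_rosenbrock_classic_start(self):
        ros = lambda v: float((1 - v[0]) ** 2 + 100 * (v[1] - v[0] ** 2) ** 2)
        x, fx, ok = simplex_minimize(ros, np.array([-1.2, 1.0]))
        assert np.max(np.abs(x - 1.0)) < 1e-3
        # independent optimizer agreement
        ref = sp_optimize.minimize(ros, [-1.2, 1.0], method="Powell")
        assert fx <= ref.fun + 1e-6

    def test_start_at_optimum_converges_immediately(self):
        x, fx, ok = simplex_minimize(lambda v: float(v[0] ** 2 + v[1] ** 2),
                                     np.array([0.0, 0.0]))
        assert ok and fx < 1e-12

    def test_iteration_cap_returns_unconverged(self):
        ros = lambda v: float((1 - v[0]) ** 2 + 100 * (v[1] - v[0] ** 2) ** 2)
        x, fx, ok = simplex_minimize(ros, np.array([-1.2, 1.0]), max_iter=5)
        assert not ok


class TestParameterize:
    def test_freezing_all_parameters_returns_initial(self):
        truth, structures = small_universe(n=2)
        spec = make_spec(truth, structures, active=())
        out, trace = parameterize(truth, [], [], spec)
        assert out is truth
        assert trace.termination == "no active parameters"

    def test_stage_bookkeeping_and_monotone_trace(self):
        truth, structures = small_universe(n=4)
        start = truth.replace(alpha=1.2)
        spec = make_spec(start, structures)
        ids = sorted(structures)
        out, trace = parameterize(start, ids[:2], ids, spec,
                                  schedule=GSASchedule(max_iter=30),
                                  polish_maxfev=60, polish_spreads=(0.02,))
        phases = [r.phase for r in trace.records]
        assert "gsa-small" in phases and "gsa-large" in phases
        for _, recs in groupby(trace.records, key=lambda r: r.phase):
            bests = [r.best for r in recs]
            assert all(b <= a + 1e-12 for a, b in zip(bests, bests[1:]))
        assert trace.termination == "completed"

    def test_single_parameter_truth_recovery(self):
        truth, structures = small_universe(n=6)
        start = truth.replace(alpha=1.6)
        spec = make_spec(start, structures, active=("alpha",))
        ids = sorted(structures)
        out, _ = parameterize(start, ids[:3], ids, spec,
                              schedule=GSASchedule(max_iter=60), polish_maxfev=200,
                              polish_spreads=(0.05, 0.01), seed=2)
        assert abs(out.alpha - truth.alpha) / truth.alpha < 0.02
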