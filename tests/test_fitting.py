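"""Co-refinement machinery: likelihood, optimiser, DRAM sampler, summaries."""

import numpy as np
import pytest

import refloat as rf
from refloat.errors import ConfigurationError
from refloat.fitting import (
    FitProblem,
    ReflectivityDataset,
    assemble_problem,
    chi_squared,
    distance_report,
    dram_sample,
    optimize,
    summarize_posterior,
)
from refloat.model import Parameter, ffb_structure
from refloat.synthetic import NoiseModel, default_qgrid, simulate_dataset, measured_fixture


def _quick_problem(data, condition="CaCl2_initial", distance=20.0, rough=8.0,
                   d_bounds=(1.0, 120.0), **kw):
    dist = Parameter(distance, "distance", d_bounds, vary=True)
    rgh = Parameter(rough, "roughness", (0.5, 40.0), vary=True)
    s = ffb_structure("POPC", condition, dist, rgh)
    return assemble_problem(data, {condition: s}, **kw)


class TestChiSquared:
    def test_zero_when_model_reproduces_data(self):
        s = measured_fixture("POPC", "NaCl")
        grid = default_qgrid(30)
        ds = simulate_dataset(s, "D2O", grid, NoiseModel(0.0, 0.0), seed=1)
        prob = _quick_problem([ds], "NaCl", distance=38.0, rough=9.0,
                              slab_width=0.5, adaptive=False)
        assert prob.chi_squared(np.array([38.0, 9.0])) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_off_by_two_sigma(self):
        s = measured_fixture("POPC", "NaCl")
        grid = default_qgrid(30)
        ds = simulate_dataset(s, "D2O", grid, NoiseModel(0.0, 0.0), seed=1)
        ds.r = ds.r.copy()
        ds.r[10] += 2.0 * ds.dr[10]
        prob = _quick_problem([ds], "NaCl", distance=38.0, rough=9.0,
                              slab_width=0.5, adaptive=False)
        assert prob.chi_squared(np.array([38.0, 9.0])) == pytest.approx(4.0, rel=1e-4)

    def test_additive_over_duplicated_dataset(self, popc_initial_data):
        ds = popc_initial_data[0]
        p1 = _quick_problem([ds])
        p2 = _quick_problem([ds, ds])
        x = np.array([13.0, 5.0])
        assert p2.chi_squared(x) == pytest.approx(2.0 * p1.chi_squared(x), rel=1e-12)

    def test_out_of_bounds_rejected_as_infinite(self, popc_initial_data):
        prob = _quick_problem(popc_initial_data[:1])
        assert chi_squared(prob, np.array([500.0, 5.0])) == np.inf

    def test_mean_chi_squared_matches_point_count(self):
        """i.i.d. standard-normal residuals give chi^2 ~ N on average."""
        s = measured_fixture("POPC", "NaCl")
        grid = default_qgrid(60)
        vals = []
        for seed in range(6):
            ds = simulate_dataset(s, "D2O", grid, seed=seed)
            prob = _quick_problem([ds], "NaCl", distance=38.0, rough=9.0,
                                  slab_width=0.5, adaptive=False)
            vals.append(prob.chi_squared(np.array([38.0, 9.0])))
        n = grid.values.size
        assert np.mean(vals) == pytest.approx(n, rel=0.2)

    def test_orphan_condition_rejected(self, popc_initial_data):
        dist = Parameter(20.0, "d", (1, 120), vary=True)
        s = ffb_structure("POPC", "EDTA", dist, 8.0)
        with pytest.raises(ConfigurationError):
            assemble_problem(popc_initial_data, {"EDTA": s})

    def test_varying_parameter_needs_bounds(self, popc_initial_data):
        dist = Parameter(20.0, "d", None, vary=True)
        s = ffb_structure("POPC", "CaCl2_initial", dist, 8.0)
        with pytest.raises(ConfigurationError):
            assemble_problem(popc_initial_data, {"CaCl2_initial": s})


class _Quadratic:
    """Convex surrogate with the FitProblem optimisation interface."""

    def __init__(self):
        self.target = np.array([0.7, -1.3, 2.1])
        self.bounds = np.array([[-5.0, 5.0]] * 3)
        self.x = None

    def chi_squared(self, x):
        return float(np.sum((np.asarray(x) - self.target) ** 2))

    def set_vector(self, x):
        self.x = np.asarray(x)


class TestOptimize:
    def test_recovers_quadratic_minimum(self):
        prob = _Quadratic()
        res = optimize(prob, seed=1)
        assert np.allclose(res.x, prob.target, atol=1e-6)

    def test_noiseless_recovery_is_exact(self):
        s = measured_fixture("POPC", "NaCl")
        grid = default_qgrid(25)
        ds = simulate_dataset(s, "D2O", grid, NoiseModel(0.0, 0.0), seed=1)
        ds.dr = np.maximum(0.02 * np.abs(ds.r), 1e-8)
        prob = _quick_problem([ds], "NaCl", slab_width=0.5, adaptive=False)
        res = optimize(prob, seed=4, maxiter=40, popsize=12, tol=1e-8)
        assert res.fun < 1e-6 * grid.values.size
        assert res.x[prob.names.index("distance")] == pytest.approx(38.0, abs=0.05)

    def test_two_seeds_agree(self):
        a, b = _Quadratic(), _Quadratic()
        fa = optimize(a, seed=10).fun
        fb = optimize(b, seed=20).fun
        assert fa == pytest.approx(fb, abs=1e-9)


class TestDram:
    @staticmethod
    def _gauss_target(cov):
        icov = np.linalg.inv(cov)

        def lp(x):
            return -0.5 * float(x @ icov @ x)

        return lp

    def test_recovers_gaussian_covariance(self):
        cov = np.array([[1.0, 0.6], [0.6, 1.5]])
        lp = self._gauss_target(cov)
        bounds = np.array([[-15.0, 15.0]] * 2)
        chains, info = dram_sample(None, np.zeros(2), n_steps=100_000, seed=8,
                                   log_post=lp, bounds=bounds)
        sample_cov = np.cov(chains[20_000:].T)
        assert np.allclose(sample_cov, cov, rtol=0.1, atol=0.05)

    def test_respects_bounds(self):
        lp = self._gauss_target(np.eye(2))
        bounds = np.array([[0.5, 4.0], [-4.0, 4.0]])  # mode excluded in dim 0
        chains, _ = dram_sample(None, np.array([1.0, 0.0]), n_steps=5000,
                                seed=3, log_post=lp, bounds=bounds)
        assert chains[:, 0].min() >= 0.5
        assert chains[:, 0].max() <= 4.0

    def test_start_outside_bounds_rejected(self):
        lp = self._gauss_target(np.eye(2))
        bounds = np.array([[0.5, 4.0], [-4.0, 4.0]])
        with pytest.raises(ConfigurationError):
            dram_sample(None, np.zeros(2), n_steps=10, seed=0,
                        log_post=lp, bounds=bounds)

    def test_delayed_rejection_raises_acceptance(self):
        """On a hard multimodal target the DR stage rescues rejected moves."""

        def lp(x):
            return float(np.log(np.exp(-0.5 * ((x[0] + 3) / 0.3) ** 2)
                                + np.exp(-0.5 * ((x[0] - 3) / 0.3) ** 2) + 1e-300))

        bounds = np.array([[-8.0, 8.0]])
        kw = dict(n_steps=20_000, seed=5, log_post=lp, bounds=bounds,
                  initial_scale=0.3)
        _, with_dr = dram_sample(None, np.array([-3.0]), **kw)
        _, without = dram_sample(None, np.array([-3.0]),
                                 delayed_rejection=False, **kw)
        assert with_dr["acceptance_rate"] > without["acceptance_rate"]

    def test_reproducible_for_seed(self):
        lp = self._gauss_target(np.eye(2))
        bounds = np.array([[-9.0, 9.0]] * 2)
        a, _ = dram_sample(None, np.zeros(2), n_steps=2000, seed=12,
                           log_post=lp, bounds=bounds)
        b, _ = dram_sample(None, np.zeros(2), n_steps=2000, seed=12,
                           log_post=lp, bounds=bounds)
        assert np.array_equal(a, b)


class TestSummaries:
    def test_constant_samples_zero_width(self):
        with pytest.warns(UserWarning):
            s = summarize_posterior(np.full(500, 3.3))
        assert s.map_estimate[0] == pytest.approx(3.3)
        assert s.ci95[0] == pytest.approx([3.3, 3.3])

    def test_uniform_interval_width(self):
        rng = np.random.default_rng(0)
        s = summarize_posterior(rng.uniform(0, 1, 200_000))
        lo, hi = s.ci95[0]
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_interval_matches_quantiles(self):
        rng = np.random.default_rng(1)
        s = summarize_posterior(rng.standard_normal(200_000))
        lo, hi = s.ci95[0]
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)
        assert abs(s.map_estimate[0]) < 0.1

    def test_map_inside_interval(self):
        rng = np.random.default_rng(2)
        x = np.column_stack([rng.gamma(2.0, 1.0, 50_000),
                             rng.standard_normal(50_000)])
        s = summarize_posterior(x)
        for j in range(2):
            assert s.ci95[j, 0] <= s.map_estimate[j] <= s.ci95[j, 1]


class TestSharing:
    @staticmethod
    def _two_condition_problem(qgrid):
        sam_apm = Parameter(22.0, "sam_apm", (18, 28), vary=True)
        structures = {}
        dists = {}
        for cond, d0 in (("CaCl2_initial", 13.0), ("NaCl", 38.0)):
            dist = Parameter(d0, f"distance[{cond}]", (1, 120), vary=True)
            s = ffb_structure("POPC", cond, dist, 6.0,
                              sam_area_per_molecule=sam_apm)
            structures[cond] = s
            dists[cond] = dist
        data = []
        for cond in structures:
            data += rf.simulate_condition(measured_fixture("POPC", cond),
                                          contrasts=("D2O",), grid=qgrid, seed=2)
        return assemble_problem(data, structures), dists, sam_apm

    def test_shared_parameter_collected_once(self, qgrid):
        prob, dists, sam_apm = self._two_condition_problem(qgrid)
        assert sum(1 for p in prob.parameters if p is sam_apm) == 1
        assert len(prob.parameters) == 3

    def test_shared_substrate_moves_every_curve(self, qgrid):
        prob, dists, sam_apm = self._two_condition_problem(qgrid)
        before = [prob.model_curve(ds) for ds in prob.datasets]
        sam_apm.value = 25.0
        after = [prob.model_curve(ds) for ds in prob.datasets]
        for b, a in zip(before, after):
            assert not np.allclose(b, a)

    def test_condition_distance_moves_only_its_curves(self, qgrid):
        prob, dists, _ = self._two_condition_problem(qgrid)
        before = {ds.name: prob.model_curve(ds) for ds in prob.datasets}
        dists["NaCl"].value = 55.0
        for ds in prob.datasets:
            after = prob.model_curve(ds)
            if ds.condition == "NaCl":
                assert not np.allclose(before[ds.name], after)
            else:
                assert np.allclose(before[ds.name], after)

    def test_standard_fourteen_dataset_layout(self, qgrid):
        """4 membrane conditions x 3 contrasts + SAM-only x 2 contrasts."""
        sam_apm = Parameter(22.0, "sam_apm", (18, 28), vary=True)
        structures = {}
        data = []
        for cond in ("CaCl2_initial", "EDTA", "NaCl", "CaCl2_final"):
            dist = Parameter(20.0, f"distance[{cond}]", (1, 650), vary=True)
            structures[cond] = ffb_structure("POPC", cond, dist, 6.0,
                                             sam_area_per_molecule=sam_apm)
            truth = measured_fixture("POPC", cond)
            data += rf.simulate_condition(truth, grid=qgrid, seed=4)
        structures["SAM_only"] = ffb_structure(
            "POPC", "SAM_only", 0.0, 5.0, sam_area_per_molecule=sam_apm,
            sam_only=True)
        sam_truth = rf.ffb_structure("POPC", "SAM_only", 0.0, 5.0, sam_only=True)
        data += rf.simulate_condition(sam_truth, contrasts=("D2O", "H2O"),
                                      grid=qgrid, seed=5)
        prob = assemble_problem(data, structures)
        assert len(prob.datasets) == 14
        assert sum(1 for p in prob.parameters if p is sam_apm) == 1
        report = distance_report(prob, _fake_summary(prob))
        assert set(report) == {"CaCl2_initial", "EDTA", "NaCl", "CaCl2_final"}


def _fake_summary(prob):
    x = prob.get_vector()
    from refloat.fitting import PosteriorSummary
    return PosteriorSummary(x, np.column_stack([x, x]), x[None, :], prob.names)
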