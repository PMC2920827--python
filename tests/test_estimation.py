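"""Objective components, parameter transforms, fitting, and bootstrap."""

import numpy as np
import pytest

import harvestipm as hi
from harvestipm.estimation import (
    FitConfig,
    ParameterSet,
    _ModelContext,
    resample_misclassification,
)
from conftest import make_truth_paramset


class TestChisqObjective:
    def test_perfect_fit_is_zero_and_single_cell_arithmetic(self):
        O = np.full((2, 3, 2), 4.0)
        assert hi.chisq_objective(O, O) == 0.0
        E = O.copy()
        O2 = O.copy()
        O2[0, 0, 0], E[0, 0, 0] = 10.0, 5.0
        assert hi.chisq_objective(O2, E) == pytest.approx((10 - 5) ** 2 / 5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        O = rng.uniform(0, 30, (2, 3, 2))
        E = rng.uniform(0.5, 30, (2, 3, 2))
        total = 0.0
        for t in range(2):
            for a in range(3):
                for s in range(2):
                    total += (O[t, a, s] - E[t, a, s]) ** 2 / max(E[t, a, s], 1e-8)
        assert hi.chisq_objective(O, E) == pytest.approx(total, abs=1e-12)

    def test_invariant_to_cell_ordering(self):
        rng = np.random.default_rng(1)
        O = rng.uniform(0, 30, (4, 5, 2))
        E = rng.uniform(0.5, 30, (4, 5, 2))
        perm = rng.permutation(4)
        assert hi.chisq_objective(O[perm], E[perm]) == pytest.approx(
            hi.chisq_objective(O, E), rel=1e-14)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hi.chisq_objective(np.zeros((2, 3, 2)), np.zeros((2, 4, 2)))


class TestMrPenalty:
    def _N(self):
        N = np.ones((3, 4, 2)) * 1000.0
        N[:, 0, :] = 500.0  # cubs, must be excluded
        return hi.AbundanceArray(N, np.array([1991, 1992, 1993]))

    def test_zero_weight_is_zero(self):
        mr = [hi.MarkRecaptureEstimate(1991, 20000, 1600)]
        assert hi.mr_penalty(mr, self._N(), 0.0) == 0.0

    def test_arithmetic_and_linearity_in_w(self):
        N = self._N()  # excl-cub total = 6000 per year
        mr = [hi.MarkRecaptureEstimate(1992, 8000.0, 1600.0)]
        expect = ((8000 - 6000) / 1600) ** 2
        assert hi.mr_penalty(mr, N, 1.0) == pytest.approx(expect)
        assert hi.mr_penalty(mr, N, 200.0) == pytest.approx(200 * expect)

    def test_year_outside_span_rejected(self):
        mr = [hi.MarkRecaptureEstimate(1888, 100.0, 10.0)]
        with pytest.raises(ValueError, match="1888"):
            hi.mr_penalty(mr, self._N(), 1.0)


class TestCountCells:
    def test_study_shape_and_small_shape(self, baseline_sim):
        assert hi.count_cells(baseline_sim.observed) == 580
        small = hi.HarvestArray(np.zeros((2, 3, 2)), [0, 1])
        assert hi.count_cells(small) == 2 * 2 * 3
        assert hi.count_cells(baseline_sim.observed) == baseline_sim.observed.counts.size


class TestParameterVector:
    @pytest.mark.parametrize("variant,n_missing", [("fe", 4), ("yr", 0)])
    def test_round_trip_exact(self, variant, n_missing):
        rng = np.random.default_rng(6)
        T, A = 29, 10
        n_temporal = 3 + n_missing if variant == "fe" else T
        P = 2 * A + (T - 1) + 3 + 3 + 1 + n_temporal
        theta = rng.normal(0, 1, P)
        ps = ParameterSet.from_vector(theta, A, T, variant, n_missing)
        np.testing.assert_array_equal(ps.to_vector(), theta)

    def test_parameter_count_matches_cells_to_params_ratios(self):
        # 62 parameters for the covariate model, 84 for the unstructured one
        fe = ParameterSet.from_vector(np.zeros(62), 10, 29, "fe", 4)
        yr = ParameterSet.from_vector(np.zeros(84), 10, 29, "yr", 0)
        assert fe.n_params == 62 and yr.n_params == 84

    def test_female_yearling_transform_respects_floor(self):
        ps = ParameterSet.from_vector(np.full(62, -8.0), 10, 29, "fe", 4)
        _, _, surv, _ = ps.constrained()
        assert surv.female_yearling >= surv.male_yearling
        ps2 = ParameterSet.from_vector(np.full(62, 8.0), 10, 29, "fe", 4)
        _, _, surv2, _ = ps2.constrained()
        assert surv2.female_yearling < 1.0


class TestFit:
    def test_self_fit_from_truth_start_reaches_zero(self, noise_free_data):
        nf = noise_free_data
        res = hi.fit(nf["data"], nf["covariates"], [],
                     FitConfig(variant="fe", w=0.0, n_starts=1), x0=nf["theta"])
        assert res.objective < 1e-6

    def test_self_fit_recovers_lambda_from_jittered_start(self, noise_free_data):
        nf = noise_free_data
        rng = np.random.default_rng(17)
        x0 = nf["theta"] + rng.normal(0, 0.2, nf["theta"].size)
        res = hi.fit(nf["data"], nf["covariates"], [],
                     FitConfig(variant="fe", w=0.0, seed=0, stop_early=False),
                     x0=x0)
        lam = hi.lambda_series(res.abundance)
        assert res.objective < 1e-6
        np.testing.assert_allclose(lam, nf["lambda_true"], atol=1e-3)

    def test_weight_zero_fit_ignores_mark_recapture_inputs(self, noise_free_data):
        nf = noise_free_data
        cfg = FitConfig(variant="fe", w=0.0, n_starts=1)
        mr_a = [hi.MarkRecaptureEstimate(1991, 20000.0, 1600.0)]
        mr_b = [hi.MarkRecaptureEstimate(1991, 55.0, 2.0)]
        ra = hi.fit(nf["data"], nf["covariates"], mr_a, cfg, x0=nf["theta"])
        rb = hi.fit(nf["data"], nf["covariates"], mr_b, cfg, x0=nf["theta"])
        np.testing.assert_array_equal(ra.params.to_vector(), rb.params.to_vector())
        assert ra.penalty == rb.penalty == 0.0

    def test_objective_decomposes_into_chi2_plus_penalty(self, baseline_sim):
        res = hi.fit(baseline_sim.observed, baseline_sim.covariates,
                     baseline_sim.mr, FitConfig(variant="fe", w=1.0, seed=1))
        assert res.objective == pytest.approx(res.chi2 + res.penalty, rel=1e-10)
        assert res.chi2 >= 0 and res.penalty >= 0
        assert res.n_cells == 580 and res.n_params == 62

    def test_unstructured_model_fits_no_worse_than_nested_covariate_model(
            self, baseline_sim):
        """The covariate sub-model is a constrained unstructured model, so
        the unstructured optimum cannot be worse on shared data (started,
        fairly, from the mapped covariate optimum)."""
        cfg_fe = FitConfig(variant="fe", w=0.0, seed=2)
        res_fe = hi.fit(baseline_sim.observed, baseline_sim.covariates, [], cfg_fe)
        fe = res_fe.params
        eta_years = (fe.harvest.intercept
                     + fe.harvest.beta_food * baseline_sim.covariates.food_index
                     + fe.harvest.beta_effort * baseline_sim.covariates.effort_index)
        eta_years[baseline_sim.covariates.missing_years] = fe.harvest.early_year_effects
        mapped = np.concatenate([
            fe.log_initial.ravel(), fe.log_recruitment, fe.survival_raw,
            fe.harvest.age_spline_coefs, [fe.harvest.sex_offset], eta_years,
        ])
        res_yr = hi.fit(baseline_sim.observed, baseline_sim.covariates, [],
                        FitConfig(variant="yr", w=0.0, n_starts=1), x0=mapped)
        assert res_yr.chi2 <= res_fe.chi2 + 1e-6

    def test_objective_at_truth_has_chi_square_scale(self):
        """Over repeated noisy datasets the objective evaluated at the true
        parameters should average close to the n - p degrees of freedom of
        the fitted chi-square statistic."""
        vals = []
        rng = np.random.default_rng(7)
        for s in rng.integers(2 ** 31 - 1, size=200):
            sim = hi.simulate(hi.ScenarioSpec(seed=int(s)))
            ctx = _ModelContext(sim.observed, sim.covariates, [],
                                FitConfig(variant="fe", w=0.0))
            theta = make_truth_paramset(sim).to_vector()
            vals.append(ctx.objective_scalar(theta))
        n_minus_p = 580 - 62
        assert abs(np.mean(vals) / n_minus_p - 1) < 0.10


class TestBootstrap:
    def test_single_replicate_gives_degenerate_interval(self, baseline_sim):
        data = hi.HarvestArray(np.round(baseline_sim.observed.counts),
                               baseline_sim.observed.year_labels)
        mis = hi.MisclassificationSample(159, 17, 183, 1)
        frac = hi.AgedFractionSeries(data.year_labels, np.full(data.n_years, 0.71))
        boot = hi.bootstrap(data, mis, frac, baseline_sim.mr,
                            baseline_sim.covariates, B=1,
                            config=FitConfig(variant="fe", w=1.0), seed=42)
        iv = boot.intervals(0.95)
        assert boot.abundance.shape[0] == 1
        np.testing.assert_allclose(iv["abundance"][0], iv["abundance"][1])

    def test_misclassification_resampling_has_binomial_mean(self):
        mis = hi.MisclassificationSample(159, 17, 183, 1)
        rng = np.random.default_rng(0)
        rates = [resample_misclassification(mis, rng).p_female_to_male
                 for _ in range(600)]
        assert np.mean(rates) == pytest.approx(17 / 159, abs=0.01)

    def test_invalid_replicate_count_rejected(self, baseline_sim):
        with pytest.raises(ValueError):
            hi.bootstrap(baseline_sim.observed, hi.MisclassificationSample(159, 17, 183, 1),
                         hi.AgedFractionSeries(baseline_sim.observed.year_labels,
                                               np.full(29, 0.71)),
                         baseline_sim.mr, baseline_sim.covariates, B=0)
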