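"""Shared fixtures: toy arrays, truth parameter vectors, and the
session-scoped Baseline simulation experiment reused by several tests."""

import numpy as np
import pytest
from scipy.special import logit

import harvestipm as hi
from harvestipm import simulation as sim_mod
from harvestipm.estimation import FitConfig, ParameterSet, _ModelContext
from harvestipm.harvest_model import HarvestParams


@pytest.fixture
def toy_harvest():
    """A tiny 4-year x 4-age x 2-sex harvest array with simple counts."""
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 40, size=(4, 4, 2)).astype(float)
    return hi.HarvestArray(counts, np.arange(2000, 2004))


@pytest.fixture(scope="session")
def baseline_sim():
    """One Baseline-scenario simulated dataset."""
    return hi.simulate(hi.ScenarioSpec(name="Baseline", seed=101))


def make_truth_paramset(sim) -> ParameterSet:
    """The operating model's parameters expressed in estimation-model form."""
    hp0 = sim_mod.baseline_harvest_params()
    covs = sim.covariates
    miss = covs.missing_years
    early = (hp0.intercept + hp0.beta_food * covs.food_index[miss]
             + hp0.beta_effort * covs.effort_index[miss])
    hp = HarvestParams(
        variant="fe", age_spline_coefs=hp0.age_spline_coefs,
        sex_offset=hp0.sex_offset, intercept=hp0.intercept,
        beta_food=hp0.beta_food, beta_effort=hp0.beta_effort,
        early_year_effects=early,
    )
    T = sim.observed.n_years
    sv = sim_mod.BASELINE_SURVIVAL
    s_m1 = hi.popdyn.MALE_YEARLING_SURVIVAL
    theta_f1 = logit((sv["female_yearling"] - s_m1) / (1 - s_m1))
    return ParameterSet(
        log_initial=np.log(np.maximum(sim.true_abundance.N[0, 1:], 1e-3)),
        log_recruitment=np.log(np.full(T - 1, sim_mod.BASELINE_RECRUITMENT)),
        survival_raw=np.array([theta_f1, logit(sv["male_adult"]),
                               logit(sv["female_adult"])]),
        harvest=hp,
    )


@pytest.fixture(scope="session")
def noise_free_data(baseline_sim):
    """Exact expected harvests generated from a known parameter set."""
    theta = make_truth_paramset(baseline_sim).to_vector()
    ctx = _ModelContext(baseline_sim.observed, baseline_sim.covariates, [],
                        FitConfig(variant="fe", w=0.0))
    N, C = ctx.predict(theta)
    data = hi.HarvestArray(C[0], baseline_sim.observed.year_labels)
    totals = N[0][:, 1:, :].sum(axis=(1, 2))
    return {"theta": theta, "data": data, "covariates": baseline_sim.covariates,
            "lambda_true": totals[1:] / totals[:-1]}


#: Replicates of the shared Baseline experiment. The full study protocol
#: uses 1000; 100 resolves the convergence, ranking, and bias comparisons
#: while keeping the suite inside a routine CI budget.
EXPERIMENT_REPS = 100


@pytest.fixture(scope="session")
def baseline_experiment():
    """Baseline scenario, all six integrated estimators + three Downing
    reconstructions, shared across acceptance tests."""
    return hi.run_experiment(["Baseline"], sim_mod.DEFAULT_ESTIMATORS,
                             n_reps=EXPERIMENT_REPS, seed=2020)
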