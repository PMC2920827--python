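"""Model fitting by penalized chi-square minimization, plus the bootstrap.

The objective is

    Lambda = Lambda_0 + penalty
    Lambda_0 = sum_{t,a,s} (C_obs - C_hat)^2 / max(C_hat, eps)
    penalty  = w * sum_t ((Nhat_mr_t - N_model_t) / SE_t)^2

where ``C_hat`` are predicted harvests from the projection model and the
penalty compares model abundance (cubs excluded) with mark-recapture
point estimates in the years such estimates exist. ``w`` sets the
relative weight of the two information sources (``w = 0`` ignores the
mark-recapture data). Assuming the dynamics model is adequate,
``Lambda_0`` at the optimum is approximately chi-square with ``n - p``
degrees of freedom, where ``n = 2 * T * A`` is the number of observation
cells and ``p`` the number of estimated parameters.

Both terms are sums of squares, so the minimizer is a trust-region
Gauss-Newton method (``scipy.optimize.least_squares``) driven by a
batched finite-difference Jacobian. A fit is declared converged when the
scaled gradient max-norm is below 1e-4 and the finite-difference Hessian
of the objective at the optimum is positive definite.

Estimated quantities (all mapped to an unconstrained scale):

* log initial abundance for ages 1..A by sex (year 1);
* log cub recruitment for years 1..T-1 (the final year's cubs never
  reach a harvestable age inside the data span and are pinned to the
  previous year's value);
* survival: logit male 2+, logit female 2+, and a difference transform
  for female yearling survival,
  ``S_f1 = S_m1 + (1 - S_m1) * logistic(theta)``, which enforces
  female yearling survival >= the fixed male value;
* the harvest sub-model block (spline coefficients, sex offset, and the
  temporal block of the chosen variant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from harvestipm.data_io import (
    AgedFractionSeries,
    CovariateSeries,
    HarvestArray,
    MarkRecaptureEstimate,
    MisclassificationSample,
    correct_sex_misclassification,
    inflate_for_unaged,
)
from harvestipm.downing import downing_reconstruct
from harvestipm.harvest_model import HarvestParams, SplineConfig, cloglog_inverse
from harvestipm.harvest_model import natural_spline_basis
from harvestipm.popdyn import (
    CUB_SURVIVAL,
    MALE_YEARLING_SURVIVAL,
    AbundanceArray,
    RecruitmentSeries,
    SurvivalParams,
    project_with_rates,
)

logger = logging.getLogger(__name__)

CHI2_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Objective components (public operations)
# ---------------------------------------------------------------------------


def chisq_objective(observed, predicted, eps: float = CHI2_FLOOR) -> float:
    """Chi-square discrepancy between observed and predicted harvests.

    ``sum (O - E)^2 / max(E, eps)`` over all (year, age, sex) cells. The
    floor ``eps`` keeps near-zero predicted cells from dominating.
    """
    O = observed.counts if isinstance(observed, HarvestArray) else np.asarray(observed, float)
    E = predicted.counts if isinstance(predicted, HarvestArray) else np.asarray(predicted, float)
    if O.shape != E.shape:
        raise ValueError(f"shape mismatch: observed {O.shape} vs predicted {E.shape}")
    if np.any(E < 0):
        raise ValueError("predicted harvests must be non-negative")
    return float(((O - E) ** 2 / np.maximum(E, eps)).sum())


def mr_penalty(mr: list[MarkRecaptureEstimate], N: AbundanceArray, w: float) -> float:
    """Mark-recapture penalty ``w * sum ((Nhat - N_model)/SE)^2``.

    Model abundance excludes cubs, matching the mark-recapture scale.
    """
    if w < 0:
        raise ValueError("penalty weight must be non-negative")
    if w == 0 or not mr:
        return 0.0
    totals = N.totals(include_cubs=False)
    acc = 0.0
    for est in mr:
        idx = np.nonzero(N.year_labels == est.year)[0]
        if idx.size == 0:
            raise ValueError(f"mark-recapture year {est.year} outside the modeled span")
        acc += ((est.estimate - totals[idx[0]]) / est.se) ** 2
    return float(w * acc)


def count_cells(data: HarvestArray) -> int:
    """Number of unique observation cells, ``2 * T * A``."""
    return 2 * data.n_years * data.n_ages


# ---------------------------------------------------------------------------
# Parameter vector
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Configuration of one model fit."""

    variant: str = "fe"
    w: float = 1.0
    spline: SplineConfig = field(default_factory=SplineConfig)
    cub_survival: tuple = CUB_SURVIVAL
    male_yearling_survival: float = MALE_YEARLING_SURVIVAL
    eps: float = CHI2_FLOOR
    n_starts: int = 5
    stop_early: bool = True
    jitter_sd: float = 0.2
    max_nfev: int = 400
    gradient_tol: float = 1e-4
    seed: int = 0


@dataclass
class ParameterSet:
    """All estimated quantities, stored on the unconstrained scale.

    ``to_vector`` / ``from_vector`` round-trip exactly; ``constrained``
    maps to the natural-scale model inputs.
    """

    log_initial: np.ndarray  # (A, 2) ages 1..A, sex (F, M)
    log_recruitment: np.ndarray  # (T-1,)
    survival_raw: np.ndarray  # (theta_f1, logit male 2+, logit female 2+)
    harvest: HarvestParams
    male_yearling_survival: float = MALE_YEARLING_SURVIVAL
    cub_survival: tuple = CUB_SURVIVAL

    def to_vector(self) -> np.ndarray:
        hp = self.harvest
        temporal = (
            np.concatenate([[hp.intercept, hp.beta_food, hp.beta_effort], hp.early_year_effects])
            if hp.variant == "fe"
            else hp.year_effects
        )
        return np.concatenate([
            self.log_initial.ravel(),
            self.log_recruitment,
            self.survival_raw,
            hp.age_spline_coefs,
            [hp.sex_offset],
            temporal,
        ])

    @classmethod
    def from_vector(
        cls,
        theta: np.ndarray,
        n_ages: int,
        n_years: int,
        variant: str,
        n_missing: int,
        df: int = 3,
        male_yearling_survival: float = MALE_YEARLING_SURVIVAL,
        cub_survival: tuple = CUB_SURVIVAL,
    ) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        i = 0
        log_init = theta[i : i + 2 * n_ages].reshape(n_ages, 2); i += 2 * n_ages
        log_rec = theta[i : i + n_years - 1]; i += n_years - 1
        surv = theta[i : i + 3]; i += 3
        coefs = theta[i : i + df]; i += df
        sex_off = theta[i]; i += 1
        if variant == "fe":
            hp = HarvestParams(
                variant="fe", age_spline_coefs=coefs, sex_offset=sex_off,
                intercept=theta[i], beta_food=theta[i + 1], beta_effort=theta[i + 2],
                early_year_effects=theta[i + 3 : i + 3 + n_missing],
            )
            i += 3 + n_missing
        else:
            hp = HarvestParams(variant="yr", age_spline_coefs=coefs, sex_offset=sex_off,
                               year_effects=theta[i : i + n_years])
            i += n_years
        if i != theta.size:
            raise ValueError(f"parameter vector length {theta.size}, expected {i}")
        return cls(log_init, log_rec, surv, hp,
                   male_yearling_survival=male_yearling_survival, cub_survival=cub_survival)

    def constrained(self) -> tuple[np.ndarray, RecruitmentSeries, SurvivalParams, HarvestParams]:
        """(initial abundance, recruitment, survival, harvest params)."""
        initial = np.exp(self.log_initial)
        rec = np.exp(self.log_recruitment)
        rec = np.concatenate([rec, rec[-1:]])  # final year pinned
        s_m1 = self.male_yearling_survival
        surv = SurvivalParams(
            female_yearling=s_m1 + (1 - s_m1) * expit(self.survival_raw[0]),
            male_adult=expit(self.survival_raw[1]),
            female_adult=expit(self.survival_raw[2]),
            cub=self.cub_survival,
            male_yearling=s_m1,
        )
        return initial, RecruitmentSeries(rec), surv, self.harvest

    @property
    def n_params(self) -> int:
        return self.to_vector().size


@dataclass
class FitResult:
    """Outcome of one model fit."""

    params: ParameterSet
    objective: float
    chi2: float
    penalty: float
    converged: bool
    n_cells: int
    n_params: int
    abundance: AbundanceArray
    predicted: HarvestArray
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Batched model evaluation
# ---------------------------------------------------------------------------


class _ModelContext:
    """Precomputed pieces shared by every objective evaluation of a fit."""

    def __init__(self, data: HarvestArray, covariates: CovariateSeries,
                 mr: list[MarkRecaptureEstimate], config: FitConfig):
        self.data = data
        self.covariates = covariates
        self.mr = list(mr) if mr else []
        self.config = config
        self.T = data.n_years
        self.A = data.n_ages
        self.basis = natural_spline_basis(data.ages.astype(float), config.spline)
        self.df = config.spline.df
        self.n_missing = covariates.missing_years.size if config.variant == "fe" else 0
        self.n_temporal = (3 + self.n_missing) if config.variant == "fe" else self.T
        self.n_params = 2 * self.A + (self.T - 1) + 3 + self.df + 1 + self.n_temporal
        self.obs = data.counts
        self.missing_idx = covariates.missing_years
        if config.variant == "fe":
            self.cov_eta = np.stack([np.ones(self.T), covariates.food_index,
                                     covariates.effort_index])  # (3, T)
        if self.mr and config.w > 0:
            self.mr_idx = np.array([
                int(np.nonzero(data.year_labels == est.year)[0][0]) for est in self.mr
            ])
            self.mr_est = np.array([est.estimate for est in self.mr])
            self.mr_se = np.array([est.se for est in self.mr])
        else:
            self.mr_idx = np.zeros(0, dtype=int)
            self.mr_est = np.zeros(0)
            self.mr_se = np.ones(0)
        for est in self.mr:
            if not np.any(data.year_labels == est.year):
                raise ValueError(f"mark-recapture year {est.year} outside the modeled span")
        self.surv_fixed = np.array(config.cub_survival)
        self.n_resid = 2 * self.T * self.A + self.mr_idx.size

    # -- evaluation --------------------------------------------------------

    def predict(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Abundance and predicted harvest for a (B, P) or (P,) theta."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        B = theta.shape[0]
        A, T, df = self.A, self.T, self.df
        i = 0
        # clip keeps far-flung trial points finite (e^30 ~ 1e13 animals)
        N1 = np.exp(np.clip(theta[:, i : i + 2 * A], -30, 30)).reshape(B, A, 2)
        i += 2 * A
        rec = np.exp(np.clip(theta[:, i : i + T - 1], -30, 30)); i += T - 1
        rec = np.concatenate([rec, rec[:, -1:]], axis=1)
        s_m1 = self.config.male_yearling_survival
        s_f1 = s_m1 + (1 - s_m1) * expit(theta[:, i])
        s_m2 = expit(theta[:, i + 1])
        s_f2 = expit(theta[:, i + 2]); i += 3
        S = np.empty((B, A, 2))
        S[:, 0, 0] = s_f1
        S[:, 0, 1] = s_m1
        S[:, 1:, 0] = s_f2[:, None]
        S[:, 1:, 1] = s_m2[:, None]
        coefs = theta[:, i : i + df]; i += df
        sex_off = theta[:, i]; i += 1
        age_eff = coefs @ self.basis.T  # (B, A)
        if self.config.variant == "fe":
            temporal = theta[:, i : i + 3] @ self.cov_eta  # (B, T)
            temporal[:, self.missing_idx] = theta[:, i + 3 : i + 3 + self.n_missing]
        else:
            temporal = theta[:, i : i + T]
        eta = (temporal[:, :, None, None] + age_eff[:, None, :, None]
               + sex_off[:, None, None, None] * np.array([0.0, 1.0]))
        H = cloglog_inverse(eta)
        N, C = project_with_rates(N1, rec, S, self.surv_fixed, H)
        return N, C

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Residual vector(s) whose squared sum is the objective."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        N, C = self.predict(theta)
        r_chi = (self.obs - C) / np.sqrt(np.maximum(C, self.config.eps))
        out = [r_chi.reshape(theta.shape[0], -1)]
        if self.mr_idx.size:
            totals = N[:, :, 1:, :].sum(axis=(2, 3))
            r_mr = np.sqrt(self.config.w) * (self.mr_est - totals[:, self.mr_idx]) / self.mr_se
            out.append(r_mr)
        return np.concatenate(out, axis=1)

    def objective(self, theta: np.ndarray) -> np.ndarray:
        r = self.residuals(theta)
        return (r ** 2).sum(axis=1)

    def objective_scalar(self, theta: np.ndarray) -> float:
        return float(self.objective(theta)[0])

    def components(self, theta: np.ndarray) -> tuple[float, float]:
        """(chi-square, penalty) components for a single theta."""
        r = self.residuals(theta)[0]
        n_chi = 2 * self.T * self.A
        return float((r[:n_chi] ** 2).sum()), float((r[n_chi:] ** 2).sum())

    # -- derivatives -------------------------------------------------------

    def fd_jacobian(self, theta: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
        """Central-difference Jacobian of the residual vector, (m, P)."""
        theta = np.asarray(theta, dtype=float)
        P = theta.size
        h = rel_step * np.maximum(1.0, np.abs(theta))
        pts = np.repeat(theta[None, :], 2 * P, axis=0)
        idx = np.arange(P)
        pts[idx, idx] += h
        pts[P + idx, idx] -= h
        r = self.residuals(pts)
        return ((r[:P] - r[P:]) / (2 * h[:, None])).T

    def fd_gradient(self, theta: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
        """Central-difference gradient of the objective."""
        theta = np.asarray(theta, dtype=float)
        P = theta.size
        h = rel_step * np.maximum(1.0, np.abs(theta))
        pts = np.repeat(theta[None, :], 2 * P, axis=0)
        idx = np.arange(P)
        pts[idx, idx] += h
        pts[P + idx, idx] -= h
        f = self.objective(pts)
        return (f[:P] - f[P:]) / (2 * h)

    def fd_hessian(self, theta: np.ndarray, rel_step: float = 3e-4) -> np.ndarray:
        """Second-difference Hessian of the objective, symmetrized."""
        theta = np.asarray(theta, dtype=float)
        P = theta.size
        h = rel_step * np.maximum(1.0, np.abs(theta))
        pts = [theta]
        for i in range(P):
            for sign in (+1, -1):
                p = theta.copy(); p[i] += sign * h[i]; pts.append(p)
        pairs = [(i, j) for i in range(P) for j in range(i + 1, P)]
        for i, j in pairs:
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                p = theta.copy(); p[i] += si * h[i]; p[j] += sj * h[j]; pts.append(p)
        f = self.objective(np.asarray(pts))
        H = np.empty((P, P))
        f0 = f[0]
        for i in range(P):
            H[i, i] = (f[1 + 2 * i] - 2 * f0 + f[2 + 2 * i]) / h[i] ** 2
        base = 1 + 2 * P
        for k, (i, j) in enumerate(pairs):
            fpp, fpm, fmp, fmm = f[base + 4 * k : base + 4 * k + 4]
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        return H


# ---------------------------------------------------------------------------
# Starting values
# ---------------------------------------------------------------------------


def default_start(ctx: _ModelContext) -> np.ndarray:
    """Data-informed starting vector.

    Initial abundances come from per-sex Downing reconstructions scaled
    by 1.5 (the reconstruction counts only the eventually harvested
    segment, so it underestimates); the pooled class is spread over ages
    3..A with a geometric decay. Recruitment starts at twice the total
    harvest of each year; survivals start at 0.85 (adults) and the
    midpoint of the allowed yearling range; harvest coefficients start
    at zero with temporal levels near cloglog(0.1).
    """
    data, A, T = ctx.data, ctx.A, ctx.T
    init = np.empty((A, 2))
    for s, mode in enumerate(("females", "males")):
        rec = downing_reconstruct(data, collapse_at=3, sex_mode=mode)
        n1 = 1.5 * rec.abundance[0]  # classes (1, 2, 3+)
        init[0, s] = n1[0]
        init[1, s] = n1[1]
        decay = 0.65 ** np.arange(A - 2)
        init[2:, s] = n1[2] * decay / decay.sum()
    init = np.maximum(init, 1.0)
    rec_start = np.maximum(2.0 * data.year_totals()[: T - 1], 10.0)
    surv_raw = np.array([0.0, logit(0.85), logit(0.85)])
    level = -2.1  # cloglog of roughly a 12% harvest rate
    if ctx.config.variant == "fe":
        temporal = np.concatenate([[level, 0.0, 0.0], np.full(ctx.n_missing, level)])
    else:
        temporal = np.full(T, level)
    return np.concatenate([
        np.log(init).ravel(), np.log(rec_start), surv_raw,
        np.zeros(ctx.df), [0.0], temporal,
    ])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _assess_convergence(ctx: _ModelContext, theta: np.ndarray, fval: float,
                        tol: float) -> tuple[bool, dict]:
    g = ctx.fd_gradient(theta)
    scaled = np.abs(g) * np.maximum(1.0, np.abs(theta)) / max(1.0, abs(fval))
    gnorm = float(scaled.max())
    grad_ok = gnorm < tol
    if grad_ok:
        H = ctx.fd_hessian(theta)
        eigs = np.linalg.eigvalsh((H + H.T) / 2)
        # eigenvalues within machine precision of zero (relative to the
        # matrix norm) cannot be resolved by a finite-difference Hessian;
        # only significantly negative curvature rejects positive definiteness
        floor = -64 * np.finfo(float).eps * max(1.0, abs(eigs[-1]))
        pd = bool(eigs[-1] > 0 and eigs[0] > floor)
        diag = {"scaled_gradient_norm": gnorm, "min_hessian_eig": float(eigs[0]),
                "max_hessian_eig": float(eigs[-1])}
    else:
        pd = False
        diag = {"scaled_gradient_norm": gnorm, "min_hessian_eig": np.nan,
                "max_hessian_eig": np.nan}
    return grad_ok and pd, diag


def fit(
    data: HarvestArray,
    covariates: CovariateSeries,
    mr: list[MarkRecaptureEstimate] | None = None,
    config: FitConfig | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit the age-at-harvest model to (already corrected) data.

    Runs a multi-start trust-region least-squares minimization (first
    start data-informed, later starts jittered) and reports convergence
    diagnostics: scaled gradient max-norm below ``config.gradient_tol``
    and a positive-definite finite-difference Hessian. With
    ``config.stop_early`` the remaining starts are skipped once a start
    converges; otherwise the best objective over all starts is kept.
    Non-convergence yields ``converged=False``, never an exception.
    """
    config = config or FitConfig()
    mr = mr or []
    ctx = _ModelContext(data, covariates, mr, config)
    rng = np.random.default_rng(config.seed)
    base = default_start(ctx) if x0 is None else np.asarray(x0, dtype=float)

    best = None
    n_run = 0
    for k in range(max(1, config.n_starts)):
        start = base if k == 0 else base + rng.normal(0.0, config.jitter_sd, base.size)
        n_run += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # generous box keeps trial points in the numerically safe
            # region (log-abundance 25 ~ 7e10 animals) without binding at
            # any plausible optimum
            sol = least_squares(
                lambda th: ctx.residuals(th)[0], np.clip(start, -24.9, 24.9),
                jac=ctx.fd_jacobian, bounds=(-25.0, 25.0),
                method="trf", x_scale="jac", max_nfev=config.max_nfev,
                xtol=1e-12, ftol=1e-12, gtol=1e-10,
            )
        fval = float(2 * sol.cost)
        converged, diag = _assess_convergence(ctx, sol.x, fval, config.gradient_tol)
        # best objective retained; converged breaks near-ties
        tie = best is not None and abs(fval - best[1]) <= 1e-9 * max(1.0, best[1])
        if (best is None or fval < best[1] or (tie and converged and not best[0])):
            best = (converged, fval, sol.x, diag)
        if converged and config.stop_early:
            break

    converged, fval, theta, diag = best
    if not converged:
        logger.info("fit did not converge after %d start(s); best objective %.4g",
                    n_run, fval)
    N, C = ctx.predict(theta)
    chi2, penalty = ctx.components(theta)
    params = ParameterSet.from_vector(
        theta, ctx.A, ctx.T, config.variant, ctx.n_missing, ctx.df,
        male_yearling_survival=config.male_yearling_survival,
        cub_survival=tuple(config.cub_survival),
    )
    diag.update(n_starts_run=n_run)
    return FitResult(
        params=params,
        objective=fval,
        chi2=chi2,
        penalty=penalty,
        converged=converged,
        n_cells=count_cells(data),
        n_params=ctx.n_params,
        abundance=AbundanceArray(N[0], data.year_labels),
        predicted=HarvestArray(np.maximum(C[0], 0.0), data.year_labels, data.plus_group),
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate-level outputs of the 4-step bootstrap."""

    abundance: np.ndarray  # (B_kept, T) totals excluding cubs
    lambdas: np.ndarray  # (B_kept, T-1)
    objectives: np.ndarray
    n_requested: int
    n_dropped: int
    year_labels: np.ndarray

    def intervals(self, level: float = 0.95) -> dict:
        """Pointwise percentile intervals for abundance and lambda."""
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        return {
            "abundance": np.percentile(self.abundance, [lo, hi], axis=0),
            "lambda": np.percentile(self.lambdas, [lo, hi], axis=0),
        }


def resample_misclassification(
    misclass: MisclassificationSample, rng: np.random.Generator
) -> MisclassificationSample:
    """Binomially resample misclassification counts at the telemetry sample sizes."""
    return MisclassificationSample(
        n_true_female=misclass.n_true_female,
        n_female_recorded_male=int(rng.binomial(
            misclass.n_true_female, misclass.p_female_to_male)),
        n_true_male=misclass.n_true_male,
        n_male_recorded_female=int(rng.binomial(
            misclass.n_true_male, misclass.p_male_to_female)),
    )


def _resample_within_year(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample (age, sex) cells with replacement within each year."""
    out = np.zeros_like(counts)
    T = counts.shape[0]
    for t in range(T):
        cell = np.round(counts[t]).astype(int).ravel()
        n = cell.sum()
        if n == 0:
            continue
        out[t] = rng.multinomial(n, cell / n).reshape(counts[t].shape)
    return out


def bootstrap(
    aged_records: HarvestArray,
    misclass: MisclassificationSample,
    fractions: AgedFractionSeries,
    mr: list[MarkRecaptureEstimate],
    covariates: CovariateSeries,
    B: int,
    config: FitConfig | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap over the whole data-preparation pipeline.

    Per replicate: (1) resample the aged-harvest records with
    replacement within each year; (2) binomially resample the
    sex-misclassification counts at their telemetry sample sizes;
    (3) re-apply the misclassification correction, then the
    aged-fraction inflation; (4) draw parametric mark-recapture
    estimates from Normal(point, SE); then refit the model.
    Non-convergent replicates are dropped and counted (a warning is
    emitted if more than 10% drop).
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    kept_N, kept_lam, kept_obj = [], [], []
    dropped = 0
    for b in range(B):
        resampled = HarvestArray(
            _resample_within_year(aged_records.counts, rng),
            aged_records.year_labels, aged_records.plus_group,
        )
        mis_b = resample_misclassification(misclass, rng)
        corrected = correct_sex_misclassification(resampled, mis_b)
        inflated = inflate_for_unaged(corrected, fractions)
        mr_b = [
            MarkRecaptureEstimate(est.year, max(float(rng.normal(est.estimate, est.se)), 1.0),
                                  est.se)
            for est in mr
        ]
        rep_cfg = FitConfig(**{**config.__dict__, "seed": int(rng.integers(2 ** 31 - 1))})
        res = fit(inflated, covariates, mr_b, rep_cfg)
        if not res.converged:
            dropped += 1
            continue
        kept_N.append(res.abundance.totals(include_cubs=False))
        kept_lam.append(kept_N[-1][1:] / kept_N[-1][:-1])
        kept_obj.append(res.objective)
    if dropped > 0.1 * B:
        warnings.warn(f"{dropped}/{B} bootstrap replicates dropped (non-convergent)")
    if not kept_N:
        raise RuntimeError("no bootstrap replicate converged")
    return BootstrapResult(
        abundance=np.array(kept_N), lambdas=np.array(kept_lam),
        objectives=np.array(kept_obj), n_requested=B, n_dropped=dropped,
        year_labels=aged_records.year_labels.copy(),
    )
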