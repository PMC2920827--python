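"""Harvest-vulnerability regression on the complementary log-log scale.

The finite annual harvest probability of an animal of age ``a`` and sex
``s`` in year ``t`` is

    H[t, a, s] = 1 - exp(-exp(eta[t, a, s]))

with an additive linear predictor

    eta = spline(a) . beta_age + delta_sex * 1[s = male] + temporal(t).

The age effect is a natural cubic regression spline (default 3 df,
interior knots at ages 2 and 7, boundary knots at ages 1 and 10). Two
temporal sub-models are supported:

* ``"fe"`` — regression on annual natural-food and hunter-effort
  indices (``intercept + b_f * food_t + b_e * effort_t``), with one free
  effect per leading year in which the covariates are unavailable (the
  linear predictor in those years is ``spline + sex + early_effect``,
  with no intercept, keeping the parameterization identifiable);
* ``"yr"`` — one unstructured vulnerability effect per year.

All effects are additive on the cloglog scale; there are no age x sex or
age x year interactions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from harvestipm.data_io import SEXES, CovariateSeries

logger = logging.getLogger(__name__)

_ETA_CLIP = 38.0


# ---------------------------------------------------------------------------
# Link function
# ---------------------------------------------------------------------------


def cloglog_inverse(eta):
    """Inverse complementary log-log link, ``1 - exp(-exp(eta))``.

    Total function: the linear predictor is clipped at ``|eta| = 38`` so
    the result lies strictly inside (0, 1) for any finite input.
    """
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    p = -np.expm1(-np.exp(eta))
    return np.clip(p, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def cloglog(p):
    """Complementary log-log link, ``log(-log(1 - p))`` for p in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("cloglog requires probabilities strictly inside (0, 1)")
    return np.log(-np.log1p(-p))


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineConfig:
    """Knot layout for the natural cubic spline age effect.

    ``df = len(interior_knots) + 1`` (the basis carries no intercept
    column; the intercept lives in the temporal block).
    """

    interior_knots: tuple = (2.0, 7.0)
    boundary_knots: tuple = (1.0, 10.0)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not all(lo < k < hi for k in self.interior_knots):
            raise ValueError("boundary knots must bracket interior knots")
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ValueError("interior knots must be increasing")

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]])

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1


def natural_spline_basis(ages, config: SplineConfig = SplineConfig()) -> np.ndarray:
    """Evaluate the natural cubic spline basis (no intercept) at ``ages``.

    Uses the truncated-power construction: with knots ``k_1 < ... < k_K``
    and ``d_j(x) = [(x - k_j)_+^3 - (x - k_K)_+^3] / (k_K - k_j)``, the
    basis is ``{x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}}``. Each column
    is cubic between knots, C2 everywhere, and linear outside the
    boundary knots (zero second derivative — the "natural" constraint).
    Ages beyond a boundary knot are evaluated by the linear extrapolation
    that constraint forces.
    """
    x = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ages must be finite")
    knots = config.all_knots
    K = len(knots)
    if K - 1 < 2:
        raise ValueError("need at least 2 degrees of freedom")

    def d(j):
        return (
            np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        ) / (knots[K - 1] - knots[j])

    cols = [x]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class HarvestParams:
    """Coefficients of one harvest sub-model.

    Exactly one temporal variant is active, selected by ``variant``:
    ``"fe"`` uses ``intercept``, ``beta_food``, ``beta_effort`` and
    ``early_year_effects`` (one per covariate-missing leading year);
    ``"yr"`` uses ``year_effects`` (one per year).
    """

    variant: str
    age_spline_coefs: np.ndarray
    sex_offset: float = 0.0
    intercept: float | None = None
    beta_food: float | None = None
    beta_effort: float | None = None
    early_year_effects: np.ndarray | None = None
    year_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age_spline_coefs = np.asarray(self.age_spline_coefs, dtype=float)
        if self.variant == "fe":
            if self.intercept is None or self.beta_food is None or self.beta_effort is None:
                raise ValueError("fe variant needs intercept, beta_food, beta_effort")
            if self.year_effects is not None:
                raise ValueError("fe variant must not carry year_effects")
            if self.early_year_effects is None:
                self.early_year_effects = np.zeros(0)
            self.early_year_effects = np.asarray(self.early_year_effects, dtype=float)
        elif self.variant == "yr":
            if self.year_effects is None:
                raise ValueError("yr variant needs year_effects")
            if any(v is not None for v in (self.intercept, self.beta_food, self.beta_effort)):
                raise ValueError("yr variant must not carry covariate coefficients")
            self.year_effects = np.asarray(self.year_effects, dtype=float)
        else:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_temporal_params(self) -> int:
        """7 for the covariate variant with 4 covariate-missing years; T for yr."""
        if self.variant == "fe":
            return 3 + self.early_year_effects.size
        return self.year_effects.size

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {"variant": self.variant,
                   "age_spline_coefs": self.age_spline_coefs.tolist(),
                   "sex_offset": self.sex_offset}
        if self.variant == "fe":
            payload.update(intercept=self.intercept, beta_food=self.beta_food,
                           beta_effort=self.beta_effort,
                           early_year_effects=self.early_year_effects.tolist())
        else:
            payload["year_effects"] = self.year_effects.tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "HarvestParams":
        d = json.loads(s)
        return cls(**d)


# ---------------------------------------------------------------------------
# Linear predictor and rates
# ---------------------------------------------------------------------------


def temporal_effects(params: HarvestParams, covariates: CovariateSeries) -> np.ndarray:
    """Per-year temporal term of the linear predictor, shape (T,)."""
    T = covariates.n_years
    if params.variant == "yr":
        if params.year_effects.size != T:
            raise ValueError("year_effects length must equal the number of years")
        return params.year_effects.copy()
    missing = covariates.missing_years
    if params.early_year_effects.size != missing.size:
        raise ValueError(
            f"expected {missing.size} early-year effects, got {params.early_year_effects.size}"
        )
    eta = params.intercept + params.beta_food * covariates.food_index \
        + params.beta_effort * covariates.effort_index
    eta = np.asarray(eta, dtype=float)
    eta[missing] = params.early_year_effects
    return eta


def harvest_rate_matrix(
    params: HarvestParams,
    config: SplineConfig,
    covariates: CovariateSeries,
    ages=None,
) -> np.ndarray:
    """Harvest probabilities ``H[t, a, s]`` of shape ``(T, A, 2)``.

    ``ages`` defaults to ``1..10``; the plus-group is evaluated at its
    nominal age (the basis extrapolates linearly past the boundary knot).
    """
    if ages is None:
        ages = np.arange(1, 11)
    if params.variant == "yr" and covariates is not None and covariates.available.any():
        logger.debug("unstructured (yr) sub-model ignores covariate values")
    basis = natural_spline_basis(ages, config)
    age_eff = basis @ params.age_spline_coefs  # (A,)
    sex_eff = params.sex_offset * np.array([0.0, 1.0])  # (F, M)
    temp = temporal_effects(params, covariates)  # (T,)
    eta = temp[:, None, None] + age_eff[None, :, None] + sex_eff[None, None, :]
    return cloglog_inverse(eta)


def harvest_rate(
    params: HarvestParams,
    config: SplineConfig,
    covariates: CovariateSeries,
    t: int,
    age: float,
    sex: str,
) -> float:
    """Scalar harvest probability for one (year index, age, sex)."""
    basis = natural_spline_basis(np.array([age]), config)
    eta = float((basis @ params.age_spline_coefs)[0])
    eta += params.sex_offset * (SEXES.index(sex.upper()))
    eta += float(temporal_effects(params, covariates)[t])
    return float(cloglog_inverse(eta))
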