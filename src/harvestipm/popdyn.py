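"""Age/sex-structured projection dynamics and predicted harvests.

Annual timeline (January census, autumn hunt, denning, January birth):

* ``N[t, a, s]`` counts animals of age ``a`` (cubs at ``a = 0``, terminal
  plus-group at ``a = A``) alive in January of year ``t``;
* all non-hunting mortality of the year acts before the hunt, so the
  number at risk of harvest is ``N * S`` and the predicted harvest is
  ``C_hat[t, a, s] = N[t, a, s] * S[a, s] * H[t, a, s]`` for ages >= 1
  (cubs are not legally harvested);
* no mortality occurs between the hunt and the January recruitment, so
  ``N[t+1, a+1, s] = N[t, a, s] * S[a, s] * (1 - H[t, a, s])`` with
  ``a + 1`` capped at the plus-group, and ``N[t+1, 0, s] = R[t+1] / 2``
  (an even birth sex ratio is assumed).

Cubs transition to yearlings with fixed sex-specific cub survival;
age-1 animals face the hunt after yearling (den-emergence-to-autumn)
survival; ages 2+ share one survival per sex, constant over age and
time. Because cubs are never observed in the harvest, cub survival and
recruitment enter predictions only through their product, reproducing
the recruitment-survival confounding that motivates fixing cub (and
male yearling) survival.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from harvestipm.data_io import CovariateSeries, HarvestArray
from harvestipm.harvest_model import HarvestParams, SplineConfig, harvest_rate_matrix

#: Fixed survival constants (from den checks / telemetry of the source system).
CUB_SURVIVAL = (0.88, 0.76)  # (female, male)
MALE_YEARLING_SURVIVAL = 0.88
BIRTH_SEX_RATIO = 0.5


@dataclass
class AbundanceArray:
    """Abundance ``N[t, a, s]`` with ages ``0..A`` (cubs at 0)."""

    N: np.ndarray
    year_labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if self.N.ndim != 3 or self.N.shape[2] != 2:
            raise ValueError("N must have shape (T, A+1, 2)")
        if np.any(self.N < 0):
            raise ValueError("abundances must be non-negative")
        if self.year_labels is None:
            self.year_labels = np.arange(self.N.shape[0])
        self.year_labels = np.asarray(self.year_labels, dtype=int)

    @property
    def n_years(self) -> int:
        return self.N.shape[0]

    @property
    def n_ages(self) -> int:
        """Number of harvestable age classes (excludes the cub class)."""
        return self.N.shape[1] - 1

    def totals(self, include_cubs: bool = False) -> np.ndarray:
        start = 0 if include_cubs else 1
        return self.N[:, start:, :].sum(axis=(1, 2))


@dataclass
class RecruitmentSeries:
    """Cubs entering the population each January, split evenly by sex."""

    cubs: np.ndarray

    def __post_init__(self) -> None:
        self.cubs = np.asarray(self.cubs, dtype=float)
        if np.any(self.cubs < 0):
            raise ValueError("recruitment must be non-negative")


@dataclass
class SurvivalParams:
    """Non-hunting survival probabilities.

    Cub survival, male yearling survival, and the birth sex ratio are
    fixed constants; female yearling and the two adult (2+) survivals
    are free, with female yearling survival constrained to be at least
    the male value.
    """

    female_yearling: float
    male_adult: float
    female_adult: float
    cub: tuple = CUB_SURVIVAL
    male_yearling: float = MALE_YEARLING_SURVIVAL

    def __post_init__(self) -> None:
        for name in ("female_yearling", "male_adult", "female_adult", "male_yearling"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not all(0.0 < v < 1.0 for v in self.cub):
            raise ValueError("cub survival must be in (0, 1)")
        if self.female_yearling < self.male_yearling:
            raise ValueError("female yearling survival must be >= male yearling survival")

    def matrix(self, n_ages: int) -> np.ndarray:
        """Pre-hunt survival per (age class 1..A, sex), shape (A, 2)."""
        S = np.empty((n_ages, 2))
        S[0] = (self.female_yearling, self.male_yearling)
        S[1:] = (self.female_adult, self.male_adult)
        return S


def project_with_rates(
    initial: np.ndarray,
    recruits: np.ndarray,
    surv_matrix: np.ndarray,
    cub_survival,
    H: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Core deterministic projection, vectorized over leading batch axes.

    Parameters
    ----------
    initial
        ``(..., A, 2)`` January abundance at ages 1..A in the first year.
    recruits
        ``(..., T)`` cubs recruited each January (split 50:50 by sex).
    surv_matrix
        ``(..., A, 2)`` pre-hunt non-hunting survival for ages 1..A.
    cub_survival
        ``(2,)`` or broadcastable; survival of the age-0 -> age-1 step.
    H
        ``(..., T, A, 2)`` harvest probabilities.

    Returns
    -------
    N : ``(..., T, A+1, 2)`` abundance (cubs at age index 0).
    C : ``(..., T, A, 2)`` predicted harvest of ages 1..A.
    """
    initial = np.asarray(initial, dtype=float)
    recruits = np.asarray(recruits, dtype=float)
    H = np.asarray(H, dtype=float)
    T = recruits.shape[-1]
    A = initial.shape[-2]
    batch = np.broadcast_shapes(
        initial.shape[:-2], recruits.shape[:-1], H.shape[:-3], np.shape(surv_matrix)[:-2]
    )
    cub_s = np.broadcast_to(np.asarray(cub_survival, dtype=float), (2,))
    N = np.zeros(batch + (T, A + 1, 2))
    C = np.zeros(batch + (T, A, 2))
    N[..., 0, 1:, :] = initial
    N[..., 0, 0, :] = (BIRTH_SEX_RATIO * recruits[..., 0])[..., None]
    for t in range(T):
        at_risk = N[..., t, 1:, :] * surv_matrix
        C[..., t, :, :] = at_risk * H[..., t, :, :]
        post = at_risk - C[..., t, :, :]
        if t + 1 < T:
            N[..., t + 1, 2:, :] = post[..., :-1, :]
            N[..., t + 1, A, :] += post[..., -1, :]
            N[..., t + 1, 1, :] = N[..., t, 0, :] * cub_s
            N[..., t + 1, 0, :] = (BIRTH_SEX_RATIO * recruits[..., t + 1])[..., None]
    return N, C


def project(
    initial: np.ndarray,
    recruits: RecruitmentSeries,
    surv: SurvivalParams,
    hp: HarvestParams,
    covariates: CovariateSeries,
    spline: SplineConfig = SplineConfig(),
    year_labels=None,
) -> tuple[AbundanceArray, HarvestArray]:
    """Project the population and predicted harvests over the data span."""
    initial = np.asarray(initial, dtype=float)
    A = initial.shape[0]
    H = harvest_rate_matrix(hp, spline, covariates, ages=np.arange(1, A + 1))
    N, C = project_with_rates(
        initial, recruits.cubs, surv.matrix(A), np.array(surv.cub), H
    )
    if year_labels is None:
        year_labels = np.arange(N.shape[0])
    return (
        AbundanceArray(N, year_labels),
        HarvestArray(C, year_labels, plus_group=True),
    )


def lambda_series(N: AbundanceArray | np.ndarray, include_cubs: bool = False) -> np.ndarray:
    """Finite annual rates of increase ``lambda_t = N_{t+1} / N_t``.

    Totals exclude cubs by default, matching the scale of the
    mark-recapture estimates (which did not cover cubs).
    """
    if isinstance(N, AbundanceArray):
        totals = N.totals(include_cubs=include_cubs)
    else:
        totals = np.asarray(N, dtype=float)
    if totals.size < 2:
        raise ValueError("need at least two years to form transitions")
    if np.any(totals <= 0):
        raise ValueError("total abundance must be positive in every year")
    return totals[1:] / totals[:-1]


def lambda_sign_disagreements(*total_series) -> int:
    """Count annual transitions on which trajectories disagree in trend.

    Each argument is a series of yearly total abundances; a transition
    counts as a disagreement when the sign of ``log(lambda_t)`` is not
    the same for all series.
    """
    if len(total_series) < 2:
        raise ValueError("need at least two trajectories to compare")
    signs = np.stack([np.sign(np.log(lambda_series(s))) for s in total_series])
    return int(np.sum(~np.all(signs == signs[0], axis=0)))


def trajectory_frame(N: AbundanceArray, C: HarvestArray):
    """Long-format (year, age, sex, N, C_pred) table for export."""
    import pandas as pd

    from harvestipm.data_io import SEXES

    rows = []
    for t, year in enumerate(N.year_labels):
        for a in range(N.N.shape[1]):
            for s, sex in enumerate(SEXES):
                c = C.counts[t, a - 1, s] if a >= 1 else 0.0
                rows.append((int(year), a, sex, N.N[t, a, s], c))
    return pd.DataFrame(rows, columns=["year", "age", "sex", "N", "C_pred"])
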