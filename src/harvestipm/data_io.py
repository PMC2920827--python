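"""Reading, writing, and pre-model correction of age-at-harvest inputs.

Harvested animals are registered with a reported sex and (for the aged
subset) an age from cementum annuli. Before model fitting the raw
registration data go through three corrections:

1. sex misclassification — reported sex is wrong at rates estimated from
   telemetered (known-sex) harvested animals; a 2x2 linear system per
   (year, age) cell recovers the true sex composition;
2. aged-fraction inflation — only a fraction of the harvest is aged each
   year; counts are scaled up assuming the aged subset is representative;
3. plus-group pooling — ages above a cutoff are pooled into a terminal
   "A+" class (old teeth are hardest to age), and illegal cub (age-0)
   records are dropped.

The canonical file format is long-format CSV with columns
``year, age, sex, count``; ``age`` is an integer or a plus-group label
like ``"10+"``; ``sex`` is ``"M"`` or ``"F"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Order of the sex axis in every (year, age, sex) array in the package.
SEXES = ("F", "M")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class HarvestArray:
    """Age-at-harvest counts ``C[t, a, s]`` for harvestable ages ``1..A``.

    Parameters
    ----------
    counts
        Array of shape ``(T, A, 2)``; axis 1 is age class ``1..A`` (no
        age-0 entries), axis 2 follows :data:`SEXES` (female, male).
        Counts may be non-integer after corrections.
    year_labels
        Calendar year of each row.
    plus_group
        Whether the terminal age class is a pooled ``A+`` class.
    """

    counts: np.ndarray
    year_labels: np.ndarray
    plus_group: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.year_labels = np.asarray(self.year_labels, dtype=int)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (T, A, 2)")
        if self.counts.shape[0] != self.year_labels.size:
            raise ValueError("year_labels length must match counts.shape[0]")
        if self.n_years < 2:
            raise ValueError("need at least 2 years of data")
        if self.n_ages < 3:
            raise ValueError("need at least 3 age classes")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_years(self) -> int:
        return self.counts.shape[0]

    @property
    def n_ages(self) -> int:
        return self.counts.shape[1]

    @property
    def ages(self) -> np.ndarray:
        """Nominal integer age of each age class (1..A)."""
        return np.arange(1, self.n_ages + 1)

    def year_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def copy(self) -> "HarvestArray":
        return HarvestArray(self.counts.copy(), self.year_labels.copy(), self.plus_group)


@dataclass(frozen=True)
class MisclassificationSample:
    """Known-sex (telemetered) harvested animals with recorded sex.

    ``n_true_female`` females were harvested of which
    ``n_female_recorded_male`` were registered as males, and analogously
    for males.
    """

    n_true_female: int
    n_female_recorded_male: int
    n_true_male: int
    n_male_recorded_female: int

    def __post_init__(self) -> None:
        if self.n_true_female <= 0 or self.n_true_male <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0 <= self.n_female_recorded_male <= self.n_true_female):
            raise ValueError("misclassified females outside [0, sample size]")
        if not (0 <= self.n_male_recorded_female <= self.n_true_male):
            raise ValueError("misclassified males outside [0, sample size]")

    @property
    def p_female_to_male(self) -> float:
        return self.n_female_recorded_male / self.n_true_female

    @property
    def p_male_to_female(self) -> float:
        return self.n_male_recorded_female / self.n_true_male


@dataclass(frozen=True)
class AgedFractionSeries:
    """Fraction of the registered harvest that was aged, per year."""

    years: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))
        if self.years.size != self.fractions.size:
            raise ValueError("years and fractions must align")
        if np.any(self.fractions <= 0) or np.any(self.fractions > 1):
            raise ValueError("aged fractions must lie in (0, 1]")

    def fraction_for(self, year: int) -> float:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"no aged fraction for year {year}")
        return float(self.fractions[idx[0]])


@dataclass(frozen=True)
class MarkRecaptureEstimate:
    """A mark-recapture abundance point estimate (cubs excluded)."""

    year: int
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise ValueError("estimate must be positive")
        if self.se < 0:
            raise ValueError("se must be non-negative")


@dataclass
class CovariateSeries:
    """Annual natural-food and hunter-effort indices.

    ``available`` may be False only for a leading block of years (the
    covariates were not collected early in the series); the covariate
    harvest sub-model replaces those years with free year effects.
    """

    food_index: np.ndarray
    effort_index: np.ndarray
    available: np.ndarray = None
    year_labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.food_index = np.asarray(self.food_index, dtype=float)
        self.effort_index = np.asarray(self.effort_index, dtype=float)
        n = self.food_index.size
        if self.effort_index.size != n:
            raise ValueError("food and effort series must align")
        if self.available is None:
            self.available = np.ones(n, dtype=bool)
        self.available = np.asarray(self.available, dtype=bool)
        if self.available.size != n:
            raise ValueError("availability flags must align with series")
        # unavailable years must form a leading block
        if self.available.size and not np.all(np.diff(self.available.astype(int)) >= 0):
            raise ValueError("unavailable years must be a leading block")
        if self.year_labels is None:
            self.year_labels = np.arange(n)
        self.year_labels = np.asarray(self.year_labels, dtype=int)

    @property
    def n_years(self) -> int:
        return self.food_index.size

    @property
    def missing_years(self) -> np.ndarray:
        """Indices of the leading covariate-missing years."""
        return np.nonzero(~self.available)[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_age_column(ages: pd.Series) -> tuple[np.ndarray, bool, int | None]:
    """Parse an age column of integers and optional 'A+' labels."""
    values = ages.astype(str).str.strip()
    is_plus = values.str.endswith("+")
    plus_ages = set()
    parsed = np.empty(len(values), dtype=int)
    for i, (v, p) in enumerate(zip(values, is_plus)):
        try:
            parsed[i] = int(v[:-1]) if p else int(v)
        except ValueError as exc:
            raise ValueError(f"cannot parse age label {v!r}") from exc
        if p:
            plus_ages.add(parsed[i])
    if len(plus_ages) > 1:
        raise ValueError(f"multiple distinct plus-group labels: {sorted(plus_ages)}")
    plus_age = plus_ages.pop() if plus_ages else None
    return parsed, plus_age is not None, plus_age


def read_harvest_table(path) -> HarvestArray:
    """Read a long-format harvest CSV into a dense :class:`HarvestArray`.

    The file must have columns ``year, age, sex, count``. Absent
    (year, age, sex) cells become zeros; a ``"10+"``-style age label sets
    the plus-group flag and the number of age classes.
    """
    df = pd.read_csv(path)
    required = {"year", "age", "sex", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"harvest table must have columns {sorted(required)}")
    if df["count"].lt(0).any():
        bad = df[df["count"] < 0].iloc[0]
        raise ValueError(
            f"negative count at (year={bad['year']}, age={bad['age']}, sex={bad['sex']})"
        )
    dup = df.duplicated(subset=["year", "age", "sex"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(
            f"duplicate key (year={bad['year']}, age={bad['age']}, sex={bad['sex']})"
        )
    ages, plus_group, plus_age = _parse_age_column(df["age"])
    df = df.assign(_age=ages)
    if (df["_age"] < 1).any():
        raise ValueError("age-at-harvest table may not contain age-0 (cub) rows")
    sex = df["sex"].astype(str).str.strip().str.upper()
    if not sex.isin(SEXES).all():
        raise ValueError("sex column must contain only 'M'/'F'")
    years = df["year"].astype(int)
    y0, y1 = years.min(), years.max()
    year_labels = np.arange(y0, y1 + 1)
    n_ages = int(df["_age"].max())
    if plus_group and plus_age != n_ages:
        raise ValueError(
            f"plus-group label {plus_age}+ must be the oldest age class (max {n_ages})"
        )
    counts = np.zeros((year_labels.size, n_ages, 2))
    ti = years.to_numpy() - y0
    ai = df["_age"].to_numpy() - 1
    si = np.array([SEXES.index(s) for s in sex])
    counts[ti, ai, si] = df["count"].to_numpy(dtype=float)
    return HarvestArray(counts, year_labels, plus_group=plus_group)


def write_harvest_table(data: HarvestArray, path) -> None:
    """Write a :class:`HarvestArray` back to the long-format CSV schema."""
    rows = []
    for t, year in enumerate(data.year_labels):
        for a in range(data.n_ages):
            label = f"{a + 1}+" if (data.plus_group and a == data.n_ages - 1) else str(a + 1)
            for s, sex in enumerate(SEXES):
                rows.append((int(year), label, sex, data.counts[t, a, s]))
    pd.DataFrame(rows, columns=["year", "age", "sex", "count"]).to_csv(path, index=False)


def read_covariates(path) -> CovariateSeries:
    """Read a covariate CSV with columns year, food_index, effort_index
    and an optional boolean ``available`` column."""
    df = pd.read_csv(path).sort_values("year")
    avail = df["available"].astype(bool).to_numpy() if "available" in df else None
    return CovariateSeries(
        df["food_index"].to_numpy(float), df["effort_index"].to_numpy(float),
        avail, df["year"].to_numpy(int),
    )


def write_covariates(covs: CovariateSeries, path) -> None:
    pd.DataFrame({
        "year": covs.year_labels, "food_index": covs.food_index,
        "effort_index": covs.effort_index, "available": covs.available,
    }).to_csv(path, index=False)


def read_mr_estimates(path) -> list:
    """Read mark-recapture estimates from a CSV with year, estimate, se."""
    df = pd.read_csv(path)
    return [MarkRecaptureEstimate(int(r.year), float(r.estimate), float(r.se))
            for r in df.itertuples()]


def write_mr_estimates(mr, path) -> None:
    pd.DataFrame([(e.year, e.estimate, e.se) for e in mr],
                 columns=["year", "estimate", "se"]).to_csv(path, index=False)


def read_aged_fractions(path) -> AgedFractionSeries:
    """Read per-year aged fractions from a CSV with year, fraction."""
    df = pd.read_csv(path)
    return AgedFractionSeries(df["year"].to_numpy(int), df["fraction"].to_numpy(float))


def read_misclassification(path) -> MisclassificationSample:
    """Read telemetry misclassification counts from a small JSON file."""
    import json

    with open(path) as fh:
        d = json.load(fh)
    return MisclassificationSample(**d)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration naming the input files."""
    import json

    import yaml

    with open(path) as fh:
        text = fh.read()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Pre-model corrections
# ---------------------------------------------------------------------------


def misclassification_matrix(rates: MisclassificationSample) -> np.ndarray:
    """Forward map from true (F, M) counts to observed (F, M) counts."""
    p_fm = rates.p_female_to_male
    p_mf = rates.p_male_to_female
    # column j = true sex j, row i = recorded sex i; sex order (F, M)
    return np.array([[1.0 - p_fm, p_mf], [p_fm, 1.0 - p_mf]])


def correct_sex_misclassification(
    observed: HarvestArray, rates: MisclassificationSample
) -> HarvestArray:
    """Recover true sex-specific counts from sex-as-recorded counts.

    Within every (year, age) cell the observed counts are the true counts
    pushed through the misclassification matrix; inverting that 2x2
    system conserves the cell total and may produce non-integer counts.
    Negative solutions (possible at extreme cells) are clipped to zero
    with the cell total preserved.
    """
    M = misclassification_matrix(rates)
    det = np.linalg.det(M)
    if abs(det) < 1e-12:
        raise ValueError(
            "misclassification rates sum to 1; the forward map is singular"
        )
    inv = np.linalg.inv(M)
    obs = observed.counts  # (T, A, 2) with sex axis (F, M)
    true = np.einsum("ij,taj->tai", inv, obs)
    if np.any(true < 0):
        neg = true < 0
        logger.warning(
            "sex-misclassification correction clipped %d negative cells", neg.sum()
        )
        totals = true.sum(axis=2, keepdims=True)
        true = np.clip(true, 0.0, None)
        scale = np.where(true.sum(axis=2, keepdims=True) > 0,
                         totals / np.maximum(true.sum(axis=2, keepdims=True), 1e-300), 1.0)
        true = true * scale
    return HarvestArray(true, observed.year_labels, observed.plus_group)


def inflate_for_unaged(
    aged_counts: HarvestArray, fractions: AgedFractionSeries
) -> HarvestArray:
    """Scale each year's aged counts up by 1/(fraction aged that year).

    Assumes ages of the aged subset are representative of the whole
    harvest, so the within-year age/sex distribution is unchanged.
    """
    out = aged_counts.counts.copy()
    for t, year in enumerate(aged_counts.year_labels):
        if out[t].sum() == 0:
            continue
        f = fractions.fraction_for(int(year))
        out[t] = out[t] / f
    return HarvestArray(out, aged_counts.year_labels, aged_counts.plus_group)


def pool_plus_group(records: pd.DataFrame, cutoff: int) -> HarvestArray:
    """Pool ages ``>= cutoff`` into a terminal plus-group.

    ``records`` is a long-format frame with columns ``year, age, sex,
    count`` and integer ages that may include age 0 (cubs) and ages past
    the cutoff. Cub records are illegal harvest and are dropped (the
    dropped total is logged); ages at or above ``cutoff`` are summed into
    the ``cutoff+`` class.
    """
    if cutoff < 2:
        raise ValueError("plus-group cutoff must be at least 2")
    df = records.copy()
    df["age"] = df["age"].astype(int)
    cubs = df["age"] == 0
    if cubs.any():
        logger.info("dropping %g cub (age-0) harvest records", df.loc[cubs, "count"].sum())
        df = df[~cubs]
    df["age"] = np.minimum(df["age"], cutoff)
    pooled = df.groupby(["year", "age", "sex"], as_index=False)["count"].sum()
    years = np.arange(pooled["year"].min(), pooled["year"].max() + 1)
    counts = np.zeros((years.size, cutoff, 2))
    ti = pooled["year"].to_numpy(dtype=int) - years[0]
    ai = pooled["age"].to_numpy(dtype=int) - 1
    si = np.array([SEXES.index(s) for s in pooled["sex"].astype(str).str.upper()])
    np.add.at(counts, (ti, ai, si), pooled["count"].to_numpy(dtype=float))
    return HarvestArray(counts, years, plus_group=True)
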