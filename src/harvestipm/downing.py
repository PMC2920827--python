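"""Downing virtual-population reconstruction from age-at-harvest data.

The reconstruction assumes zero natural mortality (every animal counted
is one that is eventually harvested) and collapses older ages into a
pooled class — by default 1, 2, 3+ — before a backward cohort recursion:

* terminal year: ``N[T, a] = C[T, a]``;
* younger classes: ``N[t, a] = C[t, a] + N[t+1, a+1]``;
* pooled class: ``N[t, P] = C[t, P] + N[t+1, P] - (N[t, P-1] - C[t, P-1])``,
  i.e. survivors of the class below, which reappear inside next year's
  pool, are not double-counted.

Because age within the pool is unobservable, the recursion is equivalent
to crediting each pooled harvest with the minimal age (exactly the
collapse age), so every harvested animal is counted alive in all prior
years back to class 1. The method estimates only the segment of the
population that dies by harvest; its yearly totals track relative trend
rather than absolute abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from harvestipm.data_io import SEXES, HarvestArray

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionResult:
    """Reconstructed abundance per year and collapsed age class."""

    abundance: np.ndarray  # (T, n_classes)
    year_labels: np.ndarray
    collapse_at: int
    sex_mode: str

    @property
    def totals(self) -> np.ndarray:
        return self.abundance.sum(axis=1)


def _collapse(counts: np.ndarray, collapse_at: int) -> np.ndarray:
    """Collapse an (T, A) age axis to classes 1..collapse_at-1, collapse_at+."""
    young = counts[:, : collapse_at - 1]
    pooled = counts[:, collapse_at - 1 :].sum(axis=1, keepdims=True)
    return np.concatenate([young, pooled], axis=1)


def downing_reconstruct(
    C: HarvestArray, collapse_at: int = 3, sex_mode: str = "combined"
) -> ReconstructionResult:
    """Run the Downing backward recursion on a harvest matrix.

    ``sex_mode`` selects ``"males"``, ``"females"``, or ``"combined"``
    (male and female matrices summed before reconstruction).
    """
    if C.n_years < 3:
        raise ValueError("need at least 3 years for a meaningful reconstruction")
    if not (2 <= collapse_at <= C.n_ages):
        raise ValueError("collapse_at must lie within the observed age range")
    if sex_mode == "males":
        counts = C.counts[:, :, SEXES.index("M")]
    elif sex_mode == "females":
        counts = C.counts[:, :, SEXES.index("F")]
    elif sex_mode == "combined":
        counts = C.counts.sum(axis=2)
    else:
        raise ValueError(f"unknown sex_mode {sex_mode!r}")

    harv = _collapse(counts, collapse_at)  # (T, P) with P = collapse_at classes
    T, P = harv.shape
    N = np.zeros_like(harv)
    N[T - 1] = harv[T - 1]
    clamped = 0
    for t in range(T - 2, -1, -1):
        for a in range(P - 1):
            N[t, a] = harv[t, a] + N[t + 1, min(a + 1, P - 1)]
        pooled = harv[t, P - 1] + N[t + 1, P - 1] - (N[t, P - 2] - harv[t, P - 2])
        if pooled < 0:
            clamped += 1
            pooled = 0.0
        N[t, P - 1] = pooled
    if clamped:
        logger.warning("Downing reconstruction clamped %d negative pooled cells", clamped)
    return ReconstructionResult(N, C.year_labels.copy(), collapse_at, sex_mode)
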