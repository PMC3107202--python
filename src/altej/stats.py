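"""Hypothesis tests and frequency/indel estimators for junction studies.

* exact / tie-corrected-asymptotic two-tailed Mann-Whitney U for comparing
  microhomology-length distributions between genotypes (or against a chance
  cohort),
* two-sided Fisher's exact test for junction-class contingency tables
  (e.g. long-insertion counts),
* pooled-variance two-tailed unpaired Student t-test for replicate
  translocation frequencies (Welch available by flag),
* translocation-frequency estimation from 96-well plate positivity counts,
  with an optional Poisson (limiting-dilution) correction for multiple
  events per well,
* the Surveyor-nuclease indel-percent formula and its inverse, and the
  colony-hybridization indel percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PlateAssay",
    "FrequencyEstimate",
    "mann_whitney_two_tailed",
    "fishers_exact_2x2",
    "t_test_unpaired_two_tailed",
    "translocation_frequency",
    "fold_change",
    "surveyor_indel_percent",
    "surveyor_fraction_cleaved",
    "colony_indel_percent",
]

# exact Mann-Whitney enumeration is used up to this many group assignments
EXACT_MW_MAX_CONFIGURATIONS = 200_000


@dataclass(frozen=True)
class PlateAssay:
    """Well-level qPCR positivity counts from a multiwell translocation assay."""

    wells: int
    cells_per_well: int
    positive_wells: int

    def __post_init__(self) -> None:
        if self.wells < 1:
            raise ValueError("wells must be >= 1")
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        if not (0 <= self.positive_wells <= self.wells):
            raise ValueError(
                f"positive_wells must be in [0, wells], got "
                f"{self.positive_wells}/{self.wells}"
            )


@dataclass(frozen=True)
class FrequencyEstimate:
    """Events-per-cell estimates; the Poisson correction is never below naive."""

    naive: float
    poisson_corrected: float


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U of sample x: pairs with x > y plus half the ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_two_tailed(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns ``(U_x, p)``.

    When the number of group assignments C(n_x + n_y, n_x) is small enough
    to enumerate, the p-value is exact over all permutations of the pooled
    data (ties handled exactly); otherwise a tie-corrected normal
    approximation is used.  The two-sided p is ``2 * min(one-sided)``
    capped at 1.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be nonempty")
    u_obs = _u_statistic(x, y)

    n_x, n_y = len(x), len(y)
    n_cfg = math.comb(n_x + n_y, n_x)
    if n_cfg <= EXACT_MW_MAX_CONFIGURATIONS:
        pooled = x + y
        idx = range(n_x + n_y)
        le = ge = 0
        for combo in combinations(idx, n_x):
            in_x = set(combo)
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in idx if i not in in_x]
            u = _u_statistic(xs, ys)
            if u <= u_obs + 1e-9:
                le += 1
            if u >= u_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / n_cfg)
        return u_obs, p

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def fishers_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables (with the same margins)
    no more probable than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be > 0")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def t_test_unpaired_two_tailed(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t-test on replicate measurements.

    Pooled-variance Student t with ``n_a + n_b - 2`` degrees of freedom by
    default; set ``welch=True`` for unequal variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must contain at least 2 replicates")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def translocation_frequency(plate: PlateAssay) -> FrequencyEstimate:
    """Events-per-cell frequency from plate positivity counts.

    ``naive = positives / (wells * cells_per_well)`` treats each positive
    well as exactly one event.  ``poisson_corrected = -ln(1 - positives /
    wells) / cells_per_well`` accounts for multiple independent events per
    well (limiting-dilution estimator); it is undefined at saturation (all
    wells positive), which raises with advice to dilute.
    """
    frac = plate.positive_wells / plate.wells
    naive = plate.positive_wells / (plate.wells * plate.cells_per_well)
    if plate.positive_wells == plate.wells:
        raise ValueError(
            "all wells positive: Poisson-corrected frequency undefined at "
            "saturation; replate at a lower cell density"
        )
    corrected = -math.log1p(-frac) / plate.cells_per_well
    return FrequencyEstimate(naive=naive, poisson_corrected=corrected)


def fold_change(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Frequency ratio rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator frequency must be > 0")
    ratio = Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def surveyor_indel_percent(fraction_cleaved: float) -> float:
    """Percent of alleles carrying indels from the Surveyor cleaved fraction.

    After denaturation and random reannealing, a fraction ``q`` of modified
    alleles produces a cleaved (heteroduplex) fraction ``1 - (1 - q)**2``;
    inverting gives ``% indel = 100 * (1 - sqrt(1 - fraction_cleaved))``.
    """
    if not (0.0 <= fraction_cleaved <= 1.0):
        raise ValueError("fraction_cleaved must be in [0, 1]")
    return 100.0 * (1.0 - math.sqrt(1.0 - fraction_cleaved))


def surveyor_fraction_cleaved(indel_percent: float) -> float:
    """Inverse of :func:`surveyor_indel_percent`."""
    if not (0.0 <= indel_percent <= 100.0):
        raise ValueError("indel_percent must be in [0, 100]")
    return 1.0 - (1.0 - indel_percent / 100.0) ** 2


def colony_indel_percent(non_hybridizing: int, total: int) -> float:
    """Percent imprecise joining from colony-hybridization counts."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not (0 <= non_hybridizing <= total):
        raise ValueError("require 0 <= non_hybridizing <= total")
    return 100.0 * non_hybridizing / total
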