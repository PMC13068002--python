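"""Poisson and double-Poisson trap-occupancy statistics.

A trap array loaded by stochastic flow captures, per trap, a Poisson-distributed
number of cells from each of two co-seeded populations (conventionally
population 1 = effector, population 2 = target).  The loading rate
``lambda = N_p / N_t`` — total trapped cells over total traps — fully
parameterises the marginal occupancy distribution, and under independent
loading the joint (k1 : k2) distribution is the product of the two marginals
(the "double Poisson").  This module provides the analytic model, empirical
estimators from observed occupancy tables, the cohort taxonomy used to bin
traps into effector-to-target (E:T) ratio groups, a chi-square goodness-of-fit
check, and a loading-rate design helper.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Cohort",
    "CohortLabel",
    "LoadingRate",
    "OccupancyTable",
    "FitReport",
    "OptimizeResult",
    "poisson_pmf",
    "empirical_frequency",
    "estimate_lambda",
    "double_poisson",
    "dual_frequency",
    "classify_cohort",
    "expected_cohort_counts",
    "goodness_of_fit",
    "optimize_lambda",
]


class Cohort(str, enum.Enum):
    """Taxonomy of trap occupancy pairs (k1 : k2).

    ``empty`` (0:0), single-population controls (>=1:0 effector-only and
    0:>=1 target-only), the 1:1 singlet, and every other doubly occupied
    combination as ``multiplet``.
    """

    EMPTY = "empty"
    EFFECTOR_ONLY = "effector_only_control"
    TARGET_ONLY = "target_only_control"
    SINGLET = "singlet_1to1"
    MULTIPLET = "multiplet"


@dataclass(frozen=True)
class CohortLabel:
    category: Cohort
    ratio: tuple[int, int]

    def __str__(self) -> str:  # "1:2" style
        return f"{self.ratio[0]}:{self.ratio[1]}"


@dataclass(frozen=True)
class LoadingRate:
    """Mean captured cells per trap for the two populations."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loading rates must be non-negative")


class OccupancyTable:
    """Per-trap occupancy counts for two populations.

    ``counts[k1, k2]`` is the number of traps holding exactly ``k1`` cells of
    population 1 and ``k2`` of population 2; the grand total is the trap count
    ``N_t``.
    """

    def __init__(
        self,
        counts: np.ndarray,
        population_labels: tuple[str, str] = ("effector", "target"),
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D (k1 x k2) matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("table must contain at least one trap")
        self.counts = counts.astype(np.int64)
        self.population_labels = tuple(population_labels)

    @property
    def n_traps(self) -> int:
        return int(self.counts.sum())

    # spec-facing alias
    N_t = n_traps

    def _pop_axis(self, population: str | int) -> int:
        if isinstance(population, int):
            if population in (1, 2):
                return population - 1
            raise ValueError("population index must be 1 or 2")
        try:
            return self.population_labels.index(population)
        except ValueError:
            raise ValueError(
                f"unknown population {population!r}; labels are {self.population_labels}"
            ) from None

    def marginal(self, population: str | int) -> np.ndarray:
        """n_t(k): number of traps holding k cells of the named population."""
        axis = self._pop_axis(population)
        return self.counts.sum(axis=1 - axis)

    def pair_count(self, k1: int, k2: int) -> int:
        if k1 < self.counts.shape[0] and k2 < self.counts.shape[1]:
            return int(self.counts[k1, k2])
        return 0

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[tuple[int, int]],
        population_labels: tuple[str, str] = ("effector", "target"),
    ) -> "OccupancyTable":
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        if np.any(pairs < 0):
            raise ValueError("occupancies must be non-negative")
        kmax = pairs.max(axis=0) if len(pairs) else np.array([0, 0])
        counts = np.zeros((kmax[0] + 1, kmax[1] + 1), dtype=np.int64)
        np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 1)
        return cls(counts, population_labels)

    def to_frame(self) -> pd.DataFrame:
        k1, k2 = np.nonzero(self.counts >= 0)
        return pd.DataFrame(
            {"k1": k1, "k2": k2, "count": self.counts[k1, k2]}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        population_labels: tuple[str, str] = ("effector", "target"),
    ) -> "OccupancyTable":
        df = pd.read_csv(path)
        required = {"k1", "k2", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"occupancy CSV needs columns {sorted(required)}")
        counts = np.zeros(
            (int(df.k1.max()) + 1, int(df.k2.max()) + 1), dtype=np.int64
        )
        counts[df.k1.to_numpy(), df.k2.to_numpy()] = df["count"].to_numpy()
        return cls(counts, population_labels)

    def __repr__(self) -> str:
        return (
            f"OccupancyTable(N_t={self.n_traps}, shape={self.counts.shape}, "
            f"labels={self.population_labels})"
        )


def poisson_pmf(lam: float, k: int) -> float:
    """P(lambda, k) = lambda^k e^(-lambda) / k!"""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if k != int(k) or k < 0:
        raise ValueError("k must be a non-negative integer")
    return float(stats.poisson.pmf(int(k), lam))


def empirical_frequency(table: OccupancyTable, k: int, population: str | int) -> float:
    """f(lambda, k) = n_t(k) / N_t for the named population."""
    if k < 0 or k != int(k):
        raise ValueError("k must be a non-negative integer")
    marginal = table.marginal(population)
    n_k = int(marginal[k]) if k < len(marginal) else 0
    return n_k / table.n_traps


def estimate_lambda(table: OccupancyTable, population: str | int) -> float:
    """lambda = N_p / N_t = sum_k k * n_t(k) / N_t."""
    marginal = table.marginal(population)
    k = np.arange(len(marginal))
    return float((k * marginal).sum() / table.n_traps)


def double_poisson(rates: LoadingRate, k1: int, k2: int) -> float:
    """Joint probability P(k1 : k2) = P(k1; lambda1) * P(k2; lambda2)."""
    return poisson_pmf(rates.lambda1, k1) * poisson_pmf(rates.lambda2, k2)


def dual_frequency(f1: float, f2: float) -> float:
    """Empirical dual loading frequency f(k1 : k2) = f(k1) * f(k2).

    Assumes the two populations load independently (no covariance correction).
    """
    for f in (f1, f2):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    return f1 * f2


def classify_cohort(k1: int, k2: int) -> CohortLabel:
    """Map an occupancy pair to its cohort category."""
    if k1 < 0 or k2 < 0 or k1 != int(k1) or k2 != int(k2):
        raise ValueError("occupancies must be non-negative integers")
    k1, k2 = int(k1), int(k2)
    if k1 == 0 and k2 == 0:
        cat = Cohort.EMPTY
    elif k2 == 0:
        cat = Cohort.EFFECTOR_ONLY
    elif k1 == 0:
        cat = Cohort.TARGET_ONLY
    elif k1 == 1 and k2 == 1:
        cat = Cohort.SINGLET
    else:
        cat = Cohort.MULTIPLET
    return CohortLabel(cat, (k1, k2))


def _binned_probs(lam: float, max_k: int) -> np.ndarray:
    """Marginal bin probabilities for k = 0..max_k-1 plus a >=max_k tail bin."""
    p = stats.poisson.pmf(np.arange(max_k), lam)
    return np.append(p, stats.poisson.sf(max_k - 1, lam))


def expected_cohort_counts(
    rates: LoadingRate, n_traps: int, max_k: int = 5
) -> pd.DataFrame:
    """Expected trap counts per (k1 : k2) bin under the double Poisson.

    Occupancies ``k >= max_k`` are aggregated into a single tail bin per
    population, so the expected counts sum exactly to ``n_traps``.  Columns:
    k1, k2 (tail bin reported as max_k with ``tail1``/``tail2`` True), cohort,
    probability, expected.
    """
    if n_traps <= 0:
        raise ValueError("n_traps must be positive")
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    p1 = _binned_probs(rates.lambda1, max_k)
    p2 = _binned_probs(rates.lambda2, max_k)
    joint = np.outer(p1, p2)
    rows = []
    for k1 in range(max_k + 1):
        for k2 in range(max_k + 1):
            rows.append(
                {
                    "k1": k1,
                    "k2": k2,
                    "tail1": k1 == max_k,
                    "tail2": k2 == max_k,
                    "cohort": classify_cohort(k1, k2).category.value,
                    "probability": joint[k1, k2],
                    "expected": n_traps * joint[k1, k2],
                }
            )
    return pd.DataFrame(rows)


def cohort_totals(expected: pd.DataFrame) -> pd.Series:
    """Aggregate an expected_cohort_counts table to per-cohort totals."""
    return expected.groupby("cohort")["expected"].sum()


@dataclass(frozen=True)
class FitReport:
    statistic: float
    dof: int
    pvalue: float
    lambda_hat: float
    n_bins: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def goodness_of_fit(
    table: OccupancyTable, population: str | int, min_expected: float = 5.0
) -> FitReport:
    """Chi-square test of the marginal occupancy against Poisson(lambda_hat).

    lambda is estimated from the same table, consuming one degree of freedom
    (dof = bins - 2).  Sparse tail bins with expected count below
    ``min_expected`` are merged upward into their lower neighbour, the
    standard validity recipe for chi-square on counts.
    """
    observed = table.marginal(population).astype(float)
    n_t = table.n_traps
    lam = estimate_lambda(table, population)
    kmax = len(observed) - 1
    expected = n_t * _binned_probs(lam, kmax + 1)[: len(observed)]
    # fold the analytic tail beyond the observed support into the last bin
    expected[-1] += n_t * stats.poisson.sf(kmax, lam)

    obs_bins, exp_bins = list(observed), list(expected)
    i = len(exp_bins) - 1
    while i > 0:
        if exp_bins[i] < min_expected:
            exp_bins[i - 1] += exp_bins.pop(i)
            obs_bins[i - 1] += obs_bins.pop(i)
        i -= 1
    if len(exp_bins) >= 2 and exp_bins[0] < min_expected:
        exp_bins[1] += exp_bins.pop(0)
        obs_bins[1] += obs_bins.pop(0)

    if len(exp_bins) < 2:
        raise ValueError("fewer than 2 usable bins after merging")
    obs = np.asarray(obs_bins)
    exp = np.asarray(exp_bins)
    statistic = float(((obs - exp) ** 2 / exp).sum())
    dof = len(exp) - 2  # one df for the total, one for lambda_hat
    if dof < 1:
        raise ValueError("not enough bins to test after estimating lambda")
    pvalue = float(stats.chi2.sf(statistic, dof))
    return FitReport(statistic, dof, pvalue, lam, len(exp))


def _cohort_probability(cohort: Cohort | tuple[int, int], lam1: float, lam2: float) -> float:
    """Closed-form probability of a cohort (or explicit pair) under the model."""
    if isinstance(cohort, tuple):
        return double_poisson(LoadingRate(lam1, lam2), *cohort)
    p0_1 = math.exp(-lam1)
    p0_2 = math.exp(-lam2)
    p1_1 = lam1 * p0_1
    p1_2 = lam2 * p0_2
    if cohort is Cohort.EMPTY:
        return p0_1 * p0_2
    if cohort is Cohort.EFFECTOR_ONLY:
        return (1 - p0_1) * p0_2
    if cohort is Cohort.TARGET_ONLY:
        return p0_1 * (1 - p0_2)
    if cohort is Cohort.SINGLET:
        return p1_1 * p1_2
    if cohort is Cohort.MULTIPLET:
        return (1 - p0_1) * (1 - p0_2) - p1_1 * p1_2
    raise ValueError(f"unknown cohort {cohort!r}")


@dataclass(frozen=True)
class OptimizeResult:
    rates: LoadingRate
    probability: float
    feasible: bool


def optimize_lambda(
    objective: Cohort | tuple[int, int],
    fixed_lambda2: float | None = None,
    target_probability: float | None = None,
    symmetric: bool = True,
    bounds: tuple[float, float] = (0.0, 5.0),
    grid_step: float = 0.05,
) -> OptimizeResult:
    """Design helper: choose loading rates for a cohort or (k1 : k2) objective.

    Without ``target_probability`` the objective probability is maximised on a
    deterministic grid followed by golden-section refinement (the objective is
    smooth in 1-D or 2-D).  With a target, the smallest lambda1 achieving it is
    found by root bracketing; an unattainable target is reported infeasible
    with the best achievable probability.
    """
    lo, hi = bounds

    if fixed_lambda2 is not None:
        prob = lambda l1: _cohort_probability(objective, l1, fixed_lambda2)
        make = lambda l1: LoadingRate(l1, fixed_lambda2)
    elif symmetric:
        prob = lambda l: _cohort_probability(objective, l, l)
        make = lambda l: LoadingRate(l, l)
    else:
        prob = None  # 2-D handled below
        make = None

    if prob is not None:
        grid = np.arange(lo, hi + grid_step, grid_step)
        values = np.array([prob(l) for l in grid])
        best = int(values.argmax())
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, len(grid) - 1)]
        if a < b:
            res = optimize.minimize_scalar(
                lambda l: -prob(l), bounds=(a, b), method="bounded",
                options={"xatol": 1e-6},
            )
            l_best, p_best = float(res.x), float(-res.fun)
            if values[best] > p_best:  # boundary maximum
                l_best, p_best = float(grid[best]), float(values[best])
        else:
            l_best, p_best = float(grid[best]), float(values[best])

        if target_probability is None:
            return OptimizeResult(make(l_best), p_best, True)
        if target_probability > p_best + 1e-12:
            return OptimizeResult(make(l_best), p_best, False)
        f = lambda l: prob(l) - target_probability
        if f(lo) >= 0:
            root = lo
        else:
            root = float(optimize.brentq(f, lo, l_best, xtol=1e-10))
        return OptimizeResult(make(root), prob(root), True)

    # free 2-D maximisation
    grid = np.arange(lo, hi + grid_step, grid_step)
    vals = np.array(
        [[_cohort_probability(objective, l1, l2) for l2 in grid] for l1 in grid]
    )
    i, j = np.unravel_index(vals.argmax(), vals.shape)
    res = optimize.minimize(
        lambda x: -_cohort_probability(objective, *np.clip(x, lo, hi)),
        x0=[grid[i], grid[j]],
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-12},
    )
    l1, l2 = np.clip(res.x, lo, hi)
    p_best = _cohort_probability(objective, l1, l2)
    if target_probability is not None and target_probability > p_best + 1e-12:
        return OptimizeResult(LoadingRate(l1, l2), p_best, False)
    return OptimizeResult(LoadingRate(float(l1), float(l2)), float(p_best), True)
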