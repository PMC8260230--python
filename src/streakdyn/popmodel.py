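"""Geometric-series model of NMP population growth under partial ingression.

The neuromesodermal progenitor (NMP) pool of the anterior primitive-streak
epiblast grows while a fixed fraction of daughter cells leaves the epiblast
at each division (ingression).  If each cell divides into two daughters and
each daughter independently ingresses with probability ``f_ingress``, the
expected population follows the geometric series

    U_n = q**n * U_0,      q = 2 * (1 - f_ingress),

where ``n`` counts division rounds, ``U_0`` is the starting population and
``q`` is the effective doubling parameter of the non-ingressed population.
``q > 1`` means net growth, ``q = 1`` steady state, ``q < 1`` decline.

This module provides the deterministic forward model, its inversion
(how many division rounds to reach a target population, and the implied
cell-cycle time), a stochastic branching-process counterpart, and
least-squares recovery of ``(q, f_ingress)`` from noisy population counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PopulationModel",
    "GrowthFit",
    "doubling_parameter",
    "project",
    "divisions_to_reach",
    "cycle_time",
    "fit_growth",
    "stochastic_growth_sim",
]


def doubling_parameter(f_ingress: float) -> float:
    """Effective doubling parameter ``q = 2 * (1 - f_ingress)``.

    ``f_ingress`` is the probability that a daughter cell ingresses
    (leaves the epiblast) after a division.  ``f = 0`` gives pure doubling
    (q = 2); ``f = 0.5`` gives a steady-state population (q = 1).
    """
    if not 0.0 <= f_ingress <= 1.0:
        raise ValueError(f"f_ingress must be in [0, 1], got {f_ingress}")
    return 2.0 * (1.0 - f_ingress)


@dataclass(frozen=True)
class PopulationModel:
    """Parameters of the geometric growth model.

    Attributes
    ----------
    U0 : initial population size (cells), >= 1.
    f_ingress : fraction of daughters ingressing per division, in [0, 1].
    """

    U0: float
    f_ingress: float

    def __post_init__(self) -> None:
        if self.U0 < 1:
            raise ValueError(f"U0 must be >= 1, got {self.U0}")
        doubling_parameter(self.f_ingress)  # range check

    @property
    def q(self) -> float:
        return doubling_parameter(self.f_ingress)


def _round_half_away(x: float) -> int:
    """Round half away from zero (530.15 -> 530, 689.19 -> 689, 0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def project(model: PopulationModel, n: int) -> tuple[float, int]:
    """Population after ``n`` division rounds: ``U_n = q**n * U0``.

    Returns ``(exact, rounded)`` where ``rounded`` uses round-half-away-
    from-zero (the convention that maps 530.15 -> 530 and 689.19 -> 689).
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"n must be a non-negative integer, got {n}")
    exact = model.q ** int(n) * model.U0
    return exact, _round_half_away(exact)


def divisions_to_reach(model: PopulationModel, target: float) -> tuple[int, int]:
    """Bracketing division counts ``(n_low, n_high)`` around a target size.

    ``n_high`` is the smallest n with ``U_n >= target``; ``n_low`` is
    ``n_high - 1``.  When the model already meets the target at n = 0 the
    degenerate pair (0, 0) is returned.  Requires a growing model
    (q > 1) whenever target > U0.
    """
    if target <= model.U0:
        return (0, 0)
    if model.q <= 1.0:
        raise ValueError(
            f"target {target} unreachable: q = {model.q} <= 1 and target > U0"
        )
    n_high = 0
    while project(model, n_high)[0] < target:
        n_high += 1
    return (n_high - 1, n_high)


def cycle_time(total_time_h: float, n: int) -> float:
    """Cell-cycle length (hours) implied by ``n`` divisions in ``total_time_h``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return total_time_h / n


@dataclass
class GrowthFit:
    """Result of :func:`fit_growth`."""

    q: float
    f_ingress: float
    q_ci: tuple[float, float]
    f_ci: tuple[float, float]
    slope: float
    intercept: float
    n_points: int
    bootstrap_q: np.ndarray = field(repr=False)


def fit_growth(
    counts: list[tuple[float, float]],
    assumed_cycle_time_h: float,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> GrowthFit:
    """Recover (q, f_ingress) from timed population counts.

    Ordinary least squares of log(count) on the division index
    ``n = time / assumed_cycle_time_h``; ``q = exp(slope)`` and
    ``f = 1 - q/2``.  A percentile bootstrap over count rows gives the
    confidence interval.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (time_h, cells) rows")
    if np.any(arr[:, 1] <= 0):
        raise ValueError("counts must be positive for log-linear fitting")
    n_idx = arr[:, 0] / assumed_cycle_time_h
    logc = np.log(arr[:, 1])

    def _fit(ni: np.ndarray, lc: np.ndarray) -> tuple[float, float]:
        res = stats.linregress(ni, lc)
        return res.slope, res.intercept

    slope, intercept = _fit(n_idx, logc)
    q_hat = float(np.exp(slope))

    rng = np.random.default_rng(seed)
    m = arr.shape[0]
    boot_q = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        # degenerate resample (all same time) -> refuse, redraw
        while np.ptp(n_idx[idx]) == 0:
            idx = rng.integers(0, m, size=m)
        s, _ = _fit(n_idx[idx], logc[idx])
        boot_q[b] = np.exp(s)
    lo, hi = np.quantile(boot_q, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return GrowthFit(
        q=q_hat,
        f_ingress=1.0 - q_hat / 2.0,
        q_ci=(float(lo), float(hi)),
        f_ci=(float(1 - hi / 2), float(1 - lo / 2)),
        slope=float(slope),
        intercept=float(intercept),
        n_points=m,
        bootstrap_q=boot_q,
    )


def stochastic_growth_sim(
    model: PopulationModel, n_generations: int, seed: int | None = None
) -> np.ndarray:
    """Branching-process counterpart of the geometric model.

    Each generation every cell divides into two daughters and each daughter
    independently ingresses with probability ``f_ingress``.  Returns the
    integer population counts for generations 0..n_generations (length
    ``n_generations + 1``).  The expectation of the final count equals
    ``project(model, n_generations)``; extinction (count 0) is possible and
    absorbing.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_generations + 1, dtype=np.int64)
    counts[0] = int(model.U0)
    p_stay = 1.0 - model.f_ingress
    for g in range(1, n_generations + 1):
        daughters = 2 * counts[g - 1]
        counts[g] = rng.binomial(daughters, p_stay) if daughters > 0 else 0
    return counts
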