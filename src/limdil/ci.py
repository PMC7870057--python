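"""Simulation-based confidence intervals by confidence-belt grid inversion.

For each parameter value on a grid (mean clones per well, or whole-transfection
clone number), platings are simulated and the equal-tailed central interval of
the outcome statistic at the nominal level is recorded (a *band*). The
confidence set for an observed outcome is the set of grid values whose band
contains the observation — the classical Neyman belt construction, here with
Monte-Carlo bands. Band edges are isotonically smoothed along the grid so the
accepted set is an interval rather than a union of intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .plating import PlateObservation, SimulationConfig, lambda_mle, p_positive

__all__ = [
    "QuantileBand",
    "ConfidenceInterval",
    "simulate_plating",
    "build_quantile_bands",
    "invert_ci",
    "efficiency_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantileBand:
    """Central interval of simulated outcomes at one grid value."""

    lambda_value: float
    k_lo: float
    k_hi: float
    n_sims_at_point: int
    wells_total: int = 96


@dataclass(frozen=True)
class ConfidenceInterval:
    """A grid-inversion confidence interval.

    ``lo``/``hi`` are endpoints on the parameter scale; ``one_sided`` marks
    intervals where the data pin only one side (k = 0 or a saturated plate);
    ``empty`` marks an observation outside every band (never expected with an
    adequate grid); ``saturated`` marks upper endpoints truncated at the grid
    maximum.
    """

    lo: float
    hi: float
    level: float
    n_sims_used: int
    one_sided: bool = False
    empty: bool = False
    saturated: bool = False

    def contains(self, value: float) -> bool:
        return (not self.empty) and self.lo <= value <= self.hi


def simulate_plating(
    lam: float, wells_total: int, rng: np.random.Generator, size: int | None = None
) -> int | np.ndarray:
    """Draw positive-well counts: k ~ Binomial(W, 1 - exp(-lam))."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    k = rng.binomial(wells_total, p_positive(lam), size=size)
    return int(k) if size is None else k


def _central_band(draws: np.ndarray, ci_level: float) -> tuple[float, float]:
    """Equal-tailed central interval; degenerates to the median at level 0."""
    alpha = 1.0 - ci_level
    lo = np.quantile(draws, alpha / 2, method="inverted_cdf")
    hi = np.quantile(draws, 1.0 - alpha / 2, method="inverted_cdf")
    return float(lo), float(hi)


def _smooth_edges(
    lo: np.ndarray, hi: np.ndarray, integer: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Isotonic (non-decreasing) smoothing of band edges along the grid.

    With ``integer`` the smoothed edges are rounded back to counts (isotonic
    pooling of an integer step function yields fractional block means).
    """
    lo_s = isotonic_regression(lo, increasing=True).x
    hi_s = isotonic_regression(hi, increasing=True).x
    if integer:
        lo_s = np.floor(lo_s + 0.5)
        hi_s = np.floor(hi_s + 0.5)
    return np.minimum(lo_s, hi_s), hi_s


def build_quantile_bands(
    wells_total: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ci_level: float | None = None,
) -> list[QuantileBand]:
    """Simulate platings across the lambda grid and record central bands.

    The total budget ``config.n_sims`` is divided equally across the grid;
    bands are isotonically smoothed in lambda so that band edges are
    monotonically non-decreasing (Monte-Carlo ripple removed).
    """
    rng = config.rng() if rng is None else rng
    level = config.ci_level if ci_level is None else ci_level
    grid = config.lambda_grid()
    m = config.sims_per_point
    if m < 100:
        logger.warning(
            "simulation budget %d gives only %d draws per grid point", config.n_sims, m
        )
    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    for i, lam in enumerate(grid):
        draws = simulate_plating(float(lam), wells_total, rng, size=m)
        lo[i], hi[i] = _central_band(draws, level)
    lo, hi = _smooth_edges(lo, hi, integer=True)
    return [
        QuantileBand(float(g), float(a), float(b), m, wells_total)
        for g, a, b in zip(grid, lo, hi)
    ]


def _interp_endpoints(
    grid: np.ndarray, inside: np.ndarray, log_scale: bool
) -> tuple[float, float]:
    """Interval endpoints at the midpoint of the acceptance boundary.

    The true boundary of the acceptance region lies between the outermost
    accepted grid value and its first rejected neighbour; the midpoint
    (geometric on a log grid) halves the quantisation error of reporting the
    accepted grid value itself.
    """
    idx = np.flatnonzero(inside)
    i_lo, i_hi = int(idx[0]), int(idx[-1])

    def mid(a: float, b: float) -> float:
        return math.sqrt(a * b) if log_scale else 0.5 * (a + b)

    lo = grid[i_lo] if i_lo == 0 else mid(grid[i_lo - 1], grid[i_lo])
    hi = grid[i_hi] if i_hi == len(grid) - 1 else mid(grid[i_hi], grid[i_hi + 1])
    return float(lo), float(hi)


def invert_ci(observed_k: int, bands: list[QuantileBand]) -> ConfidenceInterval:
    """Lambda confidence interval: grid values whose band contains observed_k.

    The lower endpoint is 0 (one-sided) when the band at the grid minimum
    contains the observation; the upper endpoint is flagged ``saturated``
    when the band at the grid maximum does.
    """
    if not bands:
        raise ValueError("no bands supplied")
    w = bands[0].wells_total
    if not 0 <= observed_k <= w:
        raise ValueError(f"observed_k must be in [0, {w}]")
    grid = np.array([b.lambda_value for b in bands])
    inside = np.array([b.k_lo <= observed_k <= b.k_hi for b in bands])
    if not inside.any():
        logger.warning("observed count %d lies outside every band", observed_k)
        return ConfidenceInterval(math.nan, math.nan, math.nan, bands[0].n_sims_at_point, empty=True)
    lo, hi = _interp_endpoints(grid, inside, log_scale=True)
    one_sided = False
    saturated = False
    if inside[0] and observed_k == 0:
        lo = 0.0
        one_sided = True
    if inside[-1] and observed_k == w:
        hi = grid[-1]
        saturated = True
        one_sided = True
    # The point estimate must lie inside its own interval; with adequately
    # simulated bands this is automatic, a guard against residual MC noise.
    if 0 < observed_k < w:
        mle = lambda_mle(observed_k, w)
        if bands[0].lambda_value <= mle <= bands[-1].lambda_value:
            lo, hi = min(lo, mle), max(hi, mle)
    n_sims = sum(b.n_sims_at_point for b in bands)
    return ConfidenceInterval(lo, hi, math.nan, n_sims, one_sided=one_sided, saturated=saturated)


def _clone_grid(observations: list[PlateObservation], config: SimulationConfig) -> np.ndarray:
    scale = [o.wells_total / o.fraction_plated for o in observations]
    n_min = config.lambda_grid_min * min(scale)
    n_max = config.lambda_grid_max * max(scale)
    return np.geomspace(n_min, n_max, config.lambda_grid_points)


def efficiency_ci(
    observations: list[PlateObservation],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ConfidenceInterval:
    """Clone-number confidence interval by belt inversion over an N grid.

    At each candidate clone number N all plates are simulated jointly and the
    combined sufficient statistic T = sum_i k_i / f_i (positive wells weighted
    by the reciprocal plated fraction) is banded; N is accepted when the
    observed T lies in its band. A single unsaturated plate reduces to the
    one-plate lambda inversion mapped through N = lambda*W/f.
    """
    if not observations:
        raise ValueError("need at least one plate observation")
    rng = config.rng() if rng is None else rng
    grid = _clone_grid(observations, config)
    m = config.sims_per_point
    if m < 100:
        logger.warning(
            "simulation budget %d gives only %d draws per grid point", config.n_sims, m
        )

    weights = np.array([1.0 / o.fraction_plated for o in observations])
    wells = np.array([o.wells_total for o in observations])
    fracs = np.array([o.fraction_plated for o in observations])
    t_obs = float(np.dot(weights, [o.wells_positive for o in observations]))
    t_max = float(np.dot(weights, wells))

    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    for i, n in enumerate(grid):
        p = -np.expm1(-n * fracs / wells)
        draws = rng.binomial(wells[None, :], p[None, :], size=(m, len(observations)))
        t = draws @ weights
        lo[i], hi[i] = _central_band(t, config.ci_level)
    lo, hi = _smooth_edges(lo, hi)

    inside = (lo <= t_obs) & (t_obs <= hi)
    n_sims = int(m * grid.size)
    if not inside.any():
        logger.warning("observed statistic %.1f lies outside every band", t_obs)
        return ConfidenceInterval(
            math.nan, math.nan, config.ci_level, n_sims, empty=True
        )
    n_lo, n_hi = _interp_endpoints(grid, inside, log_scale=True)
    one_sided = False
    saturated = False
    if t_obs == 0 and inside[0]:
        n_lo = 0.0
        one_sided = True
    if t_obs == t_max and inside[-1]:
        n_hi = float(grid[-1])
        saturated = True
        one_sided = True
    return ConfidenceInterval(
        n_lo, n_hi, config.ci_level, n_sims, one_sided=one_sided, saturated=saturated
    )
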