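"""Poisson single-hit model for limiting-dilution platings.

A transfection yields N independent stable clones. A fraction ``f`` of the
transfection is distributed over a plate of ``W`` wells, so each well receives
a Poisson-distributed number of clones with mean lambda = N*f/W, and a well is
scored positive iff it received at least one clone:

    P(well positive) = 1 - exp(-lambda)

The observed positive-well count on a plate is therefore
Binomial(W, 1 - exp(-N*f/W)), and N is estimated by maximising the joint
binomial likelihood across plates of one transfection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PlateObservation",
    "TransfectionEstimate",
    "SimulationConfig",
    "p_positive",
    "lambda_mle",
    "clones_from_lambda",
    "loglik_clones",
    "estimate_efficiency",
    "SaturatedPlateError",
]

# Positive-well counts below machine resolution of log(1-k/W) never occur for
# W <= 1e15, so plain float arithmetic suffices throughout.

# representable minimum rather than -inf: keeps the bounded optimizer's
# interpolation arithmetic finite when it probes an impossible clone number
_NEG_INF = -1e12


class SaturatedPlateError(ValueError):
    """All wells positive: lambda has no finite maximum-likelihood estimate."""


@dataclass(frozen=True)
class PlateObservation:
    """One plate of a limiting-dilution assay.

    Parameters
    ----------
    plate_id : str
        Free-text plate label.
    wells_total : int
        Number of wells on the plate (W), typically 96.
    wells_positive : int
        Wells with outgrowth after selection (k).
    fraction_plated : float
        Fraction of the whole transfection distributed on this plate
        (f, in (0, 1]).
    condition : str
        Free-text condition label (e.g. ``induced``).
    """

    plate_id: str
    wells_total: int
    wells_positive: int
    fraction_plated: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.wells_total < 1:
            raise ValueError(f"plate {self.plate_id!r}: wells_total must be >= 1")
        if not 0 <= self.wells_positive <= self.wells_total:
            raise ValueError(
                f"plate {self.plate_id!r}: wells_positive must be in "
                f"[0, {self.wells_total}], got {self.wells_positive}"
            )
        if not 0 < self.fraction_plated <= 1:
            raise ValueError(
                f"plate {self.plate_id!r}: fraction_plated must be in (0, 1], "
                f"got {self.fraction_plated}"
            )

    @property
    def saturated(self) -> bool:
        return self.wells_positive == self.wells_total


@dataclass(frozen=True)
class TransfectionEstimate:
    """Estimated clone numbers for one transfection.

    ``lambda_hat`` is the per-plate mean clones per well implied by ``clones_hat``
    for the first plate in the input; ``clones_hat`` is the whole-transfection
    clone number N. When every plate is saturated the estimate is a one-sided
    lower bound (``lower_bound_only``).
    """

    lambda_hat: float
    clones_hat: float
    ci_level: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    n_sims_used: int = 0
    saturated_plates: tuple[str, ...] = ()
    lower_bound_only: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo budget and grids for simulation-based confidence intervals.

    Defaults follow the study design: a total budget of 10^6 simulated
    platings spread over a log-spaced lambda grid from 0.001 to 10 cells
    well^-1, 90% intervals, and a loss-probability grid over [0, 1].
    """

    n_sims: int = 1_000_000
    lambda_grid_min: float = 0.001
    lambda_grid_max: float = 10.0
    lambda_grid_points: int = 200
    ci_level: float = 0.90
    q_grid_step: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.lambda_grid_min < self.lambda_grid_max:
            raise ValueError("need 0 < lambda_grid_min < lambda_grid_max")
        if self.lambda_grid_points < 2:
            raise ValueError("lambda_grid_points must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.q_grid_step <= 0.5:
            raise ValueError("q_grid_step must be in (0, 0.5]")

    @property
    def sims_per_point(self) -> int:
        return max(1, self.n_sims // self.lambda_grid_points)

    def lambda_grid(self) -> np.ndarray:
        """Log-spaced lambda grid (cells per well)."""
        return np.geomspace(
            self.lambda_grid_min, self.lambda_grid_max, self.lambda_grid_points
        )

    def q_grid(self) -> np.ndarray:
        """Loss-probability grid over [0, 1] at q_grid_step resolution."""
        n = int(round(1.0 / self.q_grid_step))
        return np.linspace(0.0, 1.0, n + 1)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def p_positive(lam: float) -> float:
    """Probability that a well is positive at mean ``lam`` clones per well.

    Single-hit model: positive iff >= 1 clone, so P = 1 - exp(-lam).
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return -math.expm1(-lam)


def lambda_mle(wells_positive: int, wells_total: int) -> float:
    """Maximum-likelihood mean clones per well from a positive-well count.

    Inverts the single-hit model: lambda = -ln(1 - k/W). Returns 0 for k = 0.

    Raises
    ------
    SaturatedPlateError
        If every well is positive (k = W): the MLE is unbounded and the
        caller must treat the plate as a lower bound only.
    """
    if wells_total < 1:
        raise ValueError("wells_total must be >= 1")
    if not 0 <= wells_positive <= wells_total:
        raise ValueError("need 0 <= wells_positive <= wells_total")
    if wells_positive == wells_total:
        raise SaturatedPlateError(
            f"all {wells_total} wells positive: lambda MLE is unbounded"
        )
    return -math.log1p(-wells_positive / wells_total)


def clones_from_lambda(lam: float, wells_total: int, fraction_plated: float) -> float:
    """Scale a per-well density to whole-transfection clones: N = lam*W/f."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < fraction_plated <= 1:
        raise ValueError("fraction_plated must be in (0, 1]")
    return lam * wells_total / fraction_plated


def loglik_clones(n_clones: float, observations: list[PlateObservation]) -> float:
    """Joint log-likelihood of plate counts given whole-transfection clones N.

    Sum over plates of Binomial(k_i; W_i, 1 - exp(-N f_i / W_i)) log-pmf
    (binomial coefficients dropped: constant in N). Returns a representable
    minimum when the data are impossible (N = 0 with positive wells).
    """
    if n_clones < 0:
        raise ValueError("clone number must be >= 0")
    total = 0.0
    for obs in observations:
        lam = n_clones * obs.fraction_plated / obs.wells_total
        p = -math.expm1(-lam)
        k, w = obs.wells_positive, obs.wells_total
        if p == 0.0:
            if k > 0:
                return _NEG_INF
            continue  # log(1-p)*W = 0
        if p == 1.0:  # numerically saturated; only k = W has mass
            if k < w:
                return _NEG_INF
            continue
        # binomial coefficient omitted: constant in N
        total += k * math.log(p) + (w - k) * math.log1p(-p)
    return total


def _single_plate_estimate(obs: PlateObservation) -> float:
    return clones_from_lambda(
        lambda_mle(obs.wells_positive, obs.wells_total),
        obs.wells_total,
        obs.fraction_plated,
    )


def estimate_efficiency(observations: list[PlateObservation]) -> TransfectionEstimate:
    """Joint maximum-likelihood clone number from one or more plates.

    All plates must come from the same transfection; they are treated as
    independent aliquots. Saturated plates (k = W) contribute their likelihood
    term; if *all* plates are saturated the returned estimate is a one-sided
    lower bound (the smallest N making all-positive plates likelier than 10%)
    and is flagged ``lower_bound_only``.
    """
    if not observations:
        raise ValueError("need at least one plate observation")

    saturated = tuple(o.plate_id for o in observations if o.saturated)

    if all(o.wells_positive == 0 for o in observations):
        return TransfectionEstimate(
            lambda_hat=0.0, clones_hat=0.0, saturated_plates=saturated
        )

    if len(saturated) == len(observations):
        # Lower bound: smallest N with P(all plates all-positive | N) >= 0.10.
        n_lo = _all_saturated_lower_bound(observations, level=0.90)
        lam0 = n_lo * observations[0].fraction_plated / observations[0].wells_total
        return TransfectionEstimate(
            lambda_hat=lam0,
            clones_hat=n_lo,
            saturated_plates=saturated,
            lower_bound_only=True,
        )

    # Bracket from per-plate closed forms on the unsaturated plates.
    per_plate = [_single_plate_estimate(o) for o in observations if not o.saturated]
    lo = 0.5 * min(per_plate)
    hi = 4.0 * max(per_plate) + 1.0
    # Saturated plates push the optimum up; widen until the bracket holds.
    while loglik_clones(hi, observations) > loglik_clones(0.99 * hi, observations):
        hi *= 4.0

    res = minimize_scalar(
        lambda n: -loglik_clones(n, observations),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6 * max(per_plate)},
    )
    n_hat = float(res.x)
    # The objective is unimodal; guard against a bracket edge beating the
    # interior optimum for single-plate inputs where the closed form is exact.
    if len(per_plate) == len(observations) == 1:
        n_hat = per_plate[0]
    lam0 = n_hat * observations[0].fraction_plated / observations[0].wells_total
    return TransfectionEstimate(
        lambda_hat=lam0, clones_hat=n_hat, saturated_plates=saturated
    )


def _all_saturated_lower_bound(
    observations: list[PlateObservation], level: float
) -> float:
    """Smallest N with P(every plate fully positive | N) >= 1 - level."""
    target = math.log(1.0 - level)

    def log_p_all_sat(n: float) -> float:
        s = 0.0
        for o in observations:
            lam = n * o.fraction_plated / o.wells_total
            p = -math.expm1(-lam)
            if p <= 0:
                return _NEG_INF
            s += o.wells_total * math.log(p)
        return s

    lo, hi = 1.0, 10.0
    while log_p_all_sat(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if log_p_all_sat(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi
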