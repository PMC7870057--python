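"""Replica-plating inference of per-cell selectable-marker loss.

After induction, each cell has independently lost the resistance marker with
probability q. Cells are plated at a mean of lambda cells per well without
selection; a populated well becomes drug-*sensitive* on the selective replica
iff every one of its founder cells lost the marker. With Poisson well filling
(zero-truncated, since only populated wells are scored) and binomial per-cell
loss, the probability that a populated well is sensitive is

    P(sensitive | populated) = (exp(-lambda*(1-q)) - exp(-lambda)) / (1 - exp(-lambda))

which tends to q as lambda -> 0 (single-cell wells) and to q^infinity-like
suppression as wells get crowded. q is estimated by inverting this relation
at the observed sensitive fraction s/n, and its confidence interval by a
belt simulation over a grid of q with lambda resampled from its estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression

from .plating import SimulationConfig, lambda_mle

__all__ = [
    "LossExperiment",
    "LossEstimate",
    "p_sensitive",
    "q_mle",
    "lambda_se",
    "loss_ci",
    "fisher_exact_two_sided",
    "per_generation_loss",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossExperiment:
    """Replica-plating counts for one clone under one condition.

    ``populated_wells`` (n) are wells positive on the drug-free replica;
    ``sensitive_wells`` (s) are those positive without drug but negative with
    drug. ``nominal_lambda`` is the intended plating density (cells per well),
    used as a fallback when lambda cannot be estimated from the counts.
    """

    clone_id: str
    condition: str
    wells_total: int
    populated_wells: int
    sensitive_wells: int
    nominal_lambda: float | None = None

    def __post_init__(self) -> None:
        if self.wells_total < 1:
            raise ValueError(f"{self.clone_id}: wells_total must be >= 1")
        if not 0 <= self.sensitive_wells <= self.populated_wells <= self.wells_total:
            raise ValueError(
                f"{self.clone_id}: need 0 <= sensitive <= populated <= wells_total, "
                f"got {self.sensitive_wells}/{self.populated_wells}/{self.wells_total}"
            )
        if self.nominal_lambda is not None and self.nominal_lambda <= 0:
            raise ValueError(f"{self.clone_id}: nominal_lambda must be > 0")


@dataclass(frozen=True)
class LossEstimate:
    """Per-cell loss probability with its simulation-based interval."""

    q_hat: float
    lambda_hat: float
    lambda_se: float
    ci_level: float
    ci_lo: float
    ci_hi: float
    one_sided: bool = False
    empty: bool = False
    n_sims_used: int = 0


def p_sensitive(lam: float, q: float) -> float:
    """Probability that a populated well is drug-sensitive.

    A populated well is sensitive iff all its (zero-truncated Poisson) founder
    cells lost the marker. At lambda = 0 the analytic single-cell limit q is
    returned.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if lam == 0.0:
        return q
    return float(_p_sensitive_arr(lam, q))


def _p_sensitive_arr(lam, q):
    """Vectorised p_sensitive; lam > 0 elementwise (limit handled by caller)."""
    lam = np.asarray(lam, dtype=float)
    q = np.asarray(q, dtype=float)
    num = np.exp(-lam * (1.0 - q)) - np.exp(-lam)
    den = -np.expm1(-lam)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.where(lam == 0.0, q, out)
    return np.clip(out, 0.0, 1.0)


def q_mle(sensitive_wells: int, populated_wells: int, lam: float) -> float:
    """Per-cell loss probability solving p_sensitive(lam, q) = s/n.

    Closed form: q = 1 + ln(s/n * (1 - e^-lam) + e^-lam) / lam.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if populated_wells < 1:
        raise ValueError("populated_wells must be >= 1")
    if not 0 <= sensitive_wells <= populated_wells:
        raise ValueError("need 0 <= sensitive_wells <= populated_wells")
    frac = sensitive_wells / populated_wells
    if frac == 0.0:
        return 0.0
    if frac == 1.0:
        return 1.0
    q = 1.0 + math.log(frac * -math.expm1(-lam) + math.exp(-lam)) / lam
    return min(max(q, 0.0), 1.0)


def lambda_se(wells_positive: int, wells_total: int) -> float:
    """Delta-method standard error of lambda_hat = -ln(1 - k/W).

    With p_hat = k/W, Var(p_hat) = p(1-p)/W and d lambda/dp = 1/(1-p), so
    SE = sqrt(p / (W (1-p))). Undefined at k = 0 or k = W.
    """
    if not 0 < wells_positive < wells_total:
        raise ValueError("SE undefined for k = 0 or k = W")
    p = wells_positive / wells_total
    return math.sqrt(p / (wells_total * (1.0 - p)))


def _lambda_for_experiment(
    exp: LossExperiment, fallback_se: float
) -> tuple[float, float]:
    """Lambda estimate and spread for belt resampling.

    Estimated from the populated-well count of the same plate; the nominal
    plating density is the fallback when the count is degenerate (0 or W),
    with ``fallback_se`` as the resampling spread.
    """
    n, w = exp.populated_wells, exp.wells_total
    if 0 < n < w:
        return lambda_mle(n, w), lambda_se(n, w)
    if exp.nominal_lambda is None:
        raise ValueError(
            f"{exp.clone_id}: populated wells {n}/{w} leave lambda unidentified "
            "and no nominal_lambda is given"
        )
    return exp.nominal_lambda, fallback_se


def loss_ci(
    experiment: LossExperiment,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    fallback_se: float = 0.2,
    resimulate_populated: bool = False,
) -> LossEstimate:
    """Belt-simulation confidence interval for the per-cell loss probability.

    For each q on a grid over [0, 1] (step ``config.q_grid_step``), replica
    readouts are simulated with lambda* drawn Normal(lambda_hat, SE)
    truncated at 0 and sensitive ~ Binomial(n, p_sensitive(lambda*, q)); q is
    accepted when the observed sensitive count lies within the equal-tailed
    central ``ci_level`` interval of the simulated counts. The simulation
    conditions on the observed populated count n — the quantity lambda_hat is
    estimated from — and carries lambda uncertainty through the resampled
    lambda* only; ``resimulate_populated`` instead redraws populated ~
    Binomial(W, 1 - e^-lambda*) each time (an unconditional belt, slightly
    conservative). Common random numbers are used across the q grid, and
    band edges are isotonically smoothed in q, so the accepted set is an
    interval. s = 0 (and s = n) are reported one-sided at the full level.
    """
    rng = config.rng() if rng is None else rng
    lam_hat, lam_sd = _lambda_for_experiment(experiment, fallback_se)
    s, n, w = experiment.sensitive_wells, experiment.populated_wells, experiment.wells_total
    level = config.ci_level
    q_grid = config.q_grid()
    m = max(1, config.n_sims // q_grid.size)
    if m < 100:
        logger.warning(
            "simulation budget %d gives only %d draws per q grid point",
            config.n_sims,
            m,
        )

    # lambda* and the populated counts do not depend on q: draw once and share
    # across the grid (common random numbers suppress band ripple).
    a = (0.0 - lam_hat) / lam_sd
    lam_star = stats.truncnorm.rvs(
        a, np.inf, loc=lam_hat, scale=lam_sd, size=m, random_state=rng
    )
    if resimulate_populated:
        populated = rng.binomial(w, -np.expm1(-lam_star))
    else:
        populated = np.full(m, n)

    alpha = 1.0 - level
    one_sided = s == 0 or s == n
    if s == 0:
        # accept while s=0 sits in the lower `level` mass: alpha-quantile == 0
        levels = (alpha, 1.0)
    elif s == n:
        levels = (0.0, level)
    else:
        levels = (alpha / 2, 1.0 - alpha / 2)

    k_lo = np.empty(q_grid.size)
    k_hi = np.empty(q_grid.size)
    for i, q in enumerate(q_grid):
        p_s = _p_sensitive_arr(lam_star, q)
        sens = rng.binomial(populated, p_s)
        k_lo[i] = np.quantile(sens, levels[0], method="inverted_cdf")
        k_hi[i] = np.quantile(sens, levels[1], method="inverted_cdf")
    k_lo = np.floor(isotonic_regression(k_lo, increasing=True).x + 0.5)
    k_hi = np.floor(isotonic_regression(k_hi, increasing=True).x + 0.5)
    k_hi = np.maximum(k_hi, k_lo)

    accepted = (k_lo <= s) & (s <= k_hi)
    q_hat = q_mle(s, n, lam_hat)
    n_sims = int(m * q_grid.size)
    if not accepted.any():
        logger.warning(
            "%s: empty acceptance set; consider a finer q grid "
            "(step %.4g) or larger budget",
            experiment.clone_id,
            config.q_grid_step,
        )
        return LossEstimate(
            q_hat, lam_hat, lam_sd, level, math.nan, math.nan,
            one_sided=one_sided, empty=True, n_sims_used=n_sims,
        )
    # endpoints at the midpoint of the acceptance boundary (halves the grid
    # quantisation error), clamped to [0, 1]
    idx = np.flatnonzero(accepted)
    step = float(q_grid[1] - q_grid[0])
    if s == 0:
        lo = 0.0
    else:
        lo = float(q_grid[idx[0]]) - (0.5 * step if idx[0] > 0 else 0.0)
    if s == n:
        hi = 1.0
    else:
        hi = float(q_grid[idx[-1]]) + (0.5 * step if idx[-1] < q_grid.size - 1 else 0.0)
    # the point estimate belongs to its own interval (guards MC edge noise)
    lo, hi = min(lo, q_hat), max(hi, q_hat)
    return LossEstimate(
        q_hat, lam_hat, lam_sd, level, lo, hi,
        one_sided=one_sided, n_sims_used=n_sims,
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Two-sided by the minimum-likelihood convention: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more probable
    than the observed one. A zero margin gives p = 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("table must hold non-negative integers")
        arr = arr.astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def per_generation_loss(p_total: float, duration_h: float, doubling_h: float) -> float:
    """Convert a total loss fraction over an interval to a per-generation one.

    Under (1 - p_gen)^generations = 1 - p_total with generations =
    duration_h / doubling_h:  p_gen = 1 - (1 - p_total)^(doubling_h/duration_h).
    """
    if not 0.0 <= p_total <= 1.0:
        raise ValueError("p_total must be in [0, 1]")
    if duration_h <= 0 or doubling_h <= 0:
        raise ValueError("durations must be positive")
    if p_total == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_total) ** (doubling_h / duration_h)
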