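"""Ground-truth generators emulating the limiting-dilution experiments.

Two scenarios are modelled:

* transfection — a known number of independent clones N is distributed over
  plates at fractions f_i, wells fill Poisson at lambda_i = N*f_i/W_i, and a
  well is positive iff it received >= 1 clone;
* marker loss — cells that each lost the marker with probability q are plated
  at lambda cells per well; a populated well is sensitive iff all its founder
  cells lost the marker.

Generators are pure functions of (truth, seed), so every inference stage can
be validated against known truth without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ci import efficiency_ci
from .loss import LossExperiment, loss_ci, _p_sensitive_arr
from .plating import PlateObservation, SimulationConfig, estimate_efficiency

__all__ = [
    "SyntheticTruth",
    "gen_transfection",
    "gen_loss_experiment",
    "run_coverage_study",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic scenario (exactly one of the two).

    Transfection scenario: ``true_clones`` with ``design`` a list of
    (wells_total, fraction_plated) pairs. Loss scenario: ``true_q`` and
    ``true_lambda`` with ``design`` a list of (wells_total, nominal_lambda)
    pairs (a single plate is typical).
    """

    seed: int
    true_clones: float | None = None
    true_q: float | None = None
    true_lambda: float | None = None
    design: tuple[tuple[int, float], ...] = ((96, 0.2), (96, 0.04))

    def __post_init__(self) -> None:
        is_transfection = self.true_clones is not None
        is_loss = self.true_q is not None
        if is_transfection == is_loss:
            raise ValueError("populate exactly one of true_clones / true_q")
        if is_transfection and self.true_clones < 0:
            raise ValueError("true_clones must be >= 0")
        if is_loss:
            if not 0.0 <= self.true_q <= 1.0:
                raise ValueError("true_q must be in [0, 1]")
            if self.true_lambda is None or self.true_lambda <= 0:
                raise ValueError("loss scenario needs true_lambda > 0")

    @property
    def scenario(self) -> str:
        return "transfection" if self.true_clones is not None else "loss"


def gen_transfection(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> list[PlateObservation]:
    """Simulate positive-well counts for each plate of the design."""
    if truth.scenario != "transfection":
        raise ValueError("transfection scenario required")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    plates = []
    for i, (w, f) in enumerate(truth.design):
        lam = truth.true_clones * f / w
        k = int(rng.binomial(w, -np.expm1(-lam)))
        plates.append(
            PlateObservation(
                plate_id=f"sim{i}", wells_total=w, wells_positive=k,
                fraction_plated=f, condition="synthetic",
            )
        )
    return plates


def gen_loss_experiment(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> LossExperiment:
    """Simulate one replica-plating readout at (true_lambda, true_q)."""
    if truth.scenario != "loss":
        raise ValueError("loss scenario required")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    w = truth.design[0][0]
    lam, q = truth.true_lambda, truth.true_q
    populated = int(rng.binomial(w, -np.expm1(-lam)))
    sensitive = int(rng.binomial(populated, float(_p_sensitive_arr(lam, q))))
    return LossExperiment(
        clone_id="sim", condition="synthetic", wells_total=w,
        populated_wells=populated, sensitive_wells=sensitive, nominal_lambda=lam,
    )


def _one_transfection_replicate(
    truth: SyntheticTruth, config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    plates = gen_transfection(truth, rng)
    est = estimate_efficiency(plates)
    ci = efficiency_ci(plates, config, rng)
    covered = ci.contains(truth.true_clones)
    return est.clones_hat, covered


def _one_loss_replicate(
    truth: SyntheticTruth, config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, bool]:
    exp = gen_loss_experiment(truth, rng)
    est = loss_ci(exp, config, rng)
    if exp.populated_wells == 0:
        return float("nan"), est.ci_lo <= truth.true_q <= est.ci_hi
    return est.q_hat, (not est.empty) and est.ci_lo <= truth.true_q <= est.ci_hi


def run_coverage_study(
    scenarios: list[SyntheticTruth],
    config: SimulationConfig,
    n_replicates: int = 500,
) -> pd.DataFrame:
    """Replicate each scenario, re-estimate, and tabulate bias/RMSE/coverage.

    Returns one row per scenario with the true parameter, mean estimate,
    relative bias, RMSE, and the fraction of ``config.ci_level`` intervals
    containing the truth.
    """
    rows = []
    for truth in scenarios:
        rng = np.random.default_rng(truth.seed)
        if n_replicates == 0:
            continue
        est, cov = [], []
        runner = (
            _one_transfection_replicate
            if truth.scenario == "transfection"
            else _one_loss_replicate
        )
        for _ in range(n_replicates):
            e, c = runner(truth, config, rng)
            est.append(e)
            cov.append(c)
        est = np.asarray(est, dtype=float)
        truth_val = (
            truth.true_clones if truth.scenario == "transfection" else truth.true_q
        )
        ok = np.isfinite(est)
        bias = float(np.mean(est[ok]) - truth_val) if ok.any() else float("nan")
        rows.append(
            {
                "scenario": truth.scenario,
                "truth": truth_val,
                "n_replicates": n_replicates,
                "mean_estimate": float(np.mean(est[ok])) if ok.any() else float("nan"),
                "bias": bias,
                "relative_bias": bias / truth_val if truth_val else float("nan"),
                "rmse": float(np.sqrt(np.mean((est[ok] - truth_val) ** 2)))
                if ok.any()
                else float("nan"),
                "coverage": float(np.mean(cov)),
                "ci_level": config.ci_level,
                "seed": truth.seed,
            }
        )
    return pd.DataFrame(rows)
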