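"""Readers and writers for plate tables, loss tables, configs and reports.

All formats are delimited text (TSV or CSV, sniffed from the header line) or
JSON/YAML; no binary formats. Validation failures name the offending row.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .loss import LossExperiment
from .plating import PlateObservation, SimulationConfig

__all__ = [
    "RunReport",
    "read_plate_table",
    "write_plate_table",
    "read_loss_table",
    "write_loss_table",
    "read_config",
    "estimate_doubling_time",
]

_PLATE_COLUMNS = ["plate_id", "condition", "wells_total", "wells_positive", "fraction_plated"]
_LOSS_COLUMNS = ["clone_id", "condition", "wells_total", "populated_wells", "sensitive_wells"]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_plate_table(path: str | Path) -> list[PlateObservation]:
    """Read a plate table (columns plate_id, condition, wells_total,
    wells_positive, fraction_plated); row-numbered validation errors."""
    df = _read_table(path, _PLATE_COLUMNS)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                PlateObservation(
                    plate_id=str(row["plate_id"]),
                    condition=str(row["condition"]),
                    wells_total=int(row["wells_total"]),
                    wells_positive=int(row["wells_positive"]),
                    fraction_plated=float(row["fraction_plated"]),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"row {i + 2} of {Path(path).name}: {err}") from err
    return out


def write_plate_table(plates: list[PlateObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plate_id": p.plate_id,
                "condition": p.condition,
                "wells_total": p.wells_total,
                "wells_positive": p.wells_positive,
                "fraction_plated": p.fraction_plated,
            }
            for p in plates
        ],
        columns=_PLATE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_loss_table(path: str | Path) -> list[LossExperiment]:
    """Read a replica-plating table (columns clone_id, condition, wells_total,
    populated_wells, sensitive_wells[, nominal_lambda])."""
    df = _read_table(path, _LOSS_COLUMNS)
    out = []
    for i, row in df.iterrows():
        lam = None
        if "nominal_lambda" in df.columns and not pd.isna(row["nominal_lambda"]):
            lam = float(row["nominal_lambda"])
        try:
            out.append(
                LossExperiment(
                    clone_id=str(row["clone_id"]),
                    condition=str(row["condition"]),
                    wells_total=int(row["wells_total"]),
                    populated_wells=int(row["populated_wells"]),
                    sensitive_wells=int(row["sensitive_wells"]),
                    nominal_lambda=lam,
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"row {i + 2} of {Path(path).name}: {err}") from err
    return out


def write_loss_table(experiments: list[LossExperiment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "clone_id": e.clone_id,
                "condition": e.condition,
                "wells_total": e.wells_total,
                "populated_wells": e.populated_wells,
                "sensitive_wells": e.sensitive_wells,
                "nominal_lambda": e.nominal_lambda,
            }
            for e in experiments
        ],
        columns=_LOSS_COLUMNS + ["nominal_lambda"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path, **overrides) -> SimulationConfig:
    """Load a SimulationConfig from YAML or JSON, with keyword overrides."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return SimulationConfig(**data)


@dataclass
class RunReport:
    """Machine-readable record of one analysis run.

    Echoes the configuration (including seed and simulation budget) so any
    run can be reproduced exactly, plus per-experiment estimates with their
    intervals and any warnings (saturated plates, one-sided intervals,
    empty acceptance sets).
    """

    command: str
    config: dict
    inputs: dict
    results: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonify))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.results).to_csv(path, sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {obj!r}")


def estimate_doubling_time(timepoints_h, densities) -> tuple[float, float]:
    """Doubling time (hours) and its SE from an exponential-growth series.

    Least-squares fit of log2(density) against time; doubling time is the
    reciprocal slope, with SE by the delta method (SE_slope / slope^2).
    """
    t = np.asarray(timepoints_h, dtype=float)
    d = np.asarray(densities, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(d <= 0):
        raise ValueError("densities must be positive")
    res = stats.linregress(t, np.log2(d))
    if res.slope <= 0:
        raise ValueError("series is not growing: cannot estimate doubling time")
    if res.slope * (t.max() - t.min()) < 1.0:
        import logging

        logging.getLogger(__name__).warning(
            "series spans less than one doubling; estimate will be unstable"
        )
    doubling = 1.0 / res.slope
    se = res.stderr / res.slope**2
    return float(doubling), float(se)
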