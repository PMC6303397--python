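"""Sequential gating of imaging-cytometry feature tables.

The senescent-cell identification proceeds through four declared stages on a
per-cell feature table: single cells (brightfield area and aspect ratio),
focused cells (contrast and gradient RMS), CD45-negative cells (excluding
immune cells), and finally SA-beta-Gal-positive / HMGB1-spot-negative cells.
The final senescent fraction is reported relative to the CD45-negative
focused singles.  Thresholds are always config-supplied — a helper can
suggest thresholds at the valley between intensity modes, but nothing is
applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataValidationError

RULES = ("ge", "le", "eq", "interval")

REQUIRED_STAGES = ("singles", "focus", "cd45_negative", "senescent")


@dataclass(frozen=True)
class Gate:
    """A single-feature rule: >= / <= / == a threshold, or within [low, high]."""

    feature: str
    rule: str
    threshold: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.rule not in RULES:
            raise ConfigurationError(f"rule: must be one of {RULES}, got {self.rule!r}")
        if self.rule == "interval":
            if self.low is None or self.high is None:
                raise ConfigurationError("interval gate requires 'low' and 'high'")
        elif self.threshold is None:
            raise ConfigurationError(f"'{self.rule}' gate requires 'threshold'")

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        if self.feature not in table.columns:
            raise DataValidationError(f"unknown feature '{self.feature}'")
        v = table[self.feature].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            raise DataValidationError(f"feature '{self.feature}' has missing values")
        if self.rule == "ge":
            return v >= self.threshold
        if self.rule == "le":
            return v <= self.threshold
        if self.rule == "eq":
            return v == self.threshold
        return (v >= self.low) & (v <= self.high)

    def to_dict(self) -> dict:
        d = {"feature": self.feature, "rule": self.rule}
        if self.rule == "interval":
            d.update(low=self.low, high=self.high)
        else:
            d["threshold"] = self.threshold
        return d


def apply_gate(table: pd.DataFrame, gate: Gate) -> tuple[pd.DataFrame, int]:
    """Rows satisfying the gate, with the surviving count."""
    mask = gate.mask(table)
    out = table[mask]
    return out, int(mask.sum())


@dataclass
class GateStage:
    name: str
    gates: list[Gate]

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(table), dtype=bool)
        for g in self.gates:
            m &= g.mask(table)
        return m


@dataclass
class GatingConfig:
    """Ordered gate stages, applied sequentially."""

    stages: list[GateStage]

    def validate_for_senescence(self) -> None:
        names = [s.name for s in self.stages]
        for required in REQUIRED_STAGES:
            if required not in names:
                raise ConfigurationError(f"gating config missing required stage '{required}'")

    @classmethod
    def from_dict(cls, data: dict) -> "GatingConfig":
        if "stages" not in data:
            raise ConfigurationError("gating config must have a 'stages' list")
        stages = []
        for s in data["stages"]:
            unknown = set(s) - {"name", "gates"}
            if unknown:
                raise ConfigurationError(f"unknown stage keys: {sorted(unknown)}")
            stages.append(GateStage(name=s["name"], gates=[Gate(**g) for g in s["gates"]]))
        return cls(stages=stages)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "gates": [g.to_dict() for g in s.gates]} for s in self.stages
            ]
        }

    @classmethod
    def from_yaml(cls, path) -> "GatingConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_gating_config() -> GatingConfig:
    """Stand-in gate boundaries matched to the synthetic cell simulator.

    These thresholds separate the simulator's default populations; they are
    synthetic placeholders, not measured instrument gates.
    """
    return GatingConfig(
        stages=[
            GateStage(
                "singles",
                [
                    Gate("bf_area", "interval", low=60.0, high=200.0),
                    Gate("bf_aspect_ratio", "ge", threshold=0.7),
                ],
            ),
            GateStage(
                "focus",
                [
                    Gate("contrast", "ge", threshold=25.0),
                    Gate("gradient_rms", "ge", threshold=35.0),
                ],
            ),
            GateStage("cd45_negative", [Gate("cd45_intensity", "le", threshold=400.0)]),
            GateStage(
                "senescent",
                [
                    Gate("sabgal_intensity", "ge", threshold=600.0),
                    Gate("hmgb1_spot_count", "le", threshold=0.0),
                ],
            ),
        ]
    )


@dataclass
class GatingResult:
    """Audit trail of a sequential gating run.

    ``stages`` rows carry (name, n_in, n_out, fraction_of_parent);
    ``senescent_fraction`` is the final count over the CD45-negative focused
    singles count.
    """

    stages: pd.DataFrame
    senescent_fraction: float
    n_input: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "senescent_fraction": self.senescent_fraction,
            "stages": self.stages.to_dict(orient="records"),
        }


def senescent_fraction(table: pd.DataFrame, config: GatingConfig) -> GatingResult:
    """Apply the gate sequence and report the senescent fraction.

    The fraction denominator is the population surviving the
    ``cd45_negative`` stage (single, focused, non-immune cells); the
    numerator is the population surviving the ``senescent`` stage.
    """
    config.validate_for_senescence()
    current = table
    rows = []
    counts: dict[str, int] = {}
    for stage in config.stages:
        n_in = len(current)
        current, n_out = apply_gate_stage(current, stage)
        counts[stage.name] = n_out
        rows.append(
            {
                "stage": stage.name,
                "n_in": n_in,
                "n_out": n_out,
                "fraction_of_parent": n_out / n_in if n_in else float("nan"),
            }
        )
    denom = counts["cd45_negative"]
    frac = counts["senescent"] / denom if denom else float("nan")
    return GatingResult(
        stages=pd.DataFrame(rows), senescent_fraction=float(frac), n_input=len(table)
    )


def apply_gate_stage(table: pd.DataFrame, stage: GateStage) -> tuple[pd.DataFrame, int]:
    mask = stage.mask(table)
    out = table[mask]
    return out, int(mask.sum())


def suggest_threshold(values, grid_size: int = 512) -> float:
    """Suggest a gate boundary at the deepest valley between the two main modes.

    A Gaussian KDE of the values is evaluated on a grid; the suggestion is the
    grid point of minimum density between the two highest local maxima.  The
    suggestion is advisory only and never applied automatically.
    """
    from scipy.stats import gaussian_kde

    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise DataValidationError("need >= 10 values to suggest a threshold")
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if maxima.size < 2:
        raise DataValidationError("could not find two modes in the distribution")
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])
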