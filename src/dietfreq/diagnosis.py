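"""Control-segment percentage-tolerance classifier.

Within each vertical band one radial segment acts as the *control*; every
other present segment in the band is compared to it, and any relative
deviation above the tolerance triggers a cancerous call. Because each breast
is compared only against itself, the criterion is self-normalising: scaling
every segment frequency by a constant leaves all deviations unchanged, so
population-level variation in breast stiffness does not bias the diagnostic.

Twelve control-segment configurations probe robustness to tumour location.
The shipped presets are: ids 1-4 hold a constant control quadrant across
bands; ids 5-8 spiral the control ascending (control = (b + z) mod 4); ids
9-12 spiral descending. They can be replaced verbatim from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import IndeterminateBreastError
from .segmentation import N_RADIAL, N_ZBANDS, SegmentTable

__all__ = [
    "Configuration",
    "Comparison",
    "DiagnosisOutcome",
    "preset_configurations",
    "load_configurations",
    "diagnose",
    "max_deviation",
    "combine_or",
    "OPTIMAL_TOLERANCES",
]

#: clinically optimal tolerances reported for the two headline configurations
OPTIMAL_TOLERANCES = {6: 0.34, 1: 0.33}


@dataclass(frozen=True)
class Configuration:
    """Mapping from each vertical band to its control radial segment."""

    id: int
    control_map: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.control_map) != N_ZBANDS:
            raise ValueError("control_map must cover all four z-bands")
        if any(not 0 <= c < N_RADIAL for c in self.control_map):
            raise ValueError(f"control indices must be in 0..3: {self.control_map}")
        object.__setattr__(self, "control_map", tuple(int(c) for c in self.control_map))


@dataclass(frozen=True)
class Comparison:
    zband: int
    radial: int
    control_radial: int
    deviation: float


@dataclass
class DiagnosisOutcome:
    breast_id: str
    configuration_id: int
    tolerance: float
    comparisons: list[Comparison]
    flagged: list[Comparison]
    indeterminate_zbands: list[int]
    is_positive: bool

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)


def preset_configurations() -> list[Configuration]:
    """The 12 shipped control-segment configurations (see module docstring)."""
    configs = []
    for b in range(4):
        configs.append(Configuration(b + 1, (b, b, b, b)))
    for b in range(4):
        configs.append(Configuration(b + 5, tuple((b + z) % 4 for z in range(4))))
    for b in range(4):
        configs.append(Configuration(b + 9, tuple((b - z) % 4 for z in range(4))))
    return configs


def load_configurations(path: str | Path) -> list[Configuration]:
    """Replace the presets verbatim with maps from a YAML file of the form
    ``{id: [c0, c1, c2, c3], ...}`` (z-band order, chest wall first)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: expected a non-empty mapping id -> 4 control indices")
    return [Configuration(int(k), tuple(v)) for k, v in sorted(raw.items())]


def _deviation(f_s: float, f_c: float, mode: str) -> float:
    if mode == "control":
        return abs(f_s - f_c) / f_c
    if mode == "symmetric":
        return abs(f_s - f_c) / ((f_s + f_c) / 2.0)
    raise ValueError(f"unknown deviation mode {mode!r}")


def diagnose(
    table: SegmentTable,
    config: Configuration,
    tolerance: float,
    deviation_mode: str = "control",
) -> DiagnosisOutcome:
    """Apply the percentage-tolerance criterion for one configuration.

    For each z-band whose control cell is present, every other present cell
    is compared to the control; a deviation above ``tolerance`` flags the
    segment, and any flag makes the breast positive. Bands with a missing
    control contribute no comparisons and are recorded as indeterminate;
    if all four controls are missing the breast is indeterminate (an error
    distinct from a negative call).
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    comparisons: list[Comparison] = []
    flagged: list[Comparison] = []
    indeterminate: list[int] = []
    for zb in range(N_ZBANDS):
        c = config.control_map[zb]
        f_c = table.mean_foi[c, zb]
        if not np.isfinite(f_c):
            indeterminate.append(zb)
            continue
        for r in range(N_RADIAL):
            if r == c:
                continue
            f_s = table.mean_foi[r, zb]
            if not np.isfinite(f_s):
                continue
            cmp_ = Comparison(zb, r, c, _deviation(float(f_s), float(f_c), deviation_mode))
            comparisons.append(cmp_)
            if cmp_.deviation > tolerance:
                flagged.append(cmp_)
    if len(indeterminate) == N_ZBANDS:
        raise IndeterminateBreastError(
            f"breast {table.breast_id}: every control segment of configuration "
            f"{config.id} is missing"
        )
    return DiagnosisOutcome(
        breast_id=table.breast_id,
        configuration_id=config.id,
        tolerance=tolerance,
        comparisons=comparisons,
        flagged=flagged,
        indeterminate_zbands=indeterminate,
        is_positive=len(flagged) > 0,
    )


def max_deviation(
    table: SegmentTable, config: Configuration, deviation_mode: str = "control"
) -> float:
    """Largest control-relative deviation over all comparisons (0.0 when no
    comparison is possible but at least one control is present). The breast
    is positive at tolerance t iff max_deviation > t, which is what the
    tolerance sweep and bootstrap exploit."""
    outcome = diagnose(table, config, tolerance=np.inf, deviation_mode=deviation_mode)
    if not outcome.comparisons:
        return 0.0
    return max(c.deviation for c in outcome.comparisons)


def combine_or(outcomes: Iterable[DiagnosisOutcome | bool | None]) -> bool:
    """OR-combination across configurations: positive iff any outcome is
    positive; indeterminate entries (None) are ignored unless everything is
    indeterminate."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("combine_or needs at least one outcome")
    calls = [
        o.is_positive if isinstance(o, DiagnosisOutcome) else o
        for o in outcomes
    ]
    defined = [c for c in calls if c is not None]
    if not defined:
        raise IndeterminateBreastError("all outcomes indeterminate")
    return any(defined)
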