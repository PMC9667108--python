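"""Pipeline configuration: every numeric constant of the method in one
serialisable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidSpecificationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Thresholds carry the method's constants: the 15% second-peak retention
    rule, the 5% boundary trim, the 2 Hz segment-irregularity rule with its
    10% per-run cap, and the usable 20-23 Hz actuation band. Bootstrap
    defaults are 50 draws x 200 trials. Cohort fields drive the synthetic
    phantom when the pipeline simulates its own input.
    """

    # method thresholds
    magnitude_threshold: float = 0.15
    trim_fraction: float = 0.05
    irregular_segment_hz: float = 2.0
    max_irregular_fraction: float = 0.10
    band_low_hz: float = 20.0
    band_high_hz: float = 23.0
    deviation_mode: str = "control"
    tolerance: float = 0.34  # preset for the optimal configuration
    tolerance_grid: list[float] = field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(21)]
    )
    configurations_file: str | None = None  # YAML override of the 12 presets

    # bootstrap
    n_draw: int = 50
    n_trials: int = 200

    # synthetic cohort
    n_healthy: int = 13
    n_cancerous: int = 13
    input_frequencies: list[float] = field(default_factory=lambda: [20.0, 21.0, 22.0, 23.0])
    n_points: int = 800
    sampling_rate: float = 250.0
    duration: float = 2.0
    noise_sd: float = 0.02
    diameter_range: tuple[float, float] = (7.0, 48.0)
    stiffness_range: tuple[float, float] = (4.0, 10.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.magnitude_threshold < 1:
            raise InvalidSpecificationError("magnitude_threshold must be in (0, 1)")
        if not 0 <= self.trim_fraction < 0.5:
            raise InvalidSpecificationError("trim_fraction must be in [0, 0.5)")
        if self.irregular_segment_hz <= 0 or not 0 < self.max_irregular_fraction <= 1:
            raise InvalidSpecificationError("irregularity thresholds out of range")
        if self.band_low_hz > self.band_high_hz:
            raise InvalidSpecificationError("usable band is empty (low > high)")
        if self.n_draw <= 0 or self.n_trials <= 0:
            raise InvalidSpecificationError("bootstrap sizes must be positive")
        self.input_frequencies = [float(f) for f in self.input_frequencies]
        self.tolerance_grid = [float(t) for t in self.tolerance_grid]
        self.diameter_range = tuple(float(v) for v in self.diameter_range)
        self.stiffness_range = tuple(float(v) for v in self.stiffness_range)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["diameter_range"] = list(self.diameter_range)
        data["stiffness_range"] = list(self.stiffness_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
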