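"""Synthetic surface-vibration phantom for DIET-style breast screening.

The Digital Image Elasto Tomography (DIET) system vibrates the free-hanging
breast sinusoidally and tracks ~14,000 surface reference points; each point
yields a 3-D displacement time series at one actuation frequency per run.
The clinical recordings are access-restricted, so this module generates
labelled synthetic cohorts with the statistical structure the diagnostic
assumes:

* a pendant half-ellipsoid surface point cloud per breast,
* per point, a steady-state *primary* tone at the actuation frequency plus a
  weaker *secondary* tone whose frequency over tumour-affected tissue is
  elevated by sqrt(k_tumor / k_healthy) — stiffer tissue vibrates at higher
  frequency (omega = sqrt(k/m)), and tumours are 4-10x stiffer than healthy
  tissue, so the elevation factor spans 2-3.16,
* amplitude noise, inflated near the chest wall and apex where the clinical
  reconstructions are least reliable.

Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecificationError

__all__ = [
    "MaterialSpec",
    "TumorSpec",
    "BreastSpec",
    "RecordingParams",
    "SurfaceMotionRecording",
    "surface_point_cloud",
    "tumor_weight",
    "synth_recording",
    "synth_cohort",
]

#: apex height over equatorial radius of the pendant half-ellipsoid
ASPECT_RATIO = 1.2

#: fraction of the z-range at each end treated as "boundary" (extra noise)
BOUNDARY_FRACTION = 0.05

#: peak amplitude (mm) of the primary tone at the apex
PRIMARY_AMPLITUDE_MM = 1.0

#: maximum off-axis component of a point's motion direction
DIRECTION_JITTER = 0.10

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class MaterialSpec:
    """Tissue/material parameters of the two-tone response model.

    stiffness_ratio
        k_tumor / k_healthy, dimensionless, >= 1. Clinically 4-10.
    healthy_secondary_ratio
        Secondary-to-input frequency ratio in healthy tissue (> 1).
    secondary_mag_fraction
        Secondary amplitude relative to the primary, in (0, 1]. The default
        0.3 sits comfortably above the 0.15 retention threshold of the
        frequency-of-interest rule; values below 0.15 emulate the
        "filtered-out" regime.
    heterogeneity_sd
        Standard deviation of a smooth multiplicative spatial jitter applied
        to the healthy secondary ratio (tissue is not homogeneous; without
        this, a tumour-free breast has bitwise-identical segment means and a
        null cohort is degenerate).
    """

    stiffness_ratio: float = 7.0
    healthy_secondary_ratio: float = 1.5
    secondary_mag_fraction: float = 0.3
    heterogeneity_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.stiffness_ratio < 1.0:
            raise InvalidSpecificationError(
                f"stiffness_ratio must be >= 1, got {self.stiffness_ratio}"
            )
        if self.healthy_secondary_ratio <= 1.0:
            raise InvalidSpecificationError(
                "healthy_secondary_ratio must be > 1, got "
                f"{self.healthy_secondary_ratio}"
            )
        if not 0.0 < self.secondary_mag_fraction <= 1.0:
            raise InvalidSpecificationError(
                "secondary_mag_fraction must be in (0, 1], got "
                f"{self.secondary_mag_fraction}"
            )
        if self.heterogeneity_sd < 0.0:
            raise InvalidSpecificationError("heterogeneity_sd must be >= 0")


@dataclass(frozen=True)
class TumorSpec:
    """Lesion placement in the clinical clock convention.

    clock_position: hours in [0, 12), 12 o'clock = superior; wraps mod 12.
    depth: mm below the apex along the apex-to-chest axis.
    diameter: mm; the surface footprint has full weight within diameter/2 of
    the projection centre and falls smoothly to zero at one diameter.
    """

    clock_position: float = 0.0
    depth: float = 30.0
    diameter: float = 20.0
    present: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "clock_position", float(self.clock_position) % 12.0)
        if self.present and self.diameter <= 0:
            raise InvalidSpecificationError(
                f"tumor diameter must be > 0 when present, got {self.diameter}"
            )


@dataclass(frozen=True)
class BreastSpec:
    breast_id: str
    side: Literal["left", "right"]
    volume: float = 500.0  # cm^3
    n_points: int = 1000
    label: Literal["healthy", "cancerous"] = "healthy"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidSpecificationError(f"side must be left/right, got {self.side}")
        if self.label not in ("healthy", "cancerous"):
            raise InvalidSpecificationError(f"unknown label {self.label}")
        if self.volume <= 0:
            raise InvalidSpecificationError(f"volume must be > 0, got {self.volume}")
        if self.n_points < 16:
            raise InvalidSpecificationError(
                f"n_points must be >= 16 (one per segment), got {self.n_points}"
            )


@dataclass(frozen=True)
class RecordingParams:
    """Acquisition parameters of one actuation run."""

    input_frequency: float = 23.0  # Hz
    sampling_rate: float = 250.0  # Hz
    duration: float = 2.0  # s
    noise_sd: float = 0.02  # mm, per displacement sample per axis
    boundary_noise_gain: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_frequency <= 0 or self.sampling_rate <= 0 or self.duration <= 0:
            raise InvalidSpecificationError("frequencies and duration must be > 0")
        if self.noise_sd < 0 or self.boundary_noise_gain < 1:
            raise InvalidSpecificationError(
                "noise_sd must be >= 0 and boundary_noise_gain >= 1"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class SurfaceMotionRecording:
    """One breast x one actuation frequency.

    points: (N, 3) rest positions in mm, z = 0 at the chest-wall rim and
    z = max at the apex. displacements: (N, T, 3) in mm.
    """

    breast_id: str
    side: str
    input_frequency: float
    sampling_rate: float
    point_ids: np.ndarray
    points: np.ndarray
    displacements: np.ndarray
    label: str = "healthy"

    def __post_init__(self) -> None:
        self.point_ids = np.asarray(self.point_ids)
        self.points = np.asarray(self.points, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if len(np.unique(self.point_ids)) != len(self.point_ids):
            raise InvalidSpecificationError("point ids must be unique")
        if self.points.shape != (len(self.point_ids), 3):
            raise InvalidSpecificationError("points must be (N, 3)")
        if self.displacements.shape[0] != len(self.point_ids) or (
            self.displacements.ndim != 3 or self.displacements.shape[2] != 3
        ):
            raise InvalidSpecificationError("displacements must be (N, T, 3)")

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    @property
    def n_samples(self) -> int:
        return self.displacements.shape[1]


def ellipsoid_radii(volume_cm3: float) -> tuple[float, float]:
    """Equatorial radius a and apex height c (mm) of the half-ellipsoid of
    revolution with the given enclosed volume; c = ASPECT_RATIO * a."""
    if volume_cm3 <= 0:
        raise InvalidSpecificationError(f"volume must be > 0, got {volume_cm3}")
    volume_mm3 = volume_cm3 * 1e3
    a = (3.0 * volume_mm3 / (2.0 * np.pi * ASPECT_RATIO)) ** (1.0 / 3.0)
    return a, ASPECT_RATIO * a


def surface_point_cloud(breast: BreastSpec, seed: int) -> np.ndarray:
    """Quasi-uniform sample of the pendant half-ellipsoid surface.

    Stratified-jittered in cos(theta) (uniform area on the reference
    hemisphere) with golden-angle azimuthal spacing; bit-identical under the
    same seed. Returns an (n_points, 3) array in mm.
    """
    a, c = ellipsoid_radii(breast.volume)
    n = breast.n_points
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    # one sample per cos(theta) stratum, jittered inside the stratum
    cos_t = (i + rng.uniform(0.05, 0.95, size=n)) / n
    cos_t = np.clip(cos_t, 0.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = i * _GOLDEN_ANGLE + rng.uniform(0.0, 2.0 * np.pi)
    pts = np.column_stack(
        [a * sin_t * np.cos(phi), a * sin_t * np.sin(phi), c * cos_t]
    )
    return pts


def _clock_direction(clock_position: float, side: str) -> tuple[float, float]:
    # 12 o'clock = +y (superior); hours run clockwise viewed facing the
    # patient's left breast; the right breast is mirrored through the
    # sagittal plane so 'outer'/'inner' stay anatomically consistent.
    ang = 2.0 * np.pi * (clock_position % 12.0) / 12.0
    dx = np.sin(ang)
    if side == "right":
        dx = -dx
    return dx, float(np.cos(ang))


def tumor_projection_centre(
    points: np.ndarray, tumor: TumorSpec, side: str = "left"
) -> np.ndarray:
    """Surface projection centre of a lesion: at its clock angle, at the
    height implied by its depth below the apex (clipped into the cloud)."""
    points = np.asarray(points, dtype=float)
    z = points[:, 2]
    c_est = float(z.max())
    rho = np.hypot(points[:, 0], points[:, 1])
    a_est = float(np.quantile(rho, 0.99))
    z_t = float(np.clip(c_est - tumor.depth, 0.1 * c_est, 0.9 * c_est))
    rho_t = a_est * np.sqrt(max(0.0, 1.0 - (z_t / c_est) ** 2))
    dx, dy = _clock_direction(tumor.clock_position, side)
    return np.array([rho_t * dx, rho_t * dy, z_t])


def tumor_weight(
    points: np.ndarray, tumor: TumorSpec | None, side: str = "left"
) -> np.ndarray:
    """Per-point lesion weight in [0, 1].

    The lesion's surface projection sits at its clock angle, at the height
    implied by its depth below the apex; weight is 1 within diameter/2 of the
    centre (3-D chord distance, monotone in the surface geodesic at lesion
    scale), falls as a raised cosine, and is 0 beyond one diameter. All zeros
    when no tumour is present.
    """
    points = np.asarray(points, dtype=float)
    if tumor is None or not tumor.present:
        return np.zeros(len(points))
    centre = tumor_projection_centre(points, tumor, side)
    d = np.linalg.norm(points - centre, axis=1)
    r = tumor.diameter / 2.0
    w = np.zeros(len(points))
    w[d <= r] = 1.0
    band = (d > r) & (d < 2.0 * r)
    w[band] = 0.5 * (1.0 + np.cos(np.pi * (d[band] - r) / r))
    return w


def _heterogeneity_field(points: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean multiplicative jitter over the surface, sd ~ `sd`.

    Low-order angular harmonics plus a linear height trend; smooth at segment
    scale so that segment means of a tumour-free breast differ by a few
    percent, as neighbouring regions of real tissue do.
    """
    coef = rng.standard_normal(5)
    if sd == 0.0:
        return np.zeros(len(points))
    theta = np.arctan2(points[:, 1], points[:, 0])
    zmax = points[:, 2].max()
    znorm = points[:, 2] / zmax if zmax > 0 else points[:, 2]
    g = (
        coef[0] * np.cos(theta)
        + coef[1] * np.sin(theta)
        + coef[2] * np.cos(2 * theta)
        + coef[3] * np.sin(2 * theta)
    ) / np.sqrt(2.0) + coef[4] * (znorm - 0.5)
    # normalise to unit-ish variance before scaling: 4 harmonics at power 1/2
    # (scaled by 1/2) plus the trend at power 1/12
    return sd * g / np.sqrt(4 * 0.5 / 2.0 + 1.0 / 12.0)


def check_nyquist(params: RecordingParams, material: MaterialSpec) -> None:
    """Raise unless the sampling rate resolves the highest synthesised tone
    and the run is long enough to separate the two tones by >= 2 bins."""
    f_max = (
        material.healthy_secondary_ratio
        * np.sqrt(material.stiffness_ratio)
        * params.input_frequency
    )
    if params.sampling_rate <= 2.0 * f_max:
        raise InvalidSpecificationError(
            f"sampling_rate {params.sampling_rate} Hz does not satisfy Nyquist "
            f"for the highest synthesised tone {f_max:.1f} Hz"
        )
    df = 1.0 / params.duration
    sep = (material.healthy_secondary_ratio - 1.0) * params.input_frequency
    if sep < 2.0 * df:
        raise InvalidSpecificationError(
            f"duration {params.duration}s cannot separate the primary and "
            f"secondary tones ({sep:.2f} Hz apart) by two spectral bins"
        )


def synth_recording(
    breast: BreastSpec,
    params: RecordingParams,
    material: MaterialSpec,
    tumor: TumorSpec | None = None,
    cloud_seed: int | None = None,
) -> SurfaceMotionRecording:
    """Synthesise one run for one breast.

    Per point p the displacement is a fixed near-axial unit direction times

        A(z) * [ sin(2 pi f_in t + ph1) + m * sin(2 pi r(p) f_in t + ph2) ]

    with r(p) = healthy_secondary_ratio * sqrt(1 + w(p) (stiffness_ratio - 1))
    (times the smooth heterogeneity jitter), m = secondary_mag_fraction, and
    A(z) tapering from the apex toward the chest wall. Gaussian noise of sd
    noise_sd is added per sample/axis, multiplied by boundary_noise_gain
    within the outer 5% z-ranges. `cloud_seed` pins the geometry and tissue
    field (shared across a breast's runs); `params.seed` drives the per-run
    phases and noise.
    """
    check_nyquist(params, material)
    cseed = params.seed if cloud_seed is None else cloud_seed
    points = surface_point_cloud(breast, cseed)
    rng_tissue = np.random.default_rng([int(cseed), 1])
    rng_run = np.random.default_rng([int(cseed), int(params.seed), 2])

    w = tumor_weight(points, tumor if breast.label == "cancerous" else None, breast.side)
    ratio = material.healthy_secondary_ratio * np.sqrt(
        1.0 + w * (material.stiffness_ratio - 1.0)
    )
    ratio = ratio * (1.0 + _heterogeneity_field(points, material.heterogeneity_sd, rng_tissue))
    f2 = ratio * params.input_frequency

    z = points[:, 2]
    zmax = z.max()
    amp = PRIMARY_AMPLITUDE_MM * (0.4 + 0.6 * z / zmax)

    jit = rng_tissue.uniform(-DIRECTION_JITTER, DIRECTION_JITTER, size=(len(points), 2))
    dirs = np.column_stack([jit, np.ones(len(points))])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    t = np.arange(params.n_samples) / params.sampling_rate
    ph = rng_run.uniform(0.0, 2.0 * np.pi, size=(len(points), 2))
    s = amp[:, None] * (
        np.sin(2.0 * np.pi * params.input_frequency * t[None, :] + ph[:, :1])
        + material.secondary_mag_fraction
        * np.sin(2.0 * np.pi * f2[:, None] * t[None, :] + ph[:, 1:])
    )
    disp = dirs[:, None, :] * s[:, :, None]

    if params.noise_sd > 0:
        sd = np.full(len(points), params.noise_sd)
        boundary = (z < BOUNDARY_FRACTION * zmax) | (z > (1 - BOUNDARY_FRACTION) * zmax)
        sd[boundary] *= params.boundary_noise_gain
        disp += rng_run.standard_normal(disp.shape) * sd[:, None, None]

    return SurfaceMotionRecording(
        breast_id=breast.breast_id,
        side=breast.side,
        input_frequency=params.input_frequency,
        sampling_rate=params.sampling_rate,
        point_ids=np.arange(len(points)),
        points=points,
        displacements=disp,
        label=breast.label,
    )


def synth_cohort(
    n_healthy: int,
    n_cancerous: int,
    input_frequencies: Sequence[float],
    *,
    seed: int = 0,
    n_points: int = 1000,
    volume_range: tuple[float, float] = (200.0, 1100.0),
    diameter_range: tuple[float, float] = (7.0, 48.0),
    depth_range: tuple[float, float] = (15.0, 45.0),
    stiffness_range: tuple[float, float] = (4.0, 10.0),
    heterogeneity_range: tuple[float, float] | None = (0.02, 0.20),
    tumor_clock_positions: Sequence[float] | None = None,
    material: MaterialSpec | None = None,
    params: RecordingParams | None = None,
) -> tuple[list[SurfaceMotionRecording], pd.DataFrame]:
    """Generate a labelled cohort: one recording per breast per frequency.

    Cancerous breasts carry exactly one tumour, with clock position uniform
    on [0, 12), diameter and depth uniform over the given ranges (defaults:
    the clinical 7-48 mm diameter span and mid-depth lesions) and stiffness
    ratio uniform over 4-10. Each breast additionally draws its own tissue
    heterogeneity scale uniformly from ``heterogeneity_range`` — breast
    properties vary far more across a population than within one breast,
    which is the very reason the diagnostic compares a breast only against
    itself; pass None to use ``material.heterogeneity_sd`` for everyone.
    ``tumor_clock_positions`` pins lesion clock angles (cycled over the
    cancerous breasts) for controlled-placement studies instead of the
    default uniform draw. Returns the recordings plus a manifest with one
    row per breast. Deterministic under `seed`.
    """
    if n_healthy < 0 or n_cancerous < 0:
        raise InvalidSpecificationError("cohort counts must be >= 0")
    if len(input_frequencies) == 0:
        raise InvalidSpecificationError("input_frequencies must be non-empty")
    material = material or MaterialSpec()
    params = params or RecordingParams()
    rng = np.random.default_rng(seed)

    recordings: list[SurfaceMotionRecording] = []
    rows = []
    labels = ["cancerous"] * n_cancerous + ["healthy"] * n_healthy
    n_cancer_seen = 0
    for k, label in enumerate(labels):
        bid = f"{'C' if label == 'cancerous' else 'H'}{(k if label == 'cancerous' else k - n_cancerous) + 1:02d}"
        side = "left" if rng.random() < 0.5 else "right"
        volume = float(rng.uniform(*volume_range))
        breast = BreastSpec(bid, side, volume=volume, n_points=n_points, label=label)
        tumor = None
        het = (
            float(rng.uniform(*heterogeneity_range))
            if heterogeneity_range is not None
            else material.heterogeneity_sd
        )
        if label == "cancerous":
            clock_draw = float(rng.uniform(0.0, 12.0))
            if tumor_clock_positions is not None:
                clock_draw = float(
                    tumor_clock_positions[n_cancer_seen % len(tumor_clock_positions)]
                )
            n_cancer_seen += 1
            tumor = TumorSpec(
                clock_position=clock_draw,
                depth=float(rng.uniform(*depth_range)),
                diameter=float(rng.uniform(*diameter_range)),
                present=True,
            )
            mat = replace(
                material,
                stiffness_ratio=float(rng.uniform(*stiffness_range)),
                heterogeneity_sd=het,
            )
        else:
            mat = replace(material, stiffness_ratio=1.0, heterogeneity_sd=het)
        cloud_seed = int(rng.integers(2**31))
        for f in input_frequencies:
            run_params = replace(
                params, input_frequency=float(f), seed=int(rng.integers(2**31))
            )
            recordings.append(
                synth_recording(breast, run_params, mat, tumor, cloud_seed=cloud_seed)
            )
        rows.append(
            {
                "breast_id": bid,
                "side": side,
                "label": label,
                "tumor_clock": tumor.clock_position if tumor else np.nan,
                "tumor_diameter_mm": tumor.diameter if tumor else np.nan,
                "tumor_depth_mm": tumor.depth if tumor else np.nan,
                "volume_cm3": volume,
                "stiffness_ratio": mat.stiffness_ratio if label == "cancerous" else 1.0,
            }
        )
    manifest = pd.DataFrame(rows)
    return recordings, manifest
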