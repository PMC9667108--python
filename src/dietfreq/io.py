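"""Recording bundles on disk.

A bundle is one directory per breast-run:

* ``metadata.yaml`` — breast_id, side, label, input_frequency_hz,
  sampling_rate_hz, n_points, n_samples
* ``points.csv`` — point_id, x_mm, y_mm, z_mm
* ``displacements.csv`` — point_id, t_index, dx_mm, dy_mm, dz_mm (long form)

Cohort manifests are plain CSV. All columns and units are documented in
docs/formats.md.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import BundleFormatError
from .phantom import SurfaceMotionRecording

__all__ = ["write_recording_bundle", "read_recording_bundle"]

_META_KEYS = (
    "breast_id",
    "side",
    "label",
    "input_frequency_hz",
    "sampling_rate_hz",
    "n_points",
    "n_samples",
)


def write_recording_bundle(recording: SurfaceMotionRecording, path: str | Path) -> Path:
    """Write one recording as a bundle directory; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "breast_id": recording.breast_id,
        "side": recording.side,
        "label": recording.label,
        "input_frequency_hz": float(recording.input_frequency),
        "sampling_rate_hz": float(recording.sampling_rate),
        "n_points": int(recording.n_points),
        "n_samples": int(recording.n_samples),
    }
    (path / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    pd.DataFrame(
        {
            "point_id": recording.point_ids,
            "x_mm": recording.points[:, 0],
            "y_mm": recording.points[:, 1],
            "z_mm": recording.points[:, 2],
        }
    ).to_csv(path / "points.csv", index=False)
    n, t = recording.n_points, recording.n_samples
    flat = recording.displacements.reshape(n * t, 3)
    pd.DataFrame(
        {
            "point_id": np.repeat(recording.point_ids, t),
            "t_index": np.tile(np.arange(t), n),
            "dx_mm": flat[:, 0],
            "dy_mm": flat[:, 1],
            "dz_mm": flat[:, 2],
        }
    ).to_csv(path / "displacements.csv", index=False)
    return path


def read_recording_bundle(path: str | Path) -> SurfaceMotionRecording:
    """Read and validate a bundle; inconsistencies are hard errors that name
    the offending points/keys."""
    path = Path(path)
    meta_path = path / "metadata.yaml"
    if not meta_path.exists():
        raise BundleFormatError(f"{path}: missing metadata.yaml")
    meta = yaml.safe_load(meta_path.read_text()) or {}
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise BundleFormatError(f"{path}: metadata missing keys {missing}")
    if not isinstance(meta["sampling_rate_hz"], (int, float)) or meta["sampling_rate_hz"] <= 0:
        raise BundleFormatError(
            f"{path}: sampling_rate_hz must be a positive number, got "
            f"{meta['sampling_rate_hz']!r}"
        )
    if not isinstance(meta["input_frequency_hz"], (int, float)) or meta["input_frequency_hz"] <= 0:
        raise BundleFormatError(f"{path}: input_frequency_hz must be positive")

    try:
        points = pd.read_csv(path / "points.csv")
        disp = pd.read_csv(path / "displacements.csv")
    except FileNotFoundError as exc:
        raise BundleFormatError(f"{path}: {exc}") from exc
    for col in ("point_id", "x_mm", "y_mm", "z_mm"):
        if col not in points.columns:
            raise BundleFormatError(f"{path}: points.csv missing column {col}")
    for col in ("point_id", "t_index", "dx_mm", "dy_mm", "dz_mm"):
        if col not in disp.columns:
            raise BundleFormatError(f"{path}: displacements.csv missing column {col}")
    if not all(
        np.issubdtype(points[c].dtype, np.number) for c in ("x_mm", "y_mm", "z_mm")
    ) or not all(
        np.issubdtype(disp[c].dtype, np.number) for c in ("dx_mm", "dy_mm", "dz_mm")
    ):
        raise BundleFormatError(f"{path}: non-numeric cells in coordinate columns")

    pids = points["point_id"].to_numpy()
    if len(np.unique(pids)) != len(pids):
        raise BundleFormatError(f"{path}: duplicate point ids in points.csv")
    if int(meta["n_points"]) != len(pids):
        raise BundleFormatError(
            f"{path}: metadata n_points={meta['n_points']} but points.csv has {len(pids)}"
        )

    counts = disp.groupby("point_id").size()
    missing_pts = sorted(set(pids) - set(counts.index))
    extra_pts = sorted(set(counts.index) - set(pids))
    if missing_pts or extra_pts:
        raise BundleFormatError(
            f"{path}: displacement/point id mismatch; missing displacements for "
            f"{missing_pts[:10]}, unknown ids {extra_pts[:10]}"
        )
    n_samples = int(meta["n_samples"])
    ragged = counts[counts != n_samples]
    if len(ragged):
        raise BundleFormatError(
            f"{path}: ragged time series (expected {n_samples} samples) for point ids "
            f"{list(ragged.index[:10])}"
        )

    disp = disp.sort_values(["point_id", "t_index"], kind="stable")
    order = np.argsort(pids, kind="stable")
    pts_sorted = points.iloc[order]
    arr = disp[["dx_mm", "dy_mm", "dz_mm"]].to_numpy().reshape(len(pids), n_samples, 3)
    return SurfaceMotionRecording(
        breast_id=str(meta["breast_id"]),
        side=str(meta["side"]),
        input_frequency=float(meta["input_frequency_hz"]),
        sampling_rate=float(meta["sampling_rate_hz"]),
        point_ids=pts_sorted["point_id"].to_numpy(),
        points=pts_sorted[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        displacements=arr,
        label=str(meta["label"]),
    )
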