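"""Surface segmentation: boundary trimming, the 4 radial x 4 vertical grid,
and per-segment reduction of frequencies of interest.

Radial quadrants are taken about the z-axis through the cloud centroid with
boundaries at the half-hour clock positions (1:30 / 4:30 / 7:30 / 10:30), so
the four quadrants are centred on 12, 3, 6 and 9 o'clock:

* radial 0 — superior-centred (12:00),
* radial 1 — outer / lateral (3:00 on the left breast),
* radial 2 — inferior-centred (6:00),
* radial 3 — inner / medial (9:00 on the left breast).

Right-breast clock angles are mirrored through the sagittal plane so
outer/inner indices are anatomically consistent, which is what lets one
control-segment configuration be applied to both sides. Vertical z-bands are
equal-count quartiles of the retained heights (band 0 nearest the chest
wall) — robust to the strongly non-uniform point density of a pendant shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "SegmentId",
    "SegmentTable",
    "trim_by_height",
    "assign_segments",
    "segment_table",
    "average_tables",
    "TRIM_FRACTION",
    "N_RADIAL",
    "N_ZBANDS",
]

TRIM_FRACTION = 0.05
N_RADIAL = 4
N_ZBANDS = 4


@dataclass(frozen=True)
class SegmentId:
    radial: int
    zband: int

    def __post_init__(self) -> None:
        if not (0 <= self.radial < N_RADIAL and 0 <= self.zband < N_ZBANDS):
            raise ValueError(f"segment indices out of range: {self}")


@dataclass
class SegmentTable:
    """4x4 grid of segment mean frequencies of interest.

    ``mean_foi[radial, zband]`` in Hz, NaN where the segment holds no
    retained point; ``counts`` are the contributing point counts
    (count 0 <=> missing).
    """

    breast_id: str
    mean_foi: np.ndarray
    counts: np.ndarray
    runs_used: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean_foi = np.asarray(self.mean_foi, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.mean_foi.shape != (N_RADIAL, N_ZBANDS) or self.counts.shape != (N_RADIAL, N_ZBANDS):
            raise ValueError("SegmentTable grids must be 4x4")
        missing = self.counts == 0
        if np.any(np.isnan(self.mean_foi) != missing):
            raise ValueError("missing cells must coincide with zero counts")

    @property
    def n_missing(self) -> int:
        return int((self.counts == 0).sum())


def trim_by_height(points: np.ndarray, fraction: float = TRIM_FRACTION) -> np.ndarray:
    """Indices of points retained after removing the lowest and highest
    ``fraction`` of points by z (nearest-rank: floor(fraction * N) points are
    dropped at each end; ties broken by input order)."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    points = np.asarray(points, dtype=float)
    z = points[:, 2] if points.ndim == 2 else points
    n = len(z)
    k = int(np.floor(fraction * n))
    if k == 0:
        return np.arange(n)
    order = np.argsort(z, kind="stable")
    return np.sort(order[k : n - k])


def assign_segments(points: np.ndarray, side: str) -> np.ndarray:
    """Assign each (retained) point a (radial, zband) pair.

    Returns an (N, 2) int array; raises DegenerateGeometryError when fewer
    than four distinct z values are present.
    """
    points = np.asarray(points, dtype=float)
    if side not in ("left", "right"):
        raise ValueError(f"side must be left/right, got {side}")
    z = points[:, 2]
    if len(np.unique(z)) < N_ZBANDS:
        raise DegenerateGeometryError(
            f"need >= {N_ZBANDS} distinct z values, got {len(np.unique(z))}"
        )
    dx = points[:, 0] - points[:, 0].mean()
    dy = points[:, 1] - points[:, 1].mean()
    if side == "right":
        dx = -dx
    # clock hours: 12:00 = +y, running clockwise (left-breast convention)
    hours = (np.arctan2(dx, dy) % (2.0 * np.pi)) / (2.0 * np.pi) * 12.0
    radial = (((hours + 1.5) % 12.0) // 3.0).astype(int) % N_RADIAL

    ranks = np.empty(len(z), dtype=int)
    ranks[np.argsort(z, kind="stable")] = np.arange(len(z))
    zband = np.minimum(N_ZBANDS - 1, ranks * N_ZBANDS // len(z))
    return np.column_stack([radial, zband])


def segment_table(
    breast_id: str,
    values: np.ndarray,
    assignments: np.ndarray,
    runs_used: Sequence[float] = (),
) -> SegmentTable:
    """Reduce per-point values (NaN = excluded point) to segment means.

    Segments where every point was excluded are missing (count 0).
    """
    values = np.asarray(values, dtype=float)
    assignments = np.asarray(assignments, dtype=int)
    if len(values) != len(assignments):
        raise ValueError("values and assignments must align")
    mean = np.full((N_RADIAL, N_ZBANDS), np.nan)
    counts = np.zeros((N_RADIAL, N_ZBANDS), dtype=int)
    for r in range(N_RADIAL):
        for zb in range(N_ZBANDS):
            sel = (assignments[:, 0] == r) & (assignments[:, 1] == zb)
            vals = values[sel]
            vals = vals[np.isfinite(vals)]
            counts[r, zb] = len(vals)
            if len(vals):
                mean[r, zb] = vals.mean()
    return SegmentTable(breast_id, mean, counts, list(runs_used))


def average_tables(tables: Sequence[SegmentTable]) -> SegmentTable:
    """Cell-wise unweighted mean over runs; a cell is missing only when it is
    missing in every run. Counts accumulate across runs."""
    if len(tables) == 0:
        raise ValueError("average_tables needs at least one run table")
    stack = np.stack([t.mean_foi for t in tables])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    counts = np.stack([t.counts for t in tables]).sum(axis=0)
    # a cell present in some run but with zero accumulated count cannot occur;
    # enforce the count/missing invariant explicitly
    counts[np.isnan(mean)] = 0
    runs = []
    for t in tables:
        runs.extend(t.runs_used)
    return SegmentTable(tables[0].breast_id, mean, counts, runs)
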