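"""Per-point spectral analysis: from displacement trajectories to the
"frequency of interest" (FoI).

The diagnostic frequency of a reference point is selected from its one-sided
magnitude spectrum:

* if the dominant peak differs from the actuation frequency, the point is
  vibrating irregularly and the dominant frequency itself is kept
  (branch ``irregular_dominant``);
* otherwise the second-dominant peak is kept, provided its magnitude is at
  least 15% of the dominant's (branch ``second_dominant``);
* otherwise the point is discarded.

Runs are then screened at segment level: a segment is *irregular* when its
mean dominant frequency differs from the actuation frequency by more than
2 Hz, and a run is usable only if fewer than 10% of its segments are
irregular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoUsableRunsError
from .phantom import SurfaceMotionRecording

__all__ = [
    "PointSpectrum",
    "Peak",
    "FoIResult",
    "project_scalar",
    "compute_spectrum",
    "rank_peaks",
    "frequency_of_interest",
    "extract_foi",
    "select_usable_runs",
    "MAGNITUDE_THRESHOLD",
    "IRREGULAR_SEGMENT_HZ",
    "MAX_IRREGULAR_FRACTION",
]

#: second peak retained only if its magnitude is >= this fraction of the dominant's
MAGNITUDE_THRESHOLD = 0.15

#: a segment's mean dominant frequency may differ from the input by at most this (Hz)
IRREGULAR_SEGMENT_HZ = 2.0

#: a run is usable when its irregular-segment fraction is below this
MAX_IRREGULAR_FRACTION = 0.10

_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class PointSpectrum:
    """One-sided magnitude spectrum with the DC (and Nyquist) bins removed."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    point_id: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequencies and magnitudes must be 1-D, same length")
        if len(f) and (f[0] <= 0 or np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be strictly increasing and positive")
        if not np.all(np.isfinite(m)):
            raise ValueError("magnitudes must be finite")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", m)

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0]) if len(self.frequencies) > 1 else np.nan


@dataclass(frozen=True)
class Peak:
    frequency: float
    magnitude: float
    index: int


@dataclass(frozen=True)
class FoIResult:
    """Outcome of the selection flowchart for one reference point."""

    point_id: int | None
    status: str  # 'retained' | 'excluded'
    branch: str | None  # 'irregular_dominant' | 'second_dominant' | None
    frequency_of_interest: float | None
    dominant_frequency: float | None
    dominant_magnitude: float | None
    second_frequency: float | None = None
    second_magnitude: float | None = None
    degenerate: bool = False


def project_scalar(trajectory: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project a mean-removed 3-D trajectory onto its first principal axis.

    Returns (zero-mean scalar series, degenerate flag); a constant trajectory
    yields the zero series flagged degenerate. The axis sign is fixed so that
    its largest-magnitude component is positive (determinism).
    """
    x = np.asarray(trajectory, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 8:
        raise ValueError("trajectory must be (T >= 8, 3)")
    x = x - x.mean(axis=0)
    scale = np.abs(x).max()
    if scale <= 0 or not np.isfinite(scale):
        return np.zeros(x.shape[0]), True
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
    series = x @ v
    if series.std() <= _DEGENERATE_RTOL * scale:
        return np.zeros(x.shape[0]), True
    return series - series.mean(), False


def compute_spectrum(series: np.ndarray, sampling_rate: float, point_id: int | None = None) -> PointSpectrum:
    """One-sided amplitude spectrum of a scalar series, DC and Nyquist bins
    removed; frequency resolution = sampling_rate / len(series)."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 8:
        raise ValueError("series must be 1-D with >= 8 samples")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    n = len(s)
    mags = np.abs(np.fft.rfft(s)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    # drop DC; drop the Nyquist bin when n is even
    hi = len(freqs) - 1 if n % 2 == 0 else len(freqs)
    return PointSpectrum(freqs[1:hi], mags[1:hi], point_id=point_id)


def _local_maxima(m: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right local maxima (ties resolved
    to the leftmost bin of a plateau); endpoints count against their single
    neighbour. A flat array has none."""
    n = len(m)
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([], dtype=int)
    keep = np.zeros(n, dtype=bool)
    keep[0] = m[0] > m[1]
    keep[-1] = m[-1] > m[-2]
    if n > 2:
        keep[1:-1] = (m[1:-1] > m[:-2]) & (m[1:-1] >= m[2:])
    return np.flatnonzero(keep)


def rank_peaks(
    spectrum: PointSpectrum,
    exclusion_halfwidth: int = 2,
    max_peaks: int | None = None,
) -> list[Peak]:
    """Local maxima in descending magnitude order, ties broken toward lower
    frequency; once a peak is selected, bins within ``exclusion_halfwidth``
    of it become ineligible (so spectral leakage around a peak is not
    mistaken for a separate peak). Empty for a flat spectrum."""
    m = spectrum.magnitudes
    cand = _local_maxima(m)
    if len(cand) == 0:
        return []
    order = np.lexsort((spectrum.frequencies[cand], -m[cand]))
    taken: list[int] = []
    peaks: list[Peak] = []
    for idx in cand[order]:
        if any(abs(idx - j) <= exclusion_halfwidth for j in taken):
            continue
        taken.append(int(idx))
        peaks.append(Peak(float(spectrum.frequencies[idx]), float(m[idx]), int(idx)))
        if max_peaks is not None and len(peaks) >= max_peaks:
            break
    return peaks


def frequency_of_interest(
    peaks: Sequence[Peak],
    input_frequency: float,
    magnitude_threshold: float = MAGNITUDE_THRESHOLD,
    match_tolerance: float = 0.5,
    point_id: int | None = None,
) -> FoIResult:
    """Apply the selection flowchart to a ranked peak list.

    ``match_tolerance`` quantifies "dominant equivalent to the input
    frequency"; callers should use max(0.5 Hz, one spectral bin).
    """
    if len(peaks) == 0:
        return FoIResult(point_id, "excluded", None, None, None, None, degenerate=True)
    dom = peaks[0]
    if abs(dom.frequency - input_frequency) > match_tolerance:
        return FoIResult(
            point_id,
            "retained",
            "irregular_dominant",
            dom.frequency,
            dom.frequency,
            dom.magnitude,
        )
    if len(peaks) >= 2:
        sec = peaks[1]
        if sec.magnitude >= magnitude_threshold * dom.magnitude:
            return FoIResult(
                point_id,
                "retained",
                "second_dominant",
                sec.frequency,
                dom.frequency,
                dom.magnitude,
                sec.frequency,
                sec.magnitude,
            )
        return FoIResult(
            point_id,
            "excluded",
            None,
            None,
            dom.frequency,
            dom.magnitude,
            sec.frequency,
            sec.magnitude,
        )
    return FoIResult(point_id, "excluded", None, None, dom.frequency, dom.magnitude)


def extract_foi(
    recording: SurfaceMotionRecording,
    magnitude_threshold: float = MAGNITUDE_THRESHOLD,
    match_tolerance: float | None = None,
    exclusion_halfwidth: int = 2,
) -> pd.DataFrame:
    """Frequency of interest for every reference point of one recording.

    Returns a DataFrame with one row per point: point_id, status, branch,
    foi_hz, dominant_hz, dominant_mag, second_hz, second_mag, degenerate.
    """
    n = recording.n_samples
    fs = recording.sampling_rate
    df_hz = fs / n
    if match_tolerance is None:
        match_tolerance = max(0.5, df_hz)

    disp = recording.displacements
    x = disp - disp.mean(axis=1, keepdims=True)
    cov = np.einsum("pti,ptj->pij", x, x)
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, :, -1]
    sign = np.sign(np.take_along_axis(v, np.argmax(np.abs(v), axis=1)[:, None], 1)[:, 0])
    sign[sign == 0] = 1.0
    v = v * sign[:, None]
    series = np.einsum("pti,pi->pt", x, v)

    scale = np.abs(x).max(axis=(1, 2))
    degenerate = (scale <= 0) | (series.std(axis=1) <= _DEGENERATE_RTOL * np.maximum(scale, 1e-300))

    mags = np.abs(np.fft.rfft(series, axis=1)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    hi = len(freqs) - 1 if n % 2 == 0 else len(freqs)
    freqs = freqs[1:hi]
    mags = mags[:, 1:hi]

    rows = []
    for p in range(recording.n_points):
        pid = int(recording.point_ids[p])
        if degenerate[p]:
            res = FoIResult(pid, "excluded", None, None, None, None, degenerate=True)
        else:
            spec = PointSpectrum(freqs, mags[p], point_id=pid)
            peaks = rank_peaks(spec, exclusion_halfwidth, max_peaks=2)
            res = frequency_of_interest(
                peaks,
                recording.input_frequency,
                magnitude_threshold,
                match_tolerance,
                point_id=pid,
            )
        rows.append(
            (
                res.point_id,
                res.status,
                res.branch,
                res.frequency_of_interest,
                res.dominant_frequency,
                res.dominant_magnitude,
                res.second_frequency,
                res.second_magnitude,
                res.degenerate,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "point_id",
            "status",
            "branch",
            "foi_hz",
            "dominant_hz",
            "dominant_mag",
            "second_hz",
            "second_mag",
            "degenerate",
        ],
    )


def select_usable_runs(
    segment_dominant_means: Mapping[float, np.ndarray],
    max_segment_diff_hz: float = IRREGULAR_SEGMENT_HZ,
    max_irregular_fraction: float = MAX_IRREGULAR_FRACTION,
) -> tuple[list[float], dict[float, float]]:
    """Screen runs by their segment-level dominant-frequency regularity.

    ``segment_dominant_means`` maps input frequency (Hz) -> array of segment
    mean dominant frequencies (NaN for empty segments). A segment is
    irregular when its mean differs from the input frequency by more than
    ``max_segment_diff_hz``; a run is retained when its irregular fraction
    (over non-empty segments) is strictly below ``max_irregular_fraction``.

    Returns (retained input frequencies, per-run irregular fractions);
    raises NoUsableRunsError when nothing survives.
    """
    fractions: dict[float, float] = {}
    retained: list[float] = []
    for f_in, means in segment_dominant_means.items():
        means = np.asarray(means, dtype=float).ravel()
        ok = np.isfinite(means)
        if not ok.any():
            fractions[f_in] = 1.0
            continue
        frac = float(np.mean(np.abs(means[ok] - f_in) > max_segment_diff_hz))
        fractions[f_in] = frac
        if frac < max_irregular_fraction:
            retained.append(f_in)
    if not retained:
        raise NoUsableRunsError(
            "no usable runs: irregular-segment fractions were "
            + ", ".join(f"{f} Hz -> {fr:.0%}" for f, fr in sorted(fractions.items())),
            fractions,
        )
    return sorted(retained), fractions
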