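"""ROC evaluation: tolerance sweep, bootstrap resampling, total-least-squares
fit of the one-parameter curve y = 1 - exp(-a x), analytic AUC, operating
points, and the diagnostic criteria report.

The one-parameter family spans everything from a nearly useless classifier
to the perfect square ROC as a grows, with the fixed closed-form area

    AUC(a) = 1 - (1 - e^(-a)) / a.

Bootstrapping (50 breasts drawn with replacement, 200 trials) up-samples the
small cohort; the pooled (FPR, TPR) points of every trial and tolerance are
summarised by the curve minimising the summed squared *orthogonal* distances
(total least squares), which treats sensitivity and specificity errors
symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .diagnosis import Configuration, max_deviation
from .errors import FitError, IndeterminateBreastError
from .segmentation import SegmentTable

__all__ = [
    "ConfusionResult",
    "ROCPoint",
    "BootstrapFit",
    "OperatingPoints",
    "CriteriaReport",
    "confusion",
    "tolerance_sweep",
    "bootstrap_points",
    "fit_exponential_roc",
    "auc_from_a",
    "a_from_auc",
    "operating_points",
    "criteria_report",
    "default_tolerance_grid",
    "N_BOOTSTRAP_DRAW",
    "N_BOOTSTRAP_TRIALS",
    "AUC_CRITERION",
]

N_BOOTSTRAP_DRAW = 50
N_BOOTSTRAP_TRIALS = 200
AUC_CRITERION = 0.73  # mammography-average AUC the method must beat
A_MAX = 50.0


def default_tolerance_grid() -> np.ndarray:
    """Percentage tolerances 0, 0.05, ..., 1.0."""
    return np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass(frozen=True)
class ConfusionResult:
    sensitivity: float | None
    specificity: float | None
    tp: int
    fn: int
    tn: int
    fp: int
    n_indeterminate: int


@dataclass(frozen=True)
class ROCPoint:
    false_positive_rate: float
    true_positive_rate: float
    tolerance: float
    trial: int | None = None


@dataclass(frozen=True)
class BootstrapFit:
    """Fitted curve parameter and its analytic area."""

    a: float
    auc: float
    n_points: int
    configuration_id: int | None = None


@dataclass(frozen=True)
class OperatingPoints:
    """Operating points on the fitted curve, as (sensitivity, specificity)
    fractions: the point closest to the ideal corner (0, 1), the point at 80%
    specificity, and the point at 80% sensitivity."""

    optimal_fpr: float
    optimal_tpr: float
    sensitivity_at_spec80: float
    specificity_at_sens80: float

    @property
    def optimal_sensitivity_pct(self) -> int:
        return int(round(100.0 * self.optimal_tpr))

    @property
    def optimal_specificity_pct(self) -> int:
        return int(round(100.0 * (1.0 - self.optimal_fpr)))

    @property
    def sensitivity_at_spec80_pct(self) -> int:
        return int(round(100.0 * self.sensitivity_at_spec80))

    @property
    def specificity_at_sens80_pct(self) -> int:
        return int(round(100.0 * self.specificity_at_sens80))


@dataclass(frozen=True)
class CriteriaReport:
    """Assessment against the published diagnostic criteria."""

    auc: float
    auc_ok: bool  # AUC > 0.73 (strict)
    criterion1_sensitivity_at_spec80: float  # %, pass when >= 60
    criterion1_pass: bool
    criterion2_specificity_at_sens80: float  # %, pass when >= 65
    criterion2_pass: bool
    optimal_sensitivity: float  # %
    optimal_specificity: float  # %


def confusion(
    calls: Mapping[str, bool | None], labels: Mapping[str, str]
) -> ConfusionResult:
    """Sensitivity/specificity of per-breast calls against labels.

    ``None`` calls (indeterminate breasts) are excluded from both rates and
    counted separately. A rate whose class is absent is None.
    """
    tp = fn = tn = fp = ind = 0
    for bid, call in calls.items():
        label = labels[bid]
        if call is None:
            ind += 1
            continue
        if label == "cancerous":
            tp += call
            fn += not call
        else:
            fp += call
            tn += not call
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return ConfusionResult(sens, spec, tp, fn, tn, fp, ind)


def _cohort_deviations(
    tables: Sequence[SegmentTable], config: Configuration, deviation_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """(max deviation, determinate mask) per breast; indeterminate breasts
    get NaN."""
    devs = np.full(len(tables), np.nan)
    for i, t in enumerate(tables):
        try:
            devs[i] = max_deviation(t, config, deviation_mode)
        except IndeterminateBreastError:
            pass
    return devs, np.isfinite(devs)


def _rates(
    devs: np.ndarray, is_cancer: np.ndarray, ok: np.ndarray, tol: float
) -> tuple[float, float]:
    pos = devs > tol
    nc = (is_cancer & ok).sum()
    nh = (~is_cancer & ok).sum()
    tpr = float(pos[is_cancer & ok].sum() / nc) if nc else np.nan
    fpr = float(pos[~is_cancer & ok].sum() / nh) if nh else np.nan
    return fpr, tpr


def tolerance_sweep(
    tables: Sequence[SegmentTable],
    labels: Mapping[str, str],
    config: Configuration,
    grid: Sequence[float] | None = None,
    deviation_mode: str = "control",
) -> pd.DataFrame:
    """Discrete ROC: one (FPR, TPR) per tolerance in the ascending grid.

    Both rates are non-increasing in the tolerance (a breast positive at t
    is positive at every t' < t).
    """
    grid = default_tolerance_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("tolerance grid must be non-empty and ascending")
    devs, ok = _cohort_deviations(tables, config, deviation_mode)
    is_cancer = np.array([labels[t.breast_id] == "cancerous" for t in tables])
    rows = [(float(t),) + _rates(devs, is_cancer, ok, float(t)) for t in grid]
    return pd.DataFrame(rows, columns=["tolerance", "fpr", "tpr"])


def bootstrap_points(
    tables: Sequence[SegmentTable],
    labels: Mapping[str, str],
    config: Configuration,
    n_draw: int = N_BOOTSTRAP_DRAW,
    n_trials: int = N_BOOTSTRAP_TRIALS,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    deviation_mode: str = "control",
) -> pd.DataFrame:
    """Pooled ROC points over bootstrap resamples of the cohort.

    Each trial draws ``n_draw`` breasts with replacement and records the
    tolerance sweep; trials whose resample lacks a class contribute only
    their defined rate(s) (the undefined one is NaN and is dropped by the
    fit). Deterministic under ``seed``.
    """
    if len(tables) == 0:
        raise ValueError("cohort is empty")
    grid = default_tolerance_grid() if grid is None else np.asarray(grid, dtype=float)
    devs, ok = _cohort_deviations(tables, config, deviation_mode)
    is_cancer = np.array([labels[t.breast_id] == "cancerous" for t in tables])
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        idx = rng.integers(0, len(tables), size=n_draw)
        d, c, o = devs[idx], is_cancer[idx], ok[idx]
        for t in grid:
            fpr, tpr = _rates(d, c, o, float(t))
            rows.append((trial, float(t), fpr, tpr))
    return pd.DataFrame(rows, columns=["trial", "tolerance", "fpr", "tpr"])


def _curve(x: np.ndarray, a: float) -> np.ndarray:
    return -np.expm1(-a * x)


def _orthogonal_sq_distances(x0: np.ndarray, y0: np.ndarray, a: float, tol: float = 1e-10) -> np.ndarray:
    """Squared orthogonal distance from each point to y = 1 - e^(-a x),
    x in [0, 1]: dense-grid presolve then vectorised golden-section refine."""
    xg = np.linspace(0.0, 1.0, 257)
    d2 = (xg[None, :] - x0[:, None]) ** 2 + (_curve(xg, a)[None, :] - y0[:, None]) ** 2
    best = np.argmin(d2, axis=1)
    h = xg[1] - xg[0]
    lo = np.clip(xg[best] - h, 0.0, 1.0)
    hi = np.clip(xg[best] + h, 0.0, 1.0)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0

    def f(x):
        return (x - x0) ** 2 + (_curve(x, a) - y0) ** 2

    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = f(c), f(d)
    while np.max(hi - lo) > tol:
        left = fc < fd
        hi = np.where(left, d, hi)
        lo = np.where(left, lo, c)
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        fc, fd = f(c), f(d)
    xm = (lo + hi) / 2.0
    return f(xm)


def fit_exponential_roc(
    points: pd.DataFrame | np.ndarray,
    configuration_id: int | None = None,
) -> BootstrapFit:
    """Total-least-squares fit of y = 1 - e^(-a x) to pooled ROC points.

    Minimises the summed squared perpendicular distances to the curve over
    a in (0, 50]; the inner projection of each point is solved to 1e-10.
    NaN rates (single-class bootstrap trials) are dropped. Deterministic.
    """
    if isinstance(points, pd.DataFrame):
        x0 = points["fpr"].to_numpy(dtype=float)
        y0 = points["tpr"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x0, y0 = arr[:, 0], arr[:, 1]
    keep = np.isfinite(x0) & np.isfinite(y0)
    x0, y0 = x0[keep], y0[keep]
    if len(x0) == 0 or not np.any((x0 > 0) | (y0 > 0)):
        raise FitError(
            "cannot fit the ROC curve: no point with a positive rate "
            "(all points at the origin leave the parameter unidentified)"
        )

    def objective(a: float) -> float:
        return float(np.sum(_orthogonal_sq_distances(x0, y0, a)))

    res = minimize_scalar(
        objective, bounds=(1e-6, A_MAX), method="bounded", options={"xatol": 1e-8}
    )
    a = float(res.x)
    return BootstrapFit(a=a, auc=auc_from_a(a), n_points=len(x0), configuration_id=configuration_id)


def auc_from_a(a: float) -> float:
    """Closed-form area under y = 1 - e^(-a x) on [0, 1]:
    AUC = 1 - (1 - e^(-a)) / a."""
    if a <= 0:
        raise ValueError(f"curve parameter a must be > 0, got {a}")
    return float(1.0 + np.expm1(-a) / a)


def a_from_auc(auc: float, tol: float = 1e-10) -> float:
    """Invert the closed form by bisection; AUC must lie in (0.5, 1)."""
    if not 0.5 < auc < 1.0:
        raise ValueError(f"auc must be in (0.5, 1), got {auc}")
    lo, hi = 1e-9, A_MAX
    while auc_from_a(hi) < auc:
        hi *= 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if auc_from_a(mid) < auc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def operating_points(a: float) -> OperatingPoints:
    """Operating points of the fitted curve.

    The *optimal* point minimises the Euclidean distance to the ideal corner
    (FPR, TPR) = (0, 1); its stationarity condition x = a e^(-2 a x) has a
    unique root (the left side grows, the right side decays), found by
    bisection. The 80%-specificity point is TPR = 1 - e^(-0.2 a); the
    80%-sensitivity point has FPR = ln(5) / a.
    """
    if a <= 0:
        raise ValueError(f"curve parameter a must be > 0, got {a}")
    lo, hi = 0.0, max(1.0, a)
    while hi - lo > 1e-12:
        mid = (lo + hi) / 2.0
        if mid - a * np.exp(-2.0 * a * mid) < 0:
            lo = mid
        else:
            hi = mid
    x_opt = (lo + hi) / 2.0
    y_opt = float(-np.expm1(-a * x_opt))
    sens80 = float(-np.expm1(-0.2 * a))
    fpr_at_sens80 = float(np.log(5.0) / a)
    return OperatingPoints(
        optimal_fpr=x_opt,
        optimal_tpr=y_opt,
        sensitivity_at_spec80=sens80,
        specificity_at_sens80=1.0 - fpr_at_sens80,
    )


def criteria_report(fit: BootstrapFit) -> CriteriaReport:
    """Assess a fitted configuration against the published criteria:
    AUC strictly greater than 0.73; sensitivity >= 60% at 80% specificity;
    specificity >= 65% at 80% sensitivity."""
    ops = operating_points(fit.a)
    sens1 = 100.0 * ops.sensitivity_at_spec80
    spec2 = 100.0 * ops.specificity_at_sens80
    return CriteriaReport(
        auc=fit.auc,
        auc_ok=fit.auc > AUC_CRITERION,
        criterion1_sensitivity_at_spec80=sens1,
        criterion1_pass=sens1 >= 60.0,
        criterion2_specificity_at_sens80=spec2,
        criterion2_pass=spec2 >= 65.0,
        optimal_sensitivity=100.0 * ops.optimal_tpr,
        optimal_specificity=100.0 * (1.0 - ops.optimal_fpr),
    )
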