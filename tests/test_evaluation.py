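"""ROC machinery: confusion rates, tolerance sweep, bootstrap, the
total-least-squares exponential fit and its closed-form area/operating
points."""

import numpy as np
import pytest
from scipy.integrate import quad

from dietfreq import evaluation as ev
from dietfreq.diagnosis import Configuration, diagnose
from dietfreq.errors import FitError

from conftest import make_table


def _cohort(seed=0, n_cancer=6, n_healthy=6, cancer_scale=0.8, healthy_scale=0.1):
    """Synthetic segment tables whose max deviations separate by label."""
    rng = np.random.default_rng(seed)
    tables, labels = [], {}
    for i in range(n_cancer + n_healthy):
        label = "cancerous" if i < n_cancer else "healthy"
        scale = cancer_scale if label == "cancerous" else healthy_scale
        grid = 40.0 * (1.0 + scale * rng.uniform(0, 1, (4, 4)))
        t = make_table(grid, breast_id=f"B{i}")
        tables.append(t)
        labels[f"B{i}"] = label
    return tables, labels


CONFIG = Configuration(1, (0, 0, 0, 0))


class TestConfusion:
    def test_two_false_negatives_of_thirteen(self):
        calls = {f"C{i}": i >= 2 for i in range(13)}
        labels = {f"C{i}": "cancerous" for i in range(13)}
        cm = ev.confusion(calls, labels)
        assert cm.sensitivity == pytest.approx(11 / 13)
        assert cm.specificity is None

    def test_three_false_positives_of_thirteen(self):
        calls = {f"H{i}": i < 3 for i in range(13)}
        labels = {f"H{i}": "healthy" for i in range(13)}
        cm = ev.confusion(calls, labels)
        assert cm.specificity == pytest.approx(10 / 13)

    def test_perfect_calls(self):
        calls = {"c": True, "h": False}
        labels = {"c": "cancerous", "h": "healthy"}
        cm = ev.confusion(calls, labels)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_indeterminate_counted_separately(self):
        calls = {"c": None, "h": False}
        labels = {"c": "cancerous", "h": "healthy"}
        cm = ev.confusion(calls, labels)
        assert cm.n_indeterminate == 1 and cm.sensitivity is None


class TestToleranceSweep:
    def test_extremes_and_monotone_staircase(self):
        tables, labels = _cohort()
        grid = np.round(np.arange(0.0, 1.01, 0.05), 2)
        sweep = ev.tolerance_sweep(tables, labels, CONFIG, grid)
        assert sweep.iloc[0][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert sweep.iloc[-1][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert np.all(np.diff(sweep["tpr"]) <= 1e-12)
        assert np.all(np.diff(sweep["fpr"]) <= 1e-12)

    def test_matches_per_tolerance_brute_force(self):
        """Oracle: re-evaluate diagnose() from scratch at every grid point."""
        tables, labels = _cohort(seed=5)
        grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
        sweep = ev.tolerance_sweep(tables, labels, CONFIG, grid)
        for _, row in sweep.iterrows():
            pos = {t.breast_id: diagnose(t, CONFIG, row.tolerance).is_positive for t in tables}
            cm = ev.confusion(pos, labels)
            assert row.tpr == pytest.approx(cm.sensitivity)
            assert row.fpr == pytest.approx(1 - cm.specificity)


class TestBootstrap:
    def test_point_count_and_determinism(self):
        tables, labels = _cohort()
        grid = np.round(np.arange(0.0, 1.01, 0.05), 2)
        p1 = ev.bootstrap_points(tables, labels, CONFIG, n_draw=10, n_trials=20, grid=grid, seed=3)
        p2 = ev.bootstrap_points(tables, labels, CONFIG, n_draw=10, n_trials=20, grid=grid, seed=3)
        assert len(p1) == 20 * 21
        assert p1.equals(p2)
        assert not p1.equals(
            ev.bootstrap_points(tables, labels, CONFIG, n_draw=10, n_trials=20, grid=grid, seed=4)
        )

    def test_single_draw_rates_are_degenerate(self):
        tables, labels = _cohort()
        pts = ev.bootstrap_points(tables, labels, CONFIG, n_draw=1, n_trials=50, seed=0)
        vals = pts[["fpr", "tpr"]].to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_single_class_trials_keep_defined_rate(self):
        tables, labels = _cohort(n_cancer=1, n_healthy=5)
        pts = ev.bootstrap_points(tables, labels, CONFIG, n_draw=3, n_trials=40, seed=1)
        # some trials must miss the lone cancerous breast -> NaN TPR, finite FPR
        nan_tpr = pts["tpr"].isna()
        assert nan_tpr.any()
        assert pts.loc[nan_tpr, "fpr"].notna().all()


class TestExponentialFit:
    def test_on_curve_points_recover_a_exactly(self):
        x = np.linspace(0.02, 1.0, 50)
        y = 1.0 - np.exp(-2.0 * x)
        fit = ev.fit_exponential_roc(np.column_stack([x, y]))
        assert fit.a == pytest.approx(2.0, abs=1e-6)

    def test_single_point_closed_form(self):
        fit = ev.fit_exponential_roc(np.array([[0.5, 0.75]]))
        assert fit.a == pytest.approx(2.0 * np.log(4.0), abs=1e-6)

    def test_noisy_recovery_matches_grid_search_oracle(self):
        a_true = 3.0
        rng = np.random.default_rng(11)
        x = rng.uniform(0.0, 1.0, 1000)
        y = 1.0 - np.exp(-a_true * x)
        # symmetric orthogonal noise
        slope = a_true * np.exp(-a_true * x)
        nx = -slope / np.hypot(1.0, slope)
        ny = 1.0 / np.hypot(1.0, slope)
        eps = rng.normal(0.0, 0.03, 1000)
        pts = np.column_stack([x + eps * nx, y + eps * ny])
        fit = ev.fit_exponential_roc(pts)
        assert fit.a == pytest.approx(a_true, abs=0.15)
        # independent coarse grid-search oracle over a
        grid = np.linspace(1.5, 5.0, 141)
        objs = [np.sum(ev._orthogonal_sq_distances(pts[:, 0], pts[:, 1], a)) for a in grid]
        assert abs(fit.a - grid[int(np.argmin(objs))]) <= 0.05

    def test_all_origin_points_fail(self):
        with pytest.raises(FitError):
            ev.fit_exponential_roc(np.zeros((10, 2)))


class TestClosedForms:
    @pytest.mark.parametrize("a", [0.5, 2.0, 6.66])
    def test_auc_matches_quadrature(self, a):
        q = quad(lambda x: 1.0 - np.exp(-a * x), 0.0, 1.0, epsabs=1e-13)[0]
        assert abs(ev.auc_from_a(a) - q) < 1e-10

    def test_auc_strictly_increasing_and_curve_endpoint(self):
        a = np.linspace(0.1, 30.0, 200)
        aucs = [ev.auc_from_a(v) for v in a]
        assert np.all(np.diff(aucs) > 0)
        assert ev._curve(np.array([1.0]), 3.0)[0] == pytest.approx(1 - np.exp(-3.0))

    def test_a_from_auc_round_trip(self):
        assert ev.a_from_auc(ev.auc_from_a(3.0)) == pytest.approx(3.0, abs=1e-8)
        a85 = ev.a_from_auc(0.85)
        assert a85 == pytest.approx(6.66, abs=0.01)
        assert ev.auc_from_a(a85) == pytest.approx(0.85, abs=1e-9)

    def test_a_from_auc_monotone(self):
        grid = np.linspace(0.55, 0.95, 41)
        avals = [ev.a_from_auc(u) for u in grid]
        assert np.all(np.diff(avals) > 0)

    @pytest.mark.parametrize("bad", [0.5, 1.0, 0.2, -1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ev.a_from_auc(bad)
        with pytest.raises(ValueError):
            ev.auc_from_a(0.0)


class TestOperatingPoints:
    def test_published_auc_085_operating_points(self):
        ops = ev.operating_points(ev.a_from_auc(0.85))
        assert ops.optimal_sensitivity_pct == 81
        assert ops.optimal_specificity_pct == 75

    def test_published_auc_080_operating_points(self):
        ops = ev.operating_points(ev.a_from_auc(0.80))
        assert ops.optimal_sensitivity_pct == 76
        assert ops.optimal_specificity_pct == 71

    def test_large_a_approaches_perfect_corner(self):
        ops = ev.operating_points(5000.0)
        assert ops.optimal_sensitivity_pct == 100
        assert ops.optimal_specificity_pct == 100

    def test_stationarity_condition_holds(self):
        a = 4.2
        ops = ev.operating_points(a)
        x = ops.optimal_fpr
        assert x == pytest.approx(a * np.exp(-2 * a * x), abs=1e-9)


class TestCriteriaReport:
    def test_auc_085_meets_everything(self):
        fit = ev.BootstrapFit(a=ev.a_from_auc(0.85), auc=0.85, n_points=100)
        rep = ev.criteria_report(fit)
        assert rep.auc_ok and rep.criterion1_pass and rep.criterion2_pass
        assert round(rep.criterion1_sensitivity_at_spec80) == 74
        assert round(rep.criterion2_specificity_at_sens80) == 76

    def test_auc_070_fails_auc_criterion(self):
        fit = ev.BootstrapFit(a=ev.a_from_auc(0.70), auc=0.70, n_points=100)
        assert not ev.criteria_report(fit).auc_ok

    def test_boundary_auc_073_fails_strict_inequality(self):
        fit = ev.BootstrapFit(a=ev.a_from_auc(0.73), auc=0.73, n_points=100)
        assert not ev.criteria_report(fit).auc_ok
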