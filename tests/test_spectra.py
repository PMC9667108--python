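"""Spectral extraction: principal-axis projection, spectra, peak ranking
(against a brute-force oracle), the frequency-of-interest flowchart, and run
screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dietfreq.errors import NoUsableRunsError
from dietfreq.phantom import BreastSpec, MaterialSpec, RecordingParams, synth_recording
from dietfreq.spectra import (
    Peak,
    PointSpectrum,
    compute_spectrum,
    extract_foi,
    frequency_of_interest,
    project_scalar,
    rank_peaks,
    select_usable_runs,
)


def _tone(freq, fs=500.0, dur=2.0, amp=1.0, phase=0.3):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestProjectScalar:
    def test_recovers_single_axis_sinusoid(self):
        axis = np.array([0.6, 0.0, 0.8])
        s = _tone(23.0)
        traj = axis[None, :] * s[:, None]
        out, degenerate = project_scalar(traj)
        assert not degenerate
        assert abs(out.mean()) < 1e-12
        # projection recovers the scalar up to sign
        assert min(np.max(np.abs(out - s)), np.max(np.abs(out + s))) < 1e-9

    def test_zero_trajectory_degenerate(self):
        out, degenerate = project_scalar(np.zeros((64, 3)))
        assert degenerate
        assert np.all(out == 0.0)

    def test_two_tone_retains_both_frequencies(self):
        # oblique two-tone motion: both tones must survive the projection
        s1, s2 = _tone(23.0), _tone(50.0, amp=0.4)
        traj = np.array([0.9, 0.1, 0.4])[None, :] * s1[:, None] + np.array(
            [0.8, 0.2, 0.5]
        )[None, :] * s2[:, None]
        out, degenerate = project_scalar(traj)
        assert not degenerate
        spec = compute_spectrum(out, 500.0)
        # oracle: per-component DFT says the tones live at 23 and 50 Hz
        for f in (23.0, 50.0):
            idx = np.argmin(np.abs(spec.frequencies - f))
            assert spec.magnitudes[idx] > 0.05


class TestComputeSpectrum:
    def test_single_tone_peak_location(self):
        spec = compute_spectrum(_tone(23.0), 500.0)
        assert spec.frequencies[np.argmax(spec.magnitudes)] == pytest.approx(23.0)
        assert spec.frequencies[0] > 0  # DC removed
        assert spec.resolution == pytest.approx(0.5)

    def test_two_tone_magnitude_ratio(self):
        s = _tone(23.0) + _tone(50.0, amp=0.3, phase=1.1)
        spec = compute_spectrum(s, 500.0)
        i23 = np.argmin(np.abs(spec.frequencies - 23.0))
        i50 = np.argmin(np.abs(spec.frequencies - 50.0))
        assert spec.magnitudes[i50] / spec.magnitudes[i23] == pytest.approx(0.3, abs=0.02)
        assert spec.magnitudes[i23] == pytest.approx(1.0, abs=0.02)

    def test_zero_series_all_zero(self):
        spec = compute_spectrum(np.zeros(256), 500.0)
        assert np.all(spec.magnitudes == 0.0)


class TestRankPeaks:
    def test_two_tone_ordering(self):
        spec = compute_spectrum(_tone(23.0) + _tone(50.0, amp=0.3), 500.0)
        peaks = rank_peaks(spec)
        assert peaks[0].frequency == pytest.approx(23.0)
        assert peaks[1].frequency == pytest.approx(50.0)

    def test_flat_spectrum_empty(self):
        spec = PointSpectrum(np.arange(1.0, 11.0), np.ones(10))
        assert rank_peaks(spec) == []

    def test_equal_peaks_tie_break_to_lower_frequency(self):
        # exact magnitude tie, constructed directly in the spectral domain
        freqs = np.arange(1.0, 61.0)
        mags = np.zeros(60)
        mags[freqs == 20.0] = 1.0
        mags[freqs == 40.0] = 1.0
        peaks = rank_peaks(PointSpectrum(freqs, mags))
        assert peaks[0].frequency == pytest.approx(20.0)
        assert peaks[1].frequency == pytest.approx(40.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        """Dominant and second-dominant agree with exhaustive local-maximum
        search plus greedy exclusion on random short signals."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(64, 1024))
        t = np.arange(n) / 200.0
        f1, f2 = rng.uniform(5, 40, 2)
        sig = (
            0.05 * rng.standard_normal(n)
            + np.sin(2 * np.pi * f1 * t)
            + 0.5 * np.sin(2 * np.pi * f2 * t)
        )
        spec = compute_spectrum(sig, 200.0)
        got = rank_peaks(spec, exclusion_halfwidth=2)

        # oracle: exhaustive plain-python enumeration of the same rule
        m = spec.magnitudes
        cands = []
        for i in range(len(m)):
            if i == 0:
                ok = m[0] > m[1]
            elif i == len(m) - 1:
                ok = m[i] > m[i - 1]
            else:
                ok = m[i] > m[i - 1] and m[i] >= m[i + 1]
            if ok:
                cands.append(i)
        cands.sort(key=lambda i: (-m[i], spec.frequencies[i]))
        expect = []
        for i in cands:
            if all(abs(i - j) > 2 for j in expect):
                expect.append(i)
        assert [p.index for p in got] == expect


class TestFrequencyOfInterest:
    def test_second_dominant_branch(self):
        peaks = [Peak(23.0, 1.0, 46), Peak(50.0, 0.3, 100)]
        res = frequency_of_interest(peaks, 23.0)
        assert res.status == "retained"
        assert res.branch == "second_dominant"
        assert res.frequency_of_interest == 50.0

    def test_weak_second_peak_discarded(self):
        peaks = [Peak(23.0, 1.0, 46), Peak(50.0, 0.10, 100)]
        res = frequency_of_interest(peaks, 23.0)
        assert res.status == "excluded"

    def test_irregular_dominant_branch(self):
        peaks = [Peak(37.0, 1.0, 74), Peak(23.0, 0.9, 46)]
        res = frequency_of_interest(peaks, 23.0)
        assert res.status == "retained"
        assert res.branch == "irregular_dominant"
        assert res.frequency_of_interest == 37.0

    def test_threshold_is_inclusive_at_15_percent(self):
        peaks = [Peak(23.0, 1.0, 46), Peak(50.0, 0.15, 100)]
        assert frequency_of_interest(peaks, 23.0).status == "retained"

    def test_empty_peaks_degenerate(self):
        res = frequency_of_interest([], 23.0)
        assert res.status == "excluded" and res.degenerate

    def test_pure_input_tone_always_excluded(self):
        """A point vibrating only at the actuation frequency offers no second
        peak and must be discarded."""
        spec = compute_spectrum(_tone(23.0), 500.0)
        peaks = rank_peaks(spec, max_peaks=2)
        res = frequency_of_interest(peaks, 23.0)
        assert res.status == "excluded"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_invariant_to_amplitude_scaling(self, scale):
        s = _tone(23.0) + _tone(50.0, amp=0.3)
        for sig in (s, scale * s):
            peaks = rank_peaks(compute_spectrum(sig, 500.0), max_peaks=2)
            res = frequency_of_interest(peaks, 23.0)
            assert res.status == "retained"
            assert res.frequency_of_interest == pytest.approx(50.0)


class TestExtractFoiOnPhantom:
    def test_noise_free_foi_matches_ground_truth(self):
        """On noise-free phantom data the second-dominant branch recovers
        r(p) x input frequency within one spectral bin."""
        b = BreastSpec("B", "left", n_points=48)
        par = RecordingParams(input_frequency=22.0, noise_sd=0.0, seed=3)
        mat = MaterialSpec(heterogeneity_sd=0.0)
        rec = synth_recording(b, par, mat)
        foi = extract_foi(rec)
        assert (foi["branch"] == "second_dominant").all()
        np.testing.assert_allclose(
            foi["foi_hz"], mat.healthy_secondary_ratio * 22.0, atol=0.51
        )

    def test_weak_secondary_regime_excluded(self):
        b = BreastSpec("B", "left", n_points=32)
        par = RecordingParams(noise_sd=0.0, seed=3)
        mat = MaterialSpec(secondary_mag_fraction=0.05, heterogeneity_sd=0.0)
        rec = synth_recording(b, par, mat)
        foi = extract_foi(rec)
        assert (foi["status"] == "excluded").all()


class TestSelectUsableRuns:
    def _means(self, n_irregular, f_in=23.0):
        means = np.full(16, f_in)
        means[:n_irregular] = f_in + 3.0  # > 2 Hz off
        return means

    def test_clean_run_retained(self):
        runs, fr = select_usable_runs({23.0: self._means(0)})
        assert runs == [23.0] and fr[23.0] == 0.0

    def test_two_of_sixteen_irregular_rejected(self):
        with pytest.raises(NoUsableRunsError) as exc:
            select_usable_runs({23.0: self._means(2)})
        assert exc.value.fractions[23.0] == pytest.approx(0.125)

    def test_one_of_sixteen_irregular_retained(self):
        runs, fr = select_usable_runs({23.0: self._means(1)})
        assert runs == [23.0] and fr[23.0] == pytest.approx(0.0625)

    def test_mixed_runs_report_all_fractions(self):
        runs, fr = select_usable_runs({20.0: self._means(0, 20.0), 23.0: self._means(3)})
        assert runs == [20.0]
        assert set(fr) == {20.0, 23.0}
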