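"""Up/Down detector: features, PCA projection, bimodal threshold,
minimum-duration filtering, state statistics and spectral analysis."""
import numpy as np
import pytest

from slowwave.containers import ValidationError
from slowwave.states import (
    BandPowerSpec,
    BistabilityError,
    FeatureMatrix,
    PsdEstimate,
    band_power,
    binarize_and_filter,
    build_feature_matrix,
    compute_gamma_variance_envelope,
    compute_log_mua,
    project_first_pc,
    segment_states,
    select_bimodal_threshold,
    state_statistics,
    welch_psd,
)
from slowwave.synthetic import SlowOscParams, simulate_slow_oscillation

FS = 5000.0


class TestLogMua:
    def test_out_of_band_sinusoid_sits_at_floor(self):
        t = np.arange(0, 4, 1 / FS)
        lm = compute_log_mua(100.0 * np.sin(2 * np.pi * 10 * t), FS)
        # no 200-1500 Hz content: power is epsilon-floored, log finite
        assert np.all(np.isfinite(lm))
        assert np.median(lm) < np.log(1e-6)

    def test_doubled_amplitude_shifts_log_power_by_log4(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        x[50_000:] *= 2.0
        lm = compute_log_mua(x, FS)
        diff = lm[55_000:95_000].mean() - lm[5_000:45_000].mean()
        assert diff == pytest.approx(np.log(4.0), rel=0.05)

    def test_up_samples_exceed_down_samples(self, slow_osc_sim):
        rec, gt = slow_osc_sim
        lm = compute_log_mua(rec.channel(0), rec.sampling_rate)
        up = gt.state_labels == 1
        assert lm[up].mean() > lm[~up].mean()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            compute_log_mua(np.zeros(1000), 2000.0, band=(200.0, 1500.0))


class TestGammaVariance:
    def test_dc_input_has_zero_envelope(self):
        env = compute_gamma_variance_envelope(np.full(20_000, 7.0), FS)
        assert np.all(env < 1e-12)

    def test_sinusoid_envelope_equals_half_amplitude_squared(self):
        A = 7.0
        t = np.arange(0, 6, 1 / FS)
        env = compute_gamma_variance_envelope(A * np.sin(2 * np.pi * 50 * t), FS)
        steady = env[5_000:25_000]
        assert steady.mean() == pytest.approx(A * A / 2, rel=0.02)

    def test_up_samples_exceed_down_samples(self, slow_osc_sim):
        rec, gt = slow_osc_sim
        env = compute_gamma_variance_envelope(rec.channel(0), rec.sampling_rate)
        up = gt.state_labels == 1
        assert env[up].mean() > env[~up].mean()

    def test_window_shorter_than_three_cycles_rejected(self):
        with pytest.raises(ValidationError):
            compute_gamma_variance_envelope(
                np.zeros(10_000), FS, gamma_band=(30.0, 100.0),
                var_window_s=0.05)


class TestFeatureMatrix:
    def test_columns_are_z_scored(self, slow_osc_sim):
        rec, _ = slow_osc_sim
        x = rec.channel(0)
        lm = compute_log_mua(x, FS)
        gv = compute_gamma_variance_envelope(x, FS)
        fm = build_feature_matrix(x, lm, gv, FS)
        assert np.allclose(fm.z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.z.std(axis=0), 1.0, atol=1e-9)
        assert not np.any(np.isnan(fm.z))

    def test_affine_invariance_of_inputs(self):
        rng = np.random.default_rng(1)
        a, b, c = rng.standard_normal((3, 5000))
        fm1 = build_feature_matrix(a, b, c, FS)
        fm2 = build_feature_matrix(3.0 * a - 7.0, b, c, FS)
        np.testing.assert_allclose(fm1.z[:, 0], fm2.z[:, 0], atol=1e-9)

    def test_hand_computed_z_scores(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fm = build_feature_matrix(col, col, col, sampling_rate=1.0,
                                  feature_step_s=1.0)
        expected = (col - 3.0) / np.std(col)
        np.testing.assert_allclose(fm.z[:, 1], expected, atol=1e-12)

    def test_zero_variance_column_named_in_error(self):
        x = np.random.default_rng(0).standard_normal(1000)
        with pytest.raises(ValidationError, match="z_gammavar"):
            build_feature_matrix(x, x, np.zeros_like(x), FS)


class TestProjection:
    def test_identical_columns_reproduce_the_column(self):
        z = np.random.default_rng(2).standard_normal(2000)
        z = (z - z.mean()) / z.std()
        fm = FeatureMatrix(z=np.column_stack([z, z, z]), feature_rate=200.0,
                           step=25)
        proj = project_first_pc(fm)
        assert proj.explained_variance_fraction == pytest.approx(1.0)
        # projection is the shared column up to the sqrt(3) loading norm
        np.testing.assert_allclose(proj.pc1 / np.sqrt(3.0), z, atol=1e-9)

    def test_two_feature_toy_matches_closed_form_eigenvector(self):
        # third column constant: covariance is effectively 2x2 with known
        # entries, whose leading eigenvector has a closed form
        rng = np.random.default_rng(3)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * rng.standard_normal(n)
        z = np.column_stack([a, b, np.zeros(n)])
        proj = project_first_pc(FeatureMatrix(z=z, feature_rate=200.0, step=25))
        assert "rank-deficient feature covariance" in proj.warnings
        cov = np.cov(a, b)
        # leading eigenvector of [[s11,s12],[s12,s22]]
        tr, det = cov[0, 0] + cov[1, 1], np.linalg.det(cov)
        lam = tr / 2 + np.sqrt(tr**2 / 4 - det)
        v = np.array([cov[0, 1], lam - cov[0, 0]])
        v /= np.linalg.norm(v)
        got = proj.loadings[:2] / np.linalg.norm(proj.loadings[:2])
        assert abs(np.dot(got, v)) == pytest.approx(1.0, abs=1e-6)

    def test_simulated_recording_has_dominant_pc1(self, slow_osc_sim):
        rec, _ = slow_osc_sim
        res = segment_states(rec, seed=0)
        assert res.projection.explained_variance_fraction > 1.0 / 3.0
        # sign convention: pc1 correlates positively with z_logmua
        r = np.corrcoef(res.projection.pc1, res.features.z[:, 1])[0, 1]
        assert r > 0


class TestBimodalThreshold:
    def test_symmetric_mixture_threshold_near_zero(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.3, 2500), rng.normal(2, 0.3, 2500)])
        res = select_bimodal_threshold(x, seed=0)
        assert -1.0 < res.threshold < 1.0
        assert abs(res.threshold) < 0.2
        assert res.separation_index > 2.0

    def test_unimodal_sample_raises(self):
        x = np.random.default_rng(5).normal(0.0, 1.0, 5000)
        with pytest.raises(BistabilityError):
            select_bimodal_threshold(x, seed=0)


def _oracle_filter(labels: np.ndarray, min_samples: int) -> np.ndarray:
    """Brute force: rescan, flip the shortest sub-minimum interior run."""
    labels = labels.copy()
    while True:
        runs = []
        start = 0
        for i in range(1, labels.size + 1):
            if i == labels.size or labels[i] != labels[start]:
                runs.append((int(labels[start]), start, i))
                start = i
        shorts = [(i1 - i0, k) for k, (st, i0, i1) in enumerate(runs)
                  if 0 < k < len(runs) - 1 and i1 - i0 < min_samples]
        if not shorts:
            return labels
        _, k = min(shorts)
        st, i0, i1 = runs[k]
        labels[i0:i1] = 1 - st


class TestBinarizeAndFilter:
    def test_hand_merge_example(self):
        # Up 100 ms, Down 40 ms, Up 200 ms at 1 kHz -> one 340 ms Up run,
        # but only once flanked so the merge rule applies to the interior
        fs = 1000.0
        labels = np.concatenate([
            np.zeros(100), np.ones(100), np.zeros(40), np.ones(200),
            np.zeros(100)])
        series = labels * 2.0 - 1.0  # above/below a 0 threshold
        seg = binarize_and_filter(series, 0.0, rate=fs, min_duration=0.080)
        states = [s for s, _, _ in seg.intervals]
        durs = [e - s for _, s, e in seg.intervals]
        assert states == [0, 1, 0]
        assert durs[1] == pytest.approx(0.340)

    def test_constant_series_single_interval(self):
        seg = binarize_and_filter(np.ones(1000), 0.5, rate=1000.0)
        assert seg.intervals == [(1, 0.0, 1.0)]

    def test_no_interior_interval_below_minimum(self):
        rng = np.random.default_rng(6)
        series = rng.standard_normal(5000)
        seg = binarize_and_filter(series, 0.0, rate=1000.0, min_duration=0.080)
        for st, s, e in seg.intervals[1:-1]:
            assert e - s >= 0.080 - 1e-12

    def test_alternation_and_label_consistency(self):
        rng = np.random.default_rng(7)
        series = np.repeat(rng.standard_normal(100), 30)
        seg = binarize_and_filter(series, 0.0, rate=1000.0)
        for (s1, _, _), (s2, _, _) in zip(seg.intervals, seg.intervals[1:]):
            assert s1 != s2
        from slowwave.synthetic import labels_to_intervals
        assert labels_to_intervals(seg.labels, 1000.0) == seg.intervals

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(8)
        fs = 1000.0
        for _ in range(300):
            n_runs = rng.integers(1, 60)
            runs = rng.integers(1, 200, size=n_runs)
            first = rng.integers(0, 2)
            labels = np.concatenate([
                np.full(r, (first + k) % 2, dtype=np.int8)
                for k, r in enumerate(runs)])
            seg = binarize_and_filter(labels.astype(float), 0.5, rate=fs,
                                      min_duration=0.080)
            expected = _oracle_filter(labels, 80)
            np.testing.assert_array_equal(seg.labels, expected)

    def test_threshold_monotonicity_prefilter(self):
        rng = np.random.default_rng(9)
        series = rng.standard_normal(20_000)
        up_time = [np.sum(series >= thr) for thr in (-1.0, 0.0, 0.5, 1.5)]
        assert all(a >= b for a, b in zip(up_time, up_time[1:]))

    def test_invalid_min_duration(self):
        with pytest.raises(ValidationError):
            binarize_and_filter(np.zeros(10), 0.0, rate=100.0, min_duration=0.0)


class TestStateStatistics:
    def _seg(self, labels, fs=1000.0):
        from slowwave.synthetic import labels_to_intervals
        from slowwave.states import StateSegmentation
        labels = np.asarray(labels, dtype=np.int8)
        return StateSegmentation(labels=labels, rate=fs,
                                 intervals=labels_to_intervals(labels, fs),
                                 threshold_used=0.0)

    def test_mean_duration_arithmetic(self):
        seg = self._seg(np.concatenate([
            np.ones(200), np.zeros(100), np.ones(400), np.zeros(100)]))
        stats = state_statistics(seg, np.zeros(800))
        assert stats.mean_up_duration == pytest.approx(0.3)
        assert stats.n_up == 2

    def test_identity_logmua_recovers_labels(self):
        labels = np.concatenate([np.ones(100), np.zeros(100)])
        seg = self._seg(labels)
        stats = state_statistics(seg, labels.astype(float))
        assert stats.firing_rate_up == 1.0
        assert stats.firing_rate_down == 0.0

    def test_no_up_interval_marks_nan(self):
        seg = self._seg(np.zeros(500))
        stats = state_statistics(seg, np.zeros(500))
        assert np.isnan(stats.mean_up_duration)
        assert stats.n_up == 0

    def test_detected_up_fires_more_than_down(self, slow_osc_sim):
        rec, _ = slow_osc_sim
        res = segment_states(rec, seed=0)
        assert res.stats.firing_rate_up > res.stats.firing_rate_down


class TestEndToEndDetection:
    def test_high_snr_recovery(self, slow_osc_sim):
        rec, gt = slow_osc_sim
        res = segment_states(rec, seed=0)
        agreement = np.mean(res.full_rate_labels == gt.state_labels)
        assert agreement >= 0.95
        true_mean = gt.mean_true_duration(1)
        assert res.stats.mean_up_duration == pytest.approx(true_mean, rel=0.10)

    def test_scale_invariance_of_segmentation(self, slow_osc_sim):
        rec, _ = slow_osc_sim
        res1 = segment_states(rec, seed=0)
        from slowwave.containers import LfpRecording
        scaled = LfpRecording(rec.samples * 37.0, rec.sampling_rate)
        res2 = segment_states(scaled, seed=0)
        np.testing.assert_array_equal(res1.segmentation.labels,
                                      res2.segmentation.labels)

    def test_logmua_detection_signal_also_recovers(self, slow_osc_sim):
        rec, gt = slow_osc_sim
        res = segment_states(rec, detection_signal="logmua", seed=0)
        agreement = np.mean(res.full_rate_labels == gt.state_labels)
        assert agreement >= 0.90


class TestSpectral:
    def test_white_noise_psd_integrates_to_variance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(int(60 * FS))
        x = (x - x.mean()) / x.std()
        psd = welch_psd(x, FS)
        assert np.sum(psd.power) * psd.df == pytest.approx(1.0, rel=0.10)

    def test_sinusoid_peak_bin_location(self):
        t = np.arange(0, 20, 1 / FS)
        s = np.sin(2 * np.pi * 10 * t)
        s = (s - s.mean()) / s.std()
        psd = welch_psd(s, FS)
        assert psd.frequencies[np.argmax(psd.power)] == pytest.approx(10.0)

    def test_zero_signal_zero_psd(self):
        psd = welch_psd(np.zeros(int(4 * FS)), FS)
        assert np.all(psd.power == 0)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValidationError):
            welch_psd(np.zeros(1000), FS, window_s=2.0)

    def test_sinusoid_alpha_dominates(self):
        t = np.arange(0, 20, 1 / FS)
        s = np.sin(2 * np.pi * 10 * t)
        psd = welch_psd((s - s.mean()) / s.std(), FS)
        bp = band_power(psd)
        assert bp["alpha"] / max(bp["beta"], bp["low_gamma"],
                                 bp["high_gamma"]) > 100

    def test_flat_psd_reports_constant_in_every_band(self):
        freqs = np.arange(0, 200.0, 0.1)
        psd = PsdEstimate(frequencies=freqs,
                          power=np.full_like(freqs, 3.5),
                          window_s=2.0, bin_hz=0.1)
        bp = band_power(psd)
        assert all(v == pytest.approx(3.5) for v in bp.values())

    def test_band_beyond_psd_range_rejected(self):
        freqs = np.arange(0, 50.0, 0.1)
        psd = PsdEstimate(freqs, np.ones_like(freqs), 2.0, 0.1)
        with pytest.raises(ValidationError):
            band_power(psd)

    def test_doubling_gamma_amplitude_raises_low_gamma_power(self):
        common = dict(duration=20.0, seed=33)
        psds = []
        for amp in (10.0, 20.0):
            rec, _ = simulate_slow_oscillation(
                SlowOscParams(up_gamma_amp=amp, **common))
            x = rec.channel(0)
            z = (x - x.mean()) / x.std()
            psds.append(band_power(welch_psd(z, FS))["low_gamma"])
        assert psds[1] > psds[0]

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValidationError):
            BandPowerSpec(bands={"a": (8.0, 30.0), "b": (12.0, 40.0)}).validate()
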