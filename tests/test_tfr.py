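import numpy as np
import pytest

from alphasync import simulate as sim
from alphasync import tfr as tfrmod
from alphasync.preprocess import EpochSet, prestim_standardize
from conftest import POWER_FREQS, single_roi_power


def _epochs(data, fs=600.0, t0=-500.0):
    return EpochSet(np.atleast_2d(data), fs, t0)


class TestMorletTfr:
    def test_standard_window_valid_range(self):
        ep = _epochs(np.zeros((2, 1500)))
        tf = tfrmod.morlet_tfr(ep, [10.0], n_cycles=7)
        vt = tf.valid_times(10.0)
        assert vt[0] == pytest.approx(-150.0, abs=1e-6)
        assert vt[-1] == pytest.approx(1650.0, abs=1e-6)

    def test_valid_mask_arithmetic_generic(self):
        # valid range is [t0 + (n_cycles/2)/f, t1 - (n_cycles/2)/f]
        ep = EpochSet(np.zeros((1, 900)), 300.0, -1000.0)
        tf = tfrmod.morlet_tfr(ep, [5.0, 15.0], n_cycles=6)
        for i, f in enumerate((5.0, 15.0)):
            half_ms = 1000.0 * 3.0 / f
            vt = tf.times_ms[tf.valid_mask[i]]
            assert vt[0] >= -1000.0 + half_ms - 1e-6
            assert vt[-1] <= 2000.0 - half_ms + 1e-6
            # and the mask is maximal: one sample earlier/later is invalid
            step = 1000.0 / 300.0
            assert vt[0] - step < -1000.0 + half_ms
            assert vt[-1] + step > 2000.0 - half_ms

    def test_zero_signal_zero_coefficients(self):
        tf = tfrmod.morlet_tfr(_epochs(np.zeros((3, 1500))), [8.0, 10.0])
        assert np.all(tf.coeffs == 0)

    def test_stationary_cosine_flat_and_selective(self):
        t = (-500.0 + 1000.0 * np.arange(1500) / 600.0) / 1000.0
        tf = tfrmod.morlet_tfr(_epochs(np.cos(2 * np.pi * 10 * t)), [10.0, 20.0])
        p10 = np.abs(tf.coeffs[0, 0, tf.valid_mask[0]]) ** 2
        p20 = np.abs(tf.coeffs[0, 1, tf.valid_mask[1]]) ** 2
        assert p10.std() / p10.mean() < 0.01  # constant over valid samples
        assert p10.mean() > 10 * p20.mean()
        assert p10.mean() == pytest.approx(1.0, rel=0.01)  # unit-gain kernel

    def test_amplitude_equivariance_of_power(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.standard_normal((2, 1500)))
        tf1 = tfrmod.morlet_tfr(ep, [10.0])
        tf2 = tfrmod.morlet_tfr(ep.copy_with(3.0 * ep.data), [10.0])
        np.testing.assert_allclose(
            np.abs(tf2.coeffs) ** 2, 9.0 * np.abs(tf1.coeffs) ** 2, rtol=1e-9
        )

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            tfrmod.morlet_tfr(_epochs(np.zeros((1, 100)), fs=100.0), [60.0])


class TestFitOneOverF:
    def test_exact_power_law(self):
        f = np.arange(5.0, 61.0)
        fit = tfrmod.fit_one_over_f(f, 8.0 / f**1.5)
        assert fit.beta == pytest.approx(8.0, rel=1e-10)
        assert fit.gamma == pytest.approx(1.5, abs=1e-10)

    def test_flat_spectrum(self):
        f = np.arange(5.0, 61.0)
        fit = tfrmod.fit_one_over_f(f, np.full_like(f, 3.0))
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)
        assert fit.beta == pytest.approx(3.0, rel=1e-12)

    def test_wavelet_spectrum_slope_of_onef_noise(self):
        # constant-cycles kernels have noise bandwidth proportional to f, so
        # the wavelet-measured spectrum of 1/f noise is flat (exponent
        # gamma - 1); the aperiodic fit must flatten exactly what the
        # wavelet measures, not the underlying PSD
        x = sim.onef_noise(1.0, 1.0, 240000, 600.0, seed=9, n_series=1)
        ep = EpochSet(x.reshape(160, 1500), 600.0, -500.0)
        tf = tfrmod.morlet_tfr(ep, np.arange(5.0, 61.0, 5.0))
        fit = tfrmod.fit_one_over_f(tf.freqs, tfrmod.prestim_spectrum(tf))
        assert abs(fit.gamma - 0.0) < 0.1

    def test_nonpositive_power_rejected(self):
        f = np.arange(5.0, 61.0)
        with pytest.raises(ValueError):
            tfrmod.fit_one_over_f(f, np.zeros_like(f))

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            tfrmod.fit_one_over_f(np.array([10.0, 20.0]), np.array([1.0, 1.0]))


class TestNormalizePower:
    def _noise_power(self, seed, n_trials=40):
        cfg = sim.SimConfig(
            n_subjects=1, n_trials=n_trials, fs=200.0,
            epoch_window_ms=(-500.0, 2000.0), rois={"roi": "null"},
            osc_amp=0.0, seed=seed,
        )
        subject, _ = sim.simulate_subject(cfg, 0)
        tf = tfrmod.morlet_tfr(subject["roi"], POWER_FREQS)
        fit = tfrmod.fit_one_over_f(tf.freqs, tfrmod.prestim_spectrum(tf),
                                    fit_range=(6, 14))
        return tfrmod.normalize_power(tf, fit=fit)

    def test_baseline_centered_and_post_stim_calibrated(self):
        # single-run baselines are short and autocorrelated, so pool z values
        # over seeds before checking the moments; post-stimulus samples are
        # independent of the baseline moments and must come out ~N(0, 1)
        base, post = [], []
        for seed in range(20):
            pt = self._noise_power(seed)
            base.append(pt.z[pt.times_ms < 0])
            post.append(pt.z[pt.times_ms > 0])
        base = np.concatenate(base)
        post = np.concatenate(post)
        assert abs(base.mean()) < 0.25
        assert base.std() < 1.2  # conservative at baseline by construction
        assert abs(post.mean()) < 0.25
        assert post.std() == pytest.approx(1.0, abs=0.3)

    def test_null_false_positive_rate_below_1_percent(self):
        # stationary noise, no event: post-stimulus |z| >= 3 should be rare
        n_extreme = 0
        n_total = 0
        for seed in range(30):
            pt = self._noise_power(seed)
            post = pt.z[pt.times_ms > 0]
            n_extreme += int((np.abs(post) >= 3).sum())
            n_total += post.size
        assert n_extreme / n_total < 0.01

    def test_amplitude_doubling_detected(self):
        # 10 Hz amplitude doubled from 300 ms onward -> z > 3 inside the window
        rng = np.random.default_rng(3)
        t_ms = -500.0 + 1000.0 * np.arange(500) / 200.0
        osc = np.cos(2 * np.pi * 10 * t_ms / 1000.0 + rng.uniform(0, 2 * np.pi, (60, 1)))
        gain = np.where(t_ms > 300.0, 2.0, 1.0)
        data = osc * gain + rng.standard_normal((60, 500))
        tf = tfrmod.morlet_tfr(EpochSet(data, 200.0, -500.0), POWER_FREQS)
        pt = tfrmod.normalize_power(tf)
        window = (pt.times_ms > 700) & (pt.times_ms < 1200)
        assert np.all(pt.z[window] > 3)

    def test_pseudo_z_invariant_to_global_scaling(self):
        cfg = sim.SimConfig(n_subjects=1, n_trials=20, fs=200.0,
                            epoch_window_ms=(-500.0, 2000.0),
                            rois={"roi": "null"}, seed=4)
        subject, _ = sim.simulate_subject(cfg, 0)
        ep = subject["roi"]
        tf1 = tfrmod.morlet_tfr(ep, POWER_FREQS)
        tf2 = tfrmod.morlet_tfr(ep.copy_with(5.0 * ep.data), POWER_FREQS)
        z1 = tfrmod.normalize_power(tf1).z
        z2 = tfrmod.normalize_power(tf2).z
        np.testing.assert_allclose(z1, z2, atol=1e-8)

    def test_pooled_variance_mode_saturates_below_three(self):
        # with K pooled frequencies the across-frequency variance bounds
        # any deterministic z by sqrt(K-1); a strong oscillation therefore
        # cannot exceed 3 under the literal pooled estimator
        pt = single_roi_power("null", 17, osc_amp=10.0)
        assert pt.z.max() > 3  # default within-freq mode does exceed 3
        cfg = sim.SimConfig(n_subjects=1, n_trials=60, fs=200.0,
                            epoch_window_ms=(-500.0, 2000.0),
                            rois={"roi": "null"}, osc_amp=10.0, seed=17)
        subject, _ = sim.simulate_subject(cfg, 0)
        tf = tfrmod.morlet_tfr(subject["roi"], POWER_FREQS)
        zp = tfrmod.normalize_power(tf, var_mode="pooled").z
        assert zp.max() < 3.0

    def test_missing_baseline_freq_rejected(self):
        ep = _epochs(np.random.default_rng(0).standard_normal((5, 1500)))
        tf = tfrmod.morlet_tfr(ep, [10.0])
        with pytest.raises(ValueError):
            tfrmod.normalize_power(tf)


class TestIntervals:
    def _pt(self, z, se=None, t0=0.0, dt=10.0):
        z = np.asarray(z, dtype=float)
        se = np.full_like(z, 0.1) if se is None else np.asarray(se, dtype=float)
        t = t0 + dt * np.arange(z.size)
        return tfrmod.PowerTimecourse(z, se, t, n=10)

    def test_constant_high_z_single_interval(self):
        pt = self._pt(np.full(20, 5.0))
        iv = tfrmod.active_intervals(pt)
        assert iv.intervals == [(0.0, 190.0)]

    def test_block_interval_endpoints(self):
        z = np.zeros(100)
        z[10:41] = 5.0  # samples at 100..400 ms inclusive
        iv = tfrmod.active_intervals(self._pt(z))
        assert iv.intervals == [(100.0, 400.0)]

    def test_erd_first_interval_ends_near_onset(self):
        pt = single_roi_power("early-drop", seed=5)
        iv = tfrmod.active_intervals(pt, 3.0)
        assert iv.intervals, "expected an above-threshold baseline interval"
        first_end = iv.intervals[0][1]
        assert abs(first_end - 300.0) <= 50.0 + 40.0  # onset minus smoothing slack

    def test_identical_inputs_no_divergence(self):
        pt = self._pt(np.sin(np.arange(50)), se=np.full(50, 0.2))
        assert tfrmod.divergence_intervals(pt, pt).intervals == []

    def test_shifted_block_divergence(self):
        za = np.zeros(100)
        zb = np.zeros(100)
        zb[50:81] = 10 * np.sqrt(2) * 0.1  # 10 x pooled SE on [500, 800] ms
        iv = tfrmod.divergence_intervals(self._pt(za), self._pt(zb), k=4.0)
        assert iv.intervals == [(500.0, 800.0)]

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            tfrmod.divergence_intervals(self._pt(np.zeros(10)),
                                        self._pt(np.zeros(11)))


class TestSubsetAverage:
    def _tfr_with_meta(self, seed=0, n_trials=40, contra_depth=None):
        cfg = sim.SimConfig(n_subjects=1, n_trials=n_trials, fs=200.0,
                            epoch_window_ms=(-500.0, 2000.0),
                            rois={"roi": "null"}, osc_amp=2.0, seed=seed)
        subject, _ = sim.simulate_subject(cfg, 0)
        ep = subject["roi"]
        if contra_depth is not None:
            # re-build with hemifield-dependent ERD using the envelope op
            rng = np.random.default_rng(seed)
            t_ms = ep.times_ms
            phases = rng.uniform(0, 2 * np.pi, (n_trials, 1))
            osc = 2.0 * np.cos(2 * np.pi * 10 * t_ms / 1000.0 + phases)
            depths = np.where(ep.trial_meta["hemifield"] == "contra",
                              contra_depth, 0.0)
            osc_ep = sim.apply_power_envelope(
                ep.copy_with(osc), "early-drop", 300.0, depths)
            noise = sim.onef_noise(1.0, 1.0, ep.n_samples, ep.fs,
                                   n_series=n_trials, rng=rng)
            ep = ep.copy_with(osc_ep.data + noise)
        return tfrmod.morlet_tfr(ep, POWER_FREQS)

    def test_single_class_equals_unconditioned(self):
        tf = self._tfr_with_meta(seed=1)
        tf.trial_meta["hemifield"] = "ipsi"
        with pytest.raises(ValueError, match="contra"):
            tfrmod.subset_average(tf, "hemifield")
        full = tfrmod.normalize_power(tf)
        by_corr = tfrmod.subset_average(tf, "correctness")
        n_corr = int(tf.trial_meta["correct"].sum())
        if n_corr == tf.n_trials:
            np.testing.assert_allclose(by_corr["correct"].z, full.z)

    def test_speed_split_at_5cms(self):
        tf = self._tfr_with_meta(seed=2)
        by_speed = tfrmod.subset_average(tf, "speed-class")
        speeds = tf.trial_meta["speed_cms"].abs()
        assert by_speed["slow"].n == int((speeds < 5.0).sum())
        assert by_speed["fast"].n == int((speeds > 5.0).sum())

    def test_identical_classes_do_not_diverge(self):
        # hemifield labels carry no generative difference: classes should
        # stay within 4 pooled SE essentially everywhere
        bad = 0
        total = 0
        for seed in range(8):
            tf = self._tfr_with_meta(seed=10 + seed, n_trials=60)
            by_h = tfrmod.subset_average(tf, "hemifield")
            iv = tfrmod.divergence_intervals(by_h["ipsi"], by_h["contra"], k=4.0)
            bad += sum(1 for _ in iv.intervals)
            total += 1
        assert bad <= 1  # >=95% of runs clean, small slack for 8 runs

    def test_contra_deeper_erd_separates_classes(self):
        tf = self._tfr_with_meta(seed=3, n_trials=120, contra_depth=0.9)
        by_h = tfrmod.subset_average(tf, "hemifield")
        ipsi, contra = by_h["ipsi"], by_h["contra"]
        window = (ipsi.times_ms > 700) & (ipsi.times_ms < 1500)
        se = np.sqrt(ipsi.dispersion**2 + contra.dispersion**2)
        assert np.all((ipsi.z - contra.z)[window] > 2 * se[window])

    def test_unknown_selector_rejected(self):
        tf = self._tfr_with_meta(seed=4)
        with pytest.raises(ValueError):
            tfrmod.subset_average(tf, "nonsense")
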