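"""Filtering, resampling, alignment, and outlier screening."""

import numpy as np
import pytest
from scipy import signal as sps

from ergolift.signal_prep import (
    Channel,
    PairedFrame,
    SignalPrepError,
    align_lag,
    butterworth_lowpass,
    pair_streams,
    resample_uniform,
    savgol_smooth,
    screen_outliers,
)
from ergolift.skeleton import JOINT_INDEX, JointName, SkeletonFrame

from conftest import make_sequence, pose_array


def _gain_oracle(cutoff, order, rate, freq):
    """Designed-filter frequency response magnitude at one frequency."""
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=rate)
    return abs(h[0])


def _steady_state_amplitude(values, rate, skip_s=5.0):
    tail = values[int(skip_s * rate):]
    return np.sqrt(2.0) * np.std(tail)


class TestResample:
    def test_constant_sequence_stays_constant(self):
        seq = make_sequence(50, rate=30.0)
        out = resample_uniform(seq, 25.0)
        np.testing.assert_allclose(out.data, np.tile(seq.data[0], (len(out), 1, 1)), atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self, rng):
        seq = make_sequence(60, rate=30.0)
        row = JOINT_INDEX[JointName.HEAD]
        seq.data[:, row, 0] = 0.2 + 0.05 * seq.times
        out = resample_uniform(seq, 47.0)
        np.testing.assert_allclose(out.data[:, row, 0], 0.2 + 0.05 * out.times, atol=1e-12)

    def test_jittered_timestamps_land_on_uniform_grid(self, rng):
        seq = make_sequence(90, rate=30.0)
        seq.times = np.cumsum(rng.uniform(1 / 32, 1 / 28, size=90))
        out = resample_uniform(seq, 30.0)
        np.testing.assert_allclose(np.diff(out.times), 1.0 / 30.0, atol=1e-12)

    def test_single_frame_raises(self):
        with pytest.raises(SignalPrepError):
            resample_uniform(make_sequence(1), 30.0)


class TestButterworth:
    def test_dc_passes_with_unity_gain(self):
        ch = Channel(values=np.full(300, 0.7), rate=30.0)
        out = butterworth_lowpass(ch, cutoff=7.0, order=4)
        np.testing.assert_allclose(out.values[30:], 0.7, atol=1e-6)

    @pytest.mark.parametrize(
        "freq,low,high", [(1.0, 0.99, 1.01), (14.0, 0.0, 0.1)]
    )
    def test_passband_and_stopband_gains(self, freq, low, high):
        rate, dur = 30.0, 30.0
        t = np.arange(int(rate * dur)) / rate
        ch = Channel(values=np.sin(2 * np.pi * freq * t), rate=rate)
        out = butterworth_lowpass(ch, cutoff=7.0, order=4)
        gain = _steady_state_amplitude(out.values, rate)
        oracle = _gain_oracle(7.0, 4, rate, freq)
        assert low <= gain <= high
        assert gain == pytest.approx(oracle, rel=0.01)

    def test_cutoff_at_nyquist_raises(self):
        with pytest.raises(SignalPrepError):
            butterworth_lowpass(Channel(np.ones(100), rate=30.0), cutoff=15.0)

    def test_linearity_constant_offset_commutes(self, rng):
        x = rng.normal(size=500)
        ch, shifted = Channel(x, 30.0), Channel(x + 3.0, 30.0)
        a = butterworth_lowpass(ch).values + 3.0
        b = butterworth_lowpass(shifted).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSavgol:
    def test_cubic_polynomial_reproduced_in_interior(self):
        t = np.linspace(-1, 1, 400)
        x = 0.5 - 1.2 * t + 0.8 * t**2 + 2.0 * t**3
        out = savgol_smooth(Channel(x, 30.0), degree=3, window=33)
        interior = slice(16, -16)
        np.testing.assert_allclose(out.values[interior], x[interior], atol=1e-9)

    def test_constant_preserved(self):
        out = savgol_smooth(Channel(np.full(100, 2.5), 30.0))
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_white_noise_variance_reduced_by_kernel_energy(self, rng):
        n = 100_000
        x = rng.normal(size=n)
        out = savgol_smooth(Channel(x, 30.0), degree=3, window=33)
        kernel = sps.savgol_coeffs(33, 3)
        expected_ratio = np.sum(kernel**2)
        ratio = np.var(out.values[33:-33]) / np.var(x)
        assert ratio == pytest.approx(expected_ratio, rel=0.05)

    @pytest.mark.parametrize("degree,window", [(3, 32), (5, 5)])
    def test_invalid_window_raises(self, degree, window):
        with pytest.raises(SignalPrepError):
            savgol_smooth(Channel(np.ones(100), 30.0), degree=degree, window=window)


def _wrist_z_sequence(z):
    return make_sequence(len(z), rate=30.0, wrist_z=np.asarray(z))


class TestAlign:
    def test_identical_sequences_have_zero_lag(self, rng):
        z = np.sin(2 * np.pi * 0.3 * np.arange(300) / 30.0)
        assert align_lag(_wrist_z_sequence(z), _wrist_z_sequence(z)) == 0

    def test_known_shift_recovered(self):
        t = np.arange(400) / 30.0
        z = np.sin(2 * np.pi * 0.25 * t) + 0.3 * np.sin(2 * np.pi * 0.6 * t)
        k = 10
        # noisy stream delayed: its sample i shows what the reference showed k frames ago
        noisy, reference = _wrist_z_sequence(z[:-k]), _wrist_z_sequence(z[k:])
        assert align_lag(noisy, reference) == k

    def test_antisymmetry(self, rng):
        t = np.arange(400) / 30.0
        z = np.cumsum(rng.normal(size=len(t))) / 10.0
        a, b = _wrist_z_sequence(z[:-7]), _wrist_z_sequence(z[7:])
        assert align_lag(a, b) == -align_lag(b, a)

    def test_zero_variance_signal_raises(self):
        flat = _wrist_z_sequence(np.ones(100))
        with pytest.raises(SignalPrepError):
            align_lag(flat, flat)

    def test_noisy_shift_recovery_rate(self):
        """Lag within +-1 frame in >= 95% of seeded 10%-noise trials."""
        hits = 0
        n_trials = 50
        for trial in range(n_trials):
            rng = np.random.default_rng(1000 + trial)
            t = np.arange(360) / 30.0
            z = np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 6)) + 0.4 * np.sin(
                2 * np.pi * 0.55 * t
            )
            k = int(rng.integers(1, 25))
            amp = np.ptp(z) / 2
            za = z[:-k] + rng.normal(0, 0.1 * amp, size=len(z) - k)
            zb = z[k:] + rng.normal(0, 0.1 * amp, size=len(z) - k)
            if abs(align_lag(_wrist_z_sequence(za), _wrist_z_sequence(zb)) - k) <= 1:
                hits += 1
        assert hits / n_trials >= 0.95


class TestScreenOutliers:
    def _pairs(self, k_data, q_data):
        return [
            PairedFrame(SkeletonFrame(i / 30.0, k), SkeletonFrame(i / 30.0, q))
            for i, (k, q) in enumerate(zip(k_data, q_data))
        ]

    def test_identical_pairs_all_kept(self):
        data = [pose_array() for _ in range(20)]
        kept, rejected, mask = screen_outliers(self._pairs(data, data))
        assert len(kept) == 20 and not rejected and mask.all()

    def test_single_displaced_joint_rejected(self):
        q = [pose_array() for _ in range(10)]
        k = [x.copy() for x in q]
        k[4][3, 2] += 1.0
        kept, rejected, mask = screen_outliers(self._pairs(k, q), threshold_m=0.30)
        assert len(rejected) == 1 and not mask[4] and mask.sum() == 9

    def test_injected_gross_outliers_fully_recalled(self, rng):
        n = 400
        q = np.tile(pose_array(), (n, 1, 1))
        k = q + rng.normal(0, 0.01, size=q.shape)  # inlier jitter
        outliers = rng.choice(n, size=int(0.05 * n), replace=False)
        for i in outliers:
            k[i, rng.integers(0, 20), :] += 0.5 + rng.random()
        kept, rejected, mask = screen_outliers(self._pairs(k, q), threshold_m=0.30)
        rejected_idx = set(np.nonzero(~mask)[0])
        assert set(outliers) <= rejected_idx  # 100% recall
        false_rejects = rejected_idx - set(outliers)
        assert len(false_rejects) / (n - len(outliers)) < 0.01


class TestPairing:
    def test_pair_streams_trims_to_overlap_and_matches_times(self):
        t = np.arange(200) / 30.0
        z = np.sin(2 * np.pi * 0.25 * t) + 0.4 * np.sin(2 * np.pi * 0.55 * t)
        k = 6
        noisy, reference = _wrist_z_sequence(z[:-k]), _wrist_z_sequence(z[k:])
        pairs = pair_streams(noisy, reference)
        assert len(pairs) == len(z) - 2 * k
        row = JOINT_INDEX[JointName.LEFT_WRIST]
        for p in pairs[:5]:
            assert p.k_frame.xyz[row, 2] == pytest.approx(p.q_frame.xyz[row, 2], abs=1e-12)
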