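import numpy as np
import pytest
from scipy.signal import hilbert

from scdhrv.features.timefreq import (
    SpwvdConfig,
    TfMap,
    _full_window,
    _half_window,
    spwvd,
    tf_band_features,
    tf_first_derivative,
    tf_window_features,
)
from scdhrv.qrs import UniformTachogram


def _tach(values, rate=4.0):
    return UniformTachogram(values=np.asarray(values, dtype=float), rate=rate, t0=0.0)


def brute_force_spwvd(x, h_len, g_len, n_freq, h_kind="hamming", g_kind="gaussian"):
    """Direct nested-loop evaluation of the smoothed lag-kernel transform."""
    xa = hilbert(np.asarray(x, dtype=float))
    L = xa.size
    h = _half_window(h_kind, h_len)
    g = _full_window(g_kind, g_len)
    gm = g_len - 1
    out = np.zeros((n_freq, L))
    for n in range(L):
        for m in range(n_freq):
            val = 0.0 + 0.0j
            for k in range(-(h_len - 1), h_len):
                acc = 0.0 + 0.0j
                for p in range(-gm, gm + 1):
                    i1, i2 = n + p + k, n + p - k
                    if 0 <= i1 < L and 0 <= i2 < L:
                        acc += g[p + gm] * xa[i1] * np.conj(xa[i2])
                val += h[abs(k)] * acc * np.exp(-2j * np.pi * k * m / n_freq)
            out[m, n] = val.real / n_freq
    return out


class TestSpwvd:
    def test_zero_signal_gives_zero_map(self):
        tf = spwvd(_tach(np.zeros(64)), SpwvdConfig(h_len=8, g_len=3, n_freq=32))
        assert np.allclose(tf.energy, 0.0)

    def test_fft_path_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 32)
        cfg = SpwvdConfig(h_len=8, g_len=3, n_freq=32)
        tf = spwvd(_tach(x), cfg)
        bf = brute_force_spwvd(x, 8, 3, 32)
        assert np.max(np.abs(tf.energy - bf)) <= 1e-9

    def test_delta_windows_reduce_to_raw_wigner_ville(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 32)
        cfg = SpwvdConfig(h_len=1, g_len=1, n_freq=16)
        tf = spwvd(_tach(x), cfg)
        bf = brute_force_spwvd(x, 1, 1, 16)
        assert np.max(np.abs(tf.energy - bf)) <= 1e-9

    def test_time_marginal_without_smoothing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 64)
        tf = spwvd(_tach(x), SpwvdConfig(h_len=1, g_len=1, n_freq=32))
        xa = hilbert(x)
        marginal = tf.energy.sum(axis=0)
        interior = slice(4, 60)
        assert np.allclose(
            marginal[interior], np.abs(xa[interior]) ** 2, rtol=0.05
        )

    def test_tone_ridge_at_modulation_frequency(self):
        t = np.arange(256) / 4.0
        tf = spwvd(_tach(np.sin(2 * np.pi * 0.1 * t)))
        interior = slice(32, 224)
        ridge = tf.freqs[np.argmax(tf.energy[:, interior], axis=0)]
        df = tf.freqs[1] - tf.freqs[0]
        assert np.all(np.abs(ridge - 0.1) <= df + 1e-12)

    def test_energy_stable_under_one_sample_shift(self):
        t = np.arange(256) / 4.0
        x = np.sin(2 * np.pi * 0.1 * t)
        e1 = spwvd(_tach(x)).rectified.sum()
        e2 = spwvd(_tach(np.roll(x, 1))).rectified.sum()
        assert e2 == pytest.approx(e1, rel=0.02)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            spwvd(_tach(np.zeros(16)), SpwvdConfig(h_len=20, g_len=1, n_freq=64))


class TestWindowFeatures:
    def _map(self, energies_per_block, n_times_per_block=10):
        energy = np.repeat(
            np.asarray(energies_per_block, dtype=float)[None, :],
            4,
            axis=0,
        )
        energy = np.repeat(energy, n_times_per_block, axis=1)
        nt = energy.shape[1]
        return TfMap(
            times=np.arange(nt) / 4.0, freqs=np.linspace(0, 2, 4), energy=energy
        )

    def test_uniform_map_has_zero_spread(self):
        wf = tf_window_features(self._map([2.0] * 5))
        assert wf.dif_w == 0.0 and wf.std_w == 0.0

    def test_hand_computed_example(self):
        wf = tf_window_features(self._map([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert wf.max_w == 5.0 and wf.min_w == 1.0 and wf.dif_w == 4.0
        assert wf.std_w == pytest.approx(1.5811, abs=1e-4)

    def test_last_block_absorbs_remainder(self):
        energy = np.ones((4, 53))
        tfmap = TfMap(
            times=np.arange(53) / 4.0, freqs=np.linspace(0, 2, 4), energy=energy
        )
        wf = tf_window_features(tfmap, n_segments=5)
        assert wf.energies.size == 5

    def test_too_few_columns_rejected(self):
        tfmap = TfMap(
            times=np.arange(3), freqs=np.linspace(0, 2, 4), energy=np.ones((4, 3))
        )
        with pytest.raises(ValueError):
            tf_window_features(tfmap, n_segments=5)


class TestBandFeatures:
    def test_zero_map_all_zero(self):
        tfmap = TfMap(
            times=np.arange(20) / 4.0,
            freqs=np.linspace(0, 2, 64),
            energy=np.zeros((64, 20)),
        )
        feats = tf_band_features(tfmap)
        assert all(v == 0.0 for v in feats.values())

    def test_hf_tone_energy_ratio(self):
        t = np.arange(256) / 4.0
        feats = tf_band_features(spwvd(_tach(np.sin(2 * np.pi * 0.25 * t))))
        assert feats["e_hf"] >= 10 * feats["e_lf"]

    def test_e_f_algebraic_identity(self):
        rng = np.random.default_rng(3)
        tf = spwvd(_tach(rng.normal(0, 1, 128)), SpwvdConfig(h_len=8, g_len=3, n_freq=64))
        feats = tf_band_features(tf)
        n_times = tf.energy.shape[1]
        for name, (lo, hi) in (("vlf", (0.003, 0.04)), ("lf", (0.04, 0.15)), ("hf", (0.15, 0.4))):
            n_rows = np.count_nonzero((tf.freqs >= lo) & (tf.freqs < hi))
            expected = feats[f"f_{name}"] * n_rows * n_times / (hi - lo)
            assert feats[f"e_{name}"] == pytest.approx(expected, rel=1e-12)


class TestFirstDerivative:
    def test_constant_energies_zero(self):
        assert tf_first_derivative([2.0] * 5, prev_interval_last_energy=2.0) == 0.0

    def test_hand_computed_example(self):
        # d = [1, 2, 3, 4, 5] -> mean |d| = 3
        assert tf_first_derivative(
            [1.0, 3.0, 6.0, 10.0, 15.0], prev_interval_last_energy=0.0
        ) == pytest.approx(3.0)

    def test_missing_context_uses_remaining_differences(self):
        # d = [2, 3, 4, 5] without the cross-interval term
        assert tf_first_derivative([1.0, 3.0, 6.0, 10.0, 15.0]) == pytest.approx(3.5)

    def test_strategies(self):
        e = [1.0, 3.0, 6.0, 10.0, 15.0]
        assert tf_first_derivative(e, 0.0, strategy="max_abs") == 5.0
        assert tf_first_derivative(e, 0.0, strategy="sum_abs") == 15.0
        with pytest.raises(ValueError):
            tf_first_derivative(e, 0.0, strategy="bogus")
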