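import numpy as np
import pytest

from ptrburst.hmm import TdeHmmModel
from ptrburst.metrics import (
    BANDS,
    DEFAULT_FREQS,
    StateSpectrum,
    band_power,
    burst_coincidence,
    multitaper_psd,
    reconstruct_tfr,
    state_psd,
    state_psd_from_model,
    summarize_region,
)


def tone(freq, fs, dur, rng=None):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    if rng is not None:
        x = x + 0.1 * rng.standard_normal(t.size)
    return x


class TestStatePsd:
    def test_pure_tone_peaks_at_carrier(self):
        fs = 100.0
        x = tone(10.0, fs, 20.0)
        onoff = np.ones(x.size, dtype=np.uint8)
        spec = state_psd(x, onoff, fs)
        assert abs(spec.peak_freq - 10.0) <= 0.5

    def test_white_noise_spectrum_flat_within_3db(self):
        rng = np.random.default_rng(0)
        fs = 100.0
        x = rng.standard_normal(int(120 * fs))
        spec = state_psd(x, np.ones(x.size, dtype=np.uint8), fs)
        sel = (spec.freqs >= 3) & (spec.freqs <= 45)
        ratio = spec.psd[sel].max() / spec.psd[sel].min()
        assert ratio < 10 ** (3 / 10) * 1.5  # taper variance allowance

    def test_zero_signal_gives_zero_psd(self):
        fs = 100.0
        spec = state_psd(np.zeros(1000), np.ones(1000, dtype=np.uint8), fs)
        assert np.allclose(spec.psd, 0.0)

    def test_insufficient_on_time_flagged_missing(self):
        fs = 100.0
        onoff = np.zeros(1000, dtype=np.uint8)
        onoff[:50] = 1  # 0.5 s < 2 s minimum
        assert state_psd(np.random.default_rng(1).standard_normal(1000), onoff, fs) is None

    def test_short_bursty_segments_resolve_carrier(self):
        # 300 ms on-segments of a 10 Hz tone against silence
        fs = 100.0
        rng = np.random.default_rng(2)
        x = 0.3 * rng.standard_normal(int(60 * fs))
        onoff = np.zeros(x.size, dtype=np.uint8)
        for start in range(0, x.size - 30, 200):
            t = np.arange(30) / fs
            x[start: start + 30] += 3 * np.sin(2 * np.pi * 10.0 * t)
            onoff[start: start + 30] = 1
        spec = state_psd(x, onoff, fs)
        assert abs(spec.peak_freq - 10.0) <= 1.0

    def test_agrees_with_mne_multitaper(self):
        mne_tf = pytest.importorskip("mne.time_frequency")
        fs = 100.0
        rng = np.random.default_rng(3)
        x = tone(10.0, fs, 2.0, rng)
        mine = multitaper_psd(x, fs, nw=4.0)
        psd_ref, freqs_ref = mne_tf.psd_array_multitaper(
            x[None, :], fs, bandwidth=2 * 4.0 * fs / x.size, adaptive=False,
            low_bias=False, normalization="full", verbose="error",
        )
        ref = np.interp(DEFAULT_FREQS, freqs_ref, psd_ref[0])
        r = np.corrcoef(mine, ref)[0, 1]
        assert r > 0.95
        assert abs(np.trapezoid(mine, DEFAULT_FREQS)
                   / np.trapezoid(ref, DEFAULT_FREQS) - 1) < 0.1


class TestModelPsd:
    def test_cosine_autocovariance_peaks_at_carrier(self):
        fs = 100.0
        d = 23
        lags = np.arange(d)
        r = np.cos(2 * np.pi * 10.0 * lags / fs)
        cov = np.array([[r[abs(i - j)] for j in range(d)] for i in range(d)])
        cov += 0.5 * np.eye(d)
        model = TdeHmmModel(
            K=1, transition=np.ones((1, 1)), initial=np.ones(1),
            covariances=cov[None],
        )
        spec = state_psd_from_model(model, 0, fs)
        assert abs(spec.peak_freq - 10.0) <= 1.5


class TestBandPower:
    def test_flat_unit_psd_band_widths(self):
        freqs = np.arange(1.0, 46.0)
        spec = StateSpectrum(freqs=freqs, psd=np.ones_like(freqs), peak_freq=10.0)
        bp = band_power(spec)
        assert bp.theta == pytest.approx(4.0)
        assert bp.alpha == pytest.approx(5.0)
        assert bp.beta == pytest.approx(17.0)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        psd = rng.random(DEFAULT_FREQS.size)
        s1 = StateSpectrum(DEFAULT_FREQS, psd, 10.0)
        s2 = StateSpectrum(DEFAULT_FREQS, 2 * psd, 10.0)
        b1, b2 = band_power(s1), band_power(s2)
        assert b2.theta == pytest.approx(2 * b1.theta)
        assert b2.alpha == pytest.approx(2 * b1.alpha)
        assert b2.beta == pytest.approx(2 * b1.beta)

    def test_alpha_tone_concentrates_in_alpha(self):
        fs = 100.0
        spec = state_psd(tone(10.0, fs, 30.0), np.ones(3000, dtype=np.uint8), fs)
        bp = band_power(spec)
        assert bp.alpha > 5 * bp.theta
        assert bp.alpha > 5 * bp.beta

    def test_band_sums_bounded_by_total_area(self):
        rng = np.random.default_rng(5)
        psd = rng.random(DEFAULT_FREQS.size)
        bp = band_power(StateSpectrum(DEFAULT_FREQS, psd, 10.0))
        sel = (DEFAULT_FREQS >= 3) & (DEFAULT_FREQS <= 45)
        total = np.trapezoid(psd[sel], DEFAULT_FREQS[sel])
        assert bp.theta + bp.alpha + bp.beta <= total + 1e-9

    def test_grid_not_covering_band_rejected(self):
        freqs = np.arange(10.0, 46.0)
        with pytest.raises(ValueError):
            band_power(StateSpectrum(freqs, np.ones_like(freqs), 10.0))


class TestSummaries:
    def _spec(self, peak):
        return StateSpectrum(DEFAULT_FREQS, np.ones_like(DEFAULT_FREQS), peak)

    def test_constant_durations(self):
        import pandas as pd

        bursts = pd.DataFrame(
            {
                "region": ["r"] * 3,
                "state": [0] * 3,
                "onset_s": [0.0, 1.0, 2.0],
                "offset_s": [0.3, 1.3, 2.3],
                "duration_s": [0.3, 0.3, 0.3],
                "participant": ["p0"] * 3,
            }
        )
        s = summarize_region(bursts, self._spec(10.0))
        assert s.mean_duration == pytest.approx(0.3)
        assert s.se_duration == pytest.approx(0.0)
        assert s.cycles_per_burst == pytest.approx(3.0)

    def test_burst_rate_from_window_budget(self):
        import pandas as pd

        n = 56
        bursts = pd.DataFrame(
            {
                "region": ["r"] * n,
                "state": [0] * n,
                "onset_s": np.arange(n, dtype=float),
                "offset_s": np.arange(n) + 0.3,
                "duration_s": [0.3] * n,
                "participant": ["p0"] * n,
            }
        )
        windows = pd.Series(["ptr"] * n, index=bursts.index)
        s = summarize_region(
            bursts, self._spec(10.0), window_durations={"ptr": 112.0},
            window_of_burst=windows,
        )
        assert s.burst_rate["ptr"] == pytest.approx(0.5)

    def test_empty_burst_table_flagged_missing(self):
        import pandas as pd

        empty = pd.DataFrame(
            columns=["region", "state", "onset_s", "offset_s", "duration_s", "participant"]
        )
        assert summarize_region(empty, self._spec(10.0)) is None


class TestReconstructTfr:
    def test_always_on_state_reproduces_psd(self):
        psd = np.linspace(1, 2, DEFAULT_FREQS.size)
        spec = StateSpectrum(DEFAULT_FREQS, psd, 10.0)
        evo = np.ones((1, 50))
        tfr = reconstruct_tfr(evo, [spec], 100.0)
        assert np.allclose(tfr.total, psd[:, None])

    def test_zero_probability_gives_zero_tfr(self):
        spec = StateSpectrum(DEFAULT_FREQS, np.ones_like(DEFAULT_FREQS), 10.0)
        tfr = reconstruct_tfr(np.zeros((1, 50)), [spec], 100.0)
        assert np.allclose(tfr.total, 0.0)

    def test_bilinearity(self):
        rng = np.random.default_rng(6)
        psd = rng.random(DEFAULT_FREQS.size)
        prob = rng.random(40)
        base = reconstruct_tfr(
            prob[None], [StateSpectrum(DEFAULT_FREQS, psd, 10.0)], 100.0
        ).total
        double_psd = reconstruct_tfr(
            prob[None], [StateSpectrum(DEFAULT_FREQS, 2 * psd, 10.0)], 100.0
        ).total
        double_prob = reconstruct_tfr(
            2 * prob[None], [StateSpectrum(DEFAULT_FREQS, psd, 10.0)], 100.0
        ).total
        assert np.allclose(double_psd, 2 * base)
        assert np.allclose(double_prob, 2 * base)

    def test_mismatched_state_count_rejected(self):
        spec = StateSpectrum(DEFAULT_FREQS, np.ones_like(DEFAULT_FREQS), 10.0)
        with pytest.raises(ValueError):
            reconstruct_tfr(np.ones((2, 10)), [spec], 100.0)


class TestCoincidence:
    def test_identical_rows_score_one(self):
        row = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        assert burst_coincidence(row, row) == 1.0

    def test_disjoint_rows_score_zero(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert burst_coincidence(a, b) == 0.0

    def test_shift_beyond_burst_duration_kills_overlap(self):
        a = np.zeros(100, dtype=np.uint8)
        a[10:15] = 1
        a[50:55] = 1
        b = np.roll(a, 7)
        assert burst_coincidence(a, b) == 0.0

    def test_empty_window_rejected(self):
        a = np.ones(10, dtype=np.uint8)
        with pytest.raises(ValueError):
            burst_coincidence(a, a, window=slice(5, 5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            burst_coincidence(np.ones(5), np.ones(6))
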