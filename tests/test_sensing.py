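"""Band-power extraction and feature ranking against independent oracles."""

import numpy as np
import pytest

from cldbs.sensing import (
    Band,
    SenseConfig,
    FeatureStream,
    compute_band_power,
    rank_features,
    select_window,
)
from cldbs.synthetic import BiomarkerSpec, LFPRecording, generate_lfp

from conftest import THETA, BETA, make_trace


def sine_recording(freq, fs=250.0, duration=20.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return LFPRecording(fs, ["ch1"], amplitude * np.sin(2 * np.pi * freq * t))


class TestComputeBandPower:
    def test_sinusoid_concentrates_in_its_band(self):
        rec = sine_recording(6.0)
        cfg = SenseConfig(window_length=256, update_interval=0.5,
                          bands=[THETA, BETA])
        stream = compute_band_power(rec, cfg)
        theta = stream.column("ch1:theta")
        beta = stream.column("ch1:beta")
        assert np.all(theta > 100 * beta)

    def test_matches_independent_dft_periodogram(self):
        # hand-rolled DFT with 'spectrum' scaling as the oracle
        rng = np.random.default_rng(7)
        fs, n = 250.0, 256
        x = rng.normal(0, 1, n)
        rec = LFPRecording(fs, ["ch1"], x)
        cfg = SenseConfig(window_length=n, update_interval=n / fs,
                          bands=[THETA], window="boxcar")
        stream = compute_band_power(rec, cfg)

        k = np.arange(n)
        freqs = np.arange(n // 2 + 1) * fs / n
        dft = np.array(
            [np.sum(x * np.exp(-2j * np.pi * m * k / n)) for m in range(n // 2 + 1)]
        )
        pxx = np.abs(dft) ** 2 / n**2
        pxx[1:-1] *= 2  # one-sided
        mask = (freqs >= 4.0) & (freqs < 8.0)
        expected = pxx[mask].mean()
        assert stream.values[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_parseval_partition_recovers_time_domain_power(self):
        rng = np.random.default_rng(8)
        fs, n = 250.0, 512
        x = rng.normal(0, 1, n)
        rec = LFPRecording(fs, ["ch1"], x)
        df = fs / n
        bands = [
            Band(label=f"b{i}", low=max(i * 25.0, df / 2), high=(i + 1) * 25.0)
            for i in range(5)
        ]
        cfg = SenseConfig(window_length=n, update_interval=n / fs, bands=bands,
                          window="boxcar")
        stream = compute_band_power(rec, cfg)
        from cldbs.sensing import band_bin_counts

        total = float(stream.values[0] @ band_bin_counts(fs, cfg))
        # partition excludes the DC and Nyquist bins
        freqs = np.fft.rfftfreq(n, 1 / fs)
        full = np.mean(x**2) - np.mean(x) ** 2
        nyq_power = np.abs(np.fft.rfft(x)[-1]) ** 2 / n**2
        assert total == pytest.approx(full - nyq_power, rel=1e-9)

    def test_orthogonal_band_content_leaves_theta_power(self):
        rng = np.random.default_rng(9)
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        base = rng.normal(0, 1, len(t))
        rec_a = LFPRecording(fs, ["ch1"], base)
        rec_b = LFPRecording(fs, ["ch1"], base + 5 * np.sin(2 * np.pi * 40 * t))
        cfg = SenseConfig(window_length=256, update_interval=1.0, bands=[THETA])
        pa = compute_band_power(rec_a, cfg).values[:, 0]
        pb = compute_band_power(rec_b, cfg).values[:, 0]
        assert np.abs(pb.mean() / pa.mean() - 1) < 0.01

    def test_recording_too_short_rejected(self):
        rec = LFPRecording(250.0, ["ch1"], np.zeros(100))
        with pytest.raises(ValueError, match="shorter"):
            compute_band_power(rec, SenseConfig(window_length=256))

    def test_band_above_nyquist_rejected(self):
        rec = sine_recording(6.0)
        cfg = SenseConfig(
            window_length=256, bands=[Band(label="hf", low=100, high=140)]
        )
        with pytest.raises(ValueError, match="Nyquist"):
            compute_band_power(rec, cfg)

    def test_update_times_uniform(self):
        rec = sine_recording(6.0, duration=30.0)
        cfg = SenseConfig(window_length=256, update_interval=0.5, bands=[THETA])
        stream = compute_band_power(rec, cfg)
        assert np.allclose(np.diff(stream.times), 0.5)


class TestRankFeatures:
    def _stream_from_columns(self, times, cols, names):
        cfg = SenseConfig(bands=[THETA])
        return FeatureStream(times, np.column_stack(cols), names, cfg,
                             {f"ch{i+1}": i for i in range(len(names))},
                             normalized=False)

    def test_self_correlation_is_one(self, block_trace):
        times = np.arange(0.0, 600.0, 0.5)
        score = block_trace.score_at(times)
        cfg = SenseConfig(bands=[THETA])
        stream = FeatureStream(times, score[:, None], ["ch1:theta"], cfg,
                               {"ch1": 0})
        ranking = rank_features(stream, block_trace)
        assert ranking.table.iloc[0]["correlation"] == pytest.approx(1.0)

    def test_independent_feature_below_permutation_bound(self, block_trace):
        rng = np.random.default_rng(10)
        times = np.arange(0.0, 600.0, 0.5)
        noise = rng.random(len(times))
        cfg = SenseConfig(bands=[THETA])
        stream = FeatureStream(times, noise[:, None], ["ch1:theta"], cfg,
                               {"ch1": 0})
        ranking = rank_features(stream, block_trace)
        obs = ranking.table.iloc[0]["importance"]
        score = block_trace.score_at(times)
        null = []
        for _ in range(200):
            perm = rng.permutation(noise)
            null.append(abs(np.corrcoef(perm, score)[0, 1]))
        assert obs < np.quantile(null, 0.95) * 2  # same order as the null
        assert obs < 0.1

    def test_synthetic_biomarker_ranks_first_among_channels_and_bands(self):
        trace = make_trace(np.r_[np.full(300, 3.0), np.full(300, 7.0)])
        bm = BiomarkerSpec(channel=2, band=(4, 8), power_low=1.0, power_high=6.0)
        rec = generate_lfp(trace, [bm], fs=250, seed=12, n_channels=4,
                           background_rms=0.5)
        cfg = SenseConfig(window_length=256, update_interval=1.0)  # 5 bands
        stream = compute_band_power(rec, cfg)
        ranking = rank_features(stream, trace)
        assert ranking.top == "ch3:theta"

    def test_zero_variance_feature_flagged_with_zero_importance(self, block_trace):
        times = np.arange(0.0, 600.0, 0.5)
        cfg = SenseConfig(bands=[THETA])
        stream = FeatureStream(times, np.ones((len(times), 1)), ["ch1:theta"],
                               cfg, {"ch1": 0})
        ranking = rank_features(stream, block_trace)
        assert ranking.degenerate == ["ch1:theta"]
        assert ranking.table.iloc[0]["importance"] == 0.0

    def test_rank_mode_invariant_to_monotone_score_rescaling(self, block_trace):
        rng = np.random.default_rng(13)
        times = np.arange(0.0, 600.0, 0.5)
        feat = block_trace.score_at(times) + rng.normal(0, 1, len(times)) + 10
        cfg = SenseConfig(bands=[THETA])
        stream = FeatureStream(times, feat[:, None], ["ch1:theta"], cfg,
                               {"ch1": 0})
        r1 = rank_features(stream, block_trace, method="spearman")
        warped = make_trace(block_trace.score**3 / 100.0,
                            cutoff=block_trace.cutoff**3 / 100.0)
        r2 = rank_features(stream, warped, method="spearman")
        assert r1.table.iloc[0]["correlation"] == pytest.approx(
            r2.table.iloc[0]["correlation"]
        )


class TestSelectWindow:
    def test_single_candidate_returned(self, theta_recording, block_trace,
                                       theta_sense_cfg):
        chosen, report = select_window(
            theta_recording, block_trace, [256], theta_sense_cfg
        )
        assert chosen == 256
        assert len(report) == 1

    def test_fine_resolution_window_beats_coarse(self, block_trace):
        bm = BiomarkerSpec(channel=0, band=(4, 8), power_low=1.0, power_high=4.0)
        rec = generate_lfp(block_trace, [bm], fs=250, seed=14, background_rms=1.0)
        cfg = SenseConfig(window_length=256, update_interval=1.0, bands=[THETA])
        chosen, report = select_window(rec, block_trace, [32, 256], cfg)
        assert chosen == 256

    def test_smaller_window_wins_when_within_fraction(self, theta_recording,
                                                      block_trace,
                                                      theta_sense_cfg):
        # fraction 0 accepts anything, so the smallest candidate must win
        chosen, _ = select_window(
            theta_recording, block_trace, [512, 128], theta_sense_cfg,
            fraction=0.0,
        )
        assert chosen == 128

    def test_all_degenerate_raises(self, block_trace):
        rec = LFPRecording(250.0, ["ch1"], np.ones(150000))
        cfg = SenseConfig(window_length=256, update_interval=1.0, bands=[THETA])
        with pytest.raises(ValueError, match="degenerate"):
            select_window(rec, block_trace, [128, 256], cfg)
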