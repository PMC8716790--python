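"""Normalization, Fisher weight fitting, and LD streaming semantics."""

import numpy as np
import pytest

from cldbs.discriminant import (
    LDComputer,
    LDConfig,
    fit_lda,
    ld_output,
    normalize,
)
from cldbs.sensing import FeatureStream, SenseConfig

from conftest import THETA


def make_stream(values, names=None):
    values = np.atleast_2d(values)
    if values.shape[0] < values.shape[1]:
        values = values.T
    names = names or [f"ch1:f{i}" for i in range(values.shape[1])]
    cfg = SenseConfig(bands=[THETA])
    times = np.arange(values.shape[0]) * 0.5
    return FeatureStream(times, values, names, cfg, {}, normalized=True)


class TestNormalize:
    def test_fit_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        stream = make_stream(rng.gamma(2.0, 3.0, (500, 2)))
        out, (means, sds) = normalize(stream, "fit")
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(out.values.std(axis=0, ddof=1) - 1) < 1e-10)

    def test_identity_stats_are_identity(self):
        rng = np.random.default_rng(1)
        stream = make_stream(rng.normal(5, 2, (100, 1)))
        out, _ = normalize(stream, (np.array([0.0]), np.array([1.0])))
        assert np.array_equal(out.values, stream.values)

    def test_zero_variance_feature_rejected(self):
        stream = make_stream(np.ones((100, 1)))
        with pytest.raises(ValueError, match="zero-variance"):
            normalize(stream, "fit")


class TestFitLda:
    def test_separation_along_first_feature_only(self):
        rng = np.random.default_rng(2)
        n = 5000
        z0 = rng.normal([0, 0], 1, (n, 2))
        z1 = rng.normal([2, 0], 1, (n, 2))
        w = fit_lda(np.vstack([z0, z1]), np.r_[np.zeros(n), np.ones(n)])
        assert abs(w[1]) < 0.05
        assert w[0] > 0  # class-1 LD mean higher

    def test_recovers_generating_direction(self):
        rng = np.random.default_rng(3)
        n = 10000
        d = np.array([0.6, -0.8])
        z0 = rng.normal(0, 1, (n, 2))
        z1 = rng.normal(0, 1, (n, 2)) + 1.5 * d
        w = fit_lda(np.vstack([z0, z1]), np.r_[np.zeros(n), np.ones(n)])
        cos = abs(w @ d) / np.linalg.norm(d)
        assert cos > 0.99

    def test_matches_sklearn_direction(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(4)
        n = 2000
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        L = np.linalg.cholesky(cov)
        z0 = rng.normal(0, 1, (n, 2)) @ L.T
        z1 = rng.normal(0, 1, (n, 2)) @ L.T + [1.0, 0.5]
        X = np.vstack([z0, z1])
        y = np.r_[np.zeros(n), np.ones(n)]
        w = fit_lda(X, y)
        ref = LinearDiscriminantAnalysis().fit(X, y).coef_.ravel()
        ref = ref / np.linalg.norm(ref)
        assert abs(w @ ref) > 0.9999

    def test_identical_class_means_raise(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, (200, 2))
        y = np.r_[np.zeros(100), np.ones(100)]
        z[y == 1] = z[y == 0]  # same points in both classes
        with pytest.raises(ValueError, match="identical class means"):
            fit_lda(z, y)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_lda(np.random.default_rng(0).normal(0, 1, (50, 2)), np.zeros(50))

    def test_collinear_features_raise(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 200)
        z = np.column_stack([a, 2 * a])
        y = np.r_[np.zeros(100), np.ones(100)]
        z[y == 1] += [1.0, 2.0]
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(z, y)

    def test_training_accuracy_beats_single_feature_rules(self):
        # Fisher optimality among linear rules, via brute-force threshold sweep
        rng = np.random.default_rng(7)
        n = 200
        d = np.array([1.0, 1.0]) / np.sqrt(2)
        z0 = rng.normal(0, 1, (n, 2))
        z1 = rng.normal(0, 1, (n, 2)) + 1.8 * d
        X = np.vstack([z0, z1])
        y = np.r_[np.zeros(n), np.ones(n)]
        w = fit_lda(X, y)

        def best_threshold_accuracy(values):
            accs = []
            for thr in np.unique(values):
                pred = (values >= thr).astype(int)
                accs.append(max(np.mean(pred == y), np.mean((1 - pred) == y)))
            return max(accs)

        ld_acc = best_threshold_accuracy(X @ w)
        for j in range(2):
            assert ld_acc >= best_threshold_accuracy(X[:, j]) - 1e-12


class TestLdOutput:
    def test_axis_projection(self):
        rng = np.random.default_rng(8)
        stream = make_stream(rng.gamma(2, 1, (300, 2)),
                             ["ch1:theta", "ch1:beta"])
        norm, (m, s) = normalize(stream, "fit")
        cfg = LDConfig(
            features=["ch1:theta", "ch1:beta"], weights=[1.0, 0.0],
            norm_mean=list(m), norm_sd=list(s), thresholds=[0.0],
        )
        ld = ld_output(stream, cfg)
        assert np.allclose(ld.ld, norm.values[:, 0])

    def test_averaging_reduces_variance_like_one_over_L(self):
        rng = np.random.default_rng(9)
        x = rng.normal(10, 1, (20000, 1))
        stream = make_stream(x, ["ch1:theta"])
        base = dict(features=["ch1:theta"], weights=[1.0], norm_mean=[10.0],
                    norm_sd=[1.0], thresholds=[0.0])
        v1 = ld_output(stream, LDConfig(**base, avg_len=1)).ld.var()
        v8 = ld_output(stream, LDConfig(**base, avg_len=8)).ld.var()
        assert v8 / v1 == pytest.approx(1 / 8, rel=0.15)

    def test_negative_weight_stim_feature_lowers_ld(self):
        rng = np.random.default_rng(10)
        theta = rng.gamma(2, 1, 500)
        stim_power = np.full(500, 8.0)  # stimulation on: high stim-band power
        stream = make_stream(np.column_stack([theta, stim_power]),
                             ["ch1:theta", "ch1:stim"])
        base = dict(norm_mean=[2.0, 0.5], norm_sd=[1.0, 0.5],
                    thresholds=[0.0])
        with_neg = LDConfig(features=["ch1:theta", "ch1:stim"],
                            weights=[0.8, -0.6], **base)
        without = LDConfig(features=["ch1:theta", "ch1:stim"],
                           weights=[0.8, 0.0], **base)
        ld_neg = ld_output(stream, with_neg).ld
        ld_ref = ld_output(stream, without).ld
        assert np.all(ld_neg < ld_ref)

    def test_missing_feature_raises(self):
        stream = make_stream(np.ones((100, 1)) * 2, ["ch1:theta"])
        cfg = LDConfig(features=["ch9:gamma"], weights=[1.0], norm_mean=[0.0],
                       norm_sd=[1.0], thresholds=[0.0])
        with pytest.raises(KeyError):
            ld_output(stream, cfg)

    def test_affine_equivariance_under_feature_rescaling(self):
        rng = np.random.default_rng(11)
        x = rng.gamma(2, 1, (400, 1))
        for c in (3.0, 0.2):
            s1 = make_stream(x, ["ch1:theta"])
            s2 = make_stream(c * x, ["ch1:theta"])
            out = []
            for s in (s1, s2):
                _, (m, sd) = normalize(s, "fit")
                cfg = LDConfig(features=["ch1:theta"], weights=[1.0],
                               norm_mean=list(m), norm_sd=list(sd),
                               thresholds=[0.0], avg_len=3)
                out.append(ld_output(s, cfg).ld)
            assert np.allclose(out[0], out[1], atol=1e-9)

    def test_streaming_equals_batch_bitwise(self):
        rng = np.random.default_rng(12)
        x = rng.gamma(2, 1, (500, 2))
        stream = make_stream(x, ["ch1:theta", "ch1:beta"])
        cfg = LDConfig(features=["ch1:theta", "ch1:beta"], weights=[0.7, -0.3],
                       norm_mean=[2.0, 2.0], norm_sd=[1.5, 1.5],
                       thresholds=[0.0], avg_len=5)
        batch = ld_output(stream, cfg).ld
        comp = LDComputer(cfg)
        streamed = np.array([comp.step(row) for row in x])
        assert np.array_equal(batch, streamed)

    def test_more_than_two_features_rejected(self):
        with pytest.raises(ValueError, match="1..2 features"):
            LDConfig(features=["a", "b", "c"], weights=[1, 1, 1],
                     norm_mean=[0, 0, 0], norm_sd=[1, 1, 1], thresholds=[0.0])
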