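"""The embedded linear-discriminant classifier.

Sense-enabled DBS implants project one or two band-power features through a
linear discriminant (LD): each feature is z-scored against stored
normalization constants, multiplied by a signed weight, summed, and the
result smoothed by a trailing moving average before threshold comparison.
This module provides normalization fitting, Fisher-discriminant weight
fitting from labeled feature data, and both batch and streaming LD output
computation (the two are bit-identical).

The device accepts at most two input features; a negatively weighted second
feature that tracks stimulation-band power is the standard trick for pulling
the LD back below threshold when stimulation artifact inflates the biomarker.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .sensing import FeatureStream

__all__ = [
    "LDConfig",
    "LDStream",
    "normalize",
    "fit_lda",
    "ld_output",
    "LDComputer",
]

MAX_FEATURES = 2  # device-faithful limit on LD inputs


class LDConfig(BaseModel):
    """Everything the device needs to turn features into a thresholded LD.

    Attributes
    ----------
    features : feature names (1 or 2), matching FeatureStream columns.
    weights : signed, unitless; scaled to unit norm by :func:`fit_lda`.
    norm_mean, norm_sd : per-feature normalization constants (defaults give
        each z-scored feature mean 0 and standard deviation 1).
    thresholds : 1 or 2 LD values, ascending; one threshold yields 2 device
        states, two yield 3.
    avg_len : number of FFT updates in the trailing moving average applied
        to the LD before threshold comparison.
    """

    model_config = ConfigDict(extra="forbid")

    features: list[str]
    weights: list[float]
    norm_mean: list[float]
    norm_sd: list[float]
    thresholds: list[float]
    avg_len: int = 1

    @model_validator(mode="after")
    def _check(self) -> "LDConfig":
        k = len(self.features)
        if not 1 <= k <= MAX_FEATURES:
            raise ValueError(f"device supports 1..{MAX_FEATURES} features, got {k}")
        if not (len(self.weights) == len(self.norm_mean) == len(self.norm_sd) == k):
            raise ValueError("weights/norm_mean/norm_sd must match features")
        if not any(w != 0 for w in self.weights):
            raise ValueError("at least one weight must be nonzero")
        if any(sd <= 0 for sd in self.norm_sd):
            raise ValueError("normalization sds must be positive")
        if not 1 <= len(self.thresholds) <= 2:
            raise ValueError("1 or 2 thresholds required")
        if len(self.thresholds) == 2 and not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly ascending")
        if self.avg_len < 1:
            raise ValueError("avg_len must be >= 1")
        return self


@dataclass
class LDStream:
    """LD values on the FFT update clock, with normalized feature vectors."""

    times: np.ndarray
    ld: np.ndarray
    z: np.ndarray  # (n_updates, n_features) normalized features

    def __len__(self) -> int:
        return len(self.times)


def normalize(
    stream: FeatureStream,
    stats: tuple[np.ndarray, np.ndarray] | str = "fit",
) -> tuple[FeatureStream, tuple[np.ndarray, np.ndarray]]:
    """Z-score a feature stream.

    With ``stats="fit"``, per-feature sample mean and sd (ddof=1) are fitted
    from the stream so each output column has mean 0 and sd 1 — the device
    default normalization.  Alternatively supply ``(means, sds)`` to apply
    stored constants.
    """
    x = stream.values
    if stats == "fit":
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [stream.names[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"zero-variance feature(s) cannot be fit: {bad}")
    else:
        means, sds = (np.asarray(a, float) for a in stats)
        if np.any(sds <= 0):
            raise ValueError("supplied sds must be positive")
    z = (x - means) / sds
    out = FeatureStream(
        stream.times, z, stream.names, stream.config, stream.channel_index,
        normalized=True,
    )
    return out, (means, sds)


def fit_lda(z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher-discriminant weights from normalized features and binary labels.

    Returns w proportional to S_w^{-1} (mu_1 - mu_0) where S_w is the pooled
    within-class covariance, scaled to unit norm, with the sign fixed so the
    label-1 (high-symptom) class has the larger LD mean.
    """
    z = np.atleast_2d(np.asarray(z, float))
    y = np.asarray(labels, int)
    if z.shape[0] != len(y):
        raise ValueError("features and labels must align")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    z0, z1 = z[y == classes[0]], z[y == classes[1]]
    mu0, mu1 = z0.mean(axis=0), z1.mean(axis=0)
    diff = mu1 - mu0
    if np.allclose(diff, 0):
        raise ValueError("identical class means: no separating direction")
    n0, n1 = len(z0), len(z1)
    sw = ((n0 - 1) * np.cov(z0, rowvar=False, ddof=1)
          + (n1 - 1) * np.cov(z1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    sw = np.atleast_2d(sw)
    if np.linalg.cond(sw) > 1e10:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular (collinear features?)"
        )
    w = np.linalg.solve(sw, diff)
    w = w / np.linalg.norm(w)
    if w @ diff < 0:  # higher LD must mean higher symptom
        w = -w
    return w


def _project(z: np.ndarray, w: np.ndarray) -> np.ndarray:
    # explicit multiply-add per feature so batch and streaming paths share
    # the exact floating-point evaluation order (bit-identical outputs)
    acc = z[..., 0] * w[0]
    for j in range(1, z.shape[-1]):
        acc = acc + z[..., j] * w[j]
    return acc


def _normalized_columns(stream: FeatureStream, cfg: LDConfig) -> np.ndarray:
    cols = []
    for name, m, sd in zip(cfg.features, cfg.norm_mean, cfg.norm_sd):
        cols.append((stream.column(name) - m) / sd)
    return np.column_stack(cols)


def ld_output(stream: FeatureStream, cfg: LDConfig) -> LDStream:
    """Batch LD computation: normalize, weight, sum, trailing moving average.

    The moving average is causal over the last ``avg_len`` updates (fewer at
    the start of the stream, where the buffer is still filling).
    """
    z = _normalized_columns(stream, cfg)
    raw = _project(z, np.asarray(cfg.weights, float))
    ld = np.empty_like(raw)
    L = cfg.avg_len
    for k in range(len(raw)):
        ld[k] = np.mean(raw[max(0, k - L + 1) : k + 1])
    return LDStream(stream.times, ld, z)


class LDComputer:
    """Streaming LD computation, one FFT update at a time.

    Maintains the trailing moving-average buffer; produces values
    bit-identical to :func:`ld_output` on the same inputs.
    """

    def __init__(self, cfg: LDConfig) -> None:
        self.cfg = cfg
        self._w = np.asarray(cfg.weights, float)
        self._mean = np.asarray(cfg.norm_mean, float)
        self._sd = np.asarray(cfg.norm_sd, float)
        self._buf: deque[float] = deque(maxlen=cfg.avg_len)

    def step(self, features: np.ndarray) -> float:
        """Consume one raw feature vector (ordered as cfg.features); return
        the smoothed LD value."""
        z = (np.asarray(features, float) - self._mean) / self._sd
        self._buf.append(float(_project(z, self._w)))
        return float(np.mean(np.array(self._buf)))
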