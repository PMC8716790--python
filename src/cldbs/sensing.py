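"""Windowed band-power feature extraction and biomarker ranking.

Emulates the on-device sensing stage of a closed-loop DBS implant: at a
configurable FFT update rate, the power spectrum of the trailing window on
each sensed channel is computed and averaged within labeled frequency bands
(e.g. theta, 4-8 Hz).  Candidate (channel, band) features are then ranked by
the strength of their correlation with concurrent symptom reports — the
biomarker-discovery step of the programming workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import signal, stats

from .synthetic import LFPRecording, SymptomTrace

__all__ = [
    "Band",
    "SenseConfig",
    "FeatureStream",
    "FeatureRanking",
    "compute_band_power",
    "rank_features",
    "select_window",
]


class Band(BaseModel):
    """A labeled frequency band, half-open on periodogram bin centers:
    bins with low <= f < high contribute."""

    model_config = ConfigDict(extra="forbid")

    label: str
    low: float  # Hz
    high: float  # Hz

    @model_validator(mode="after")
    def _check(self) -> "Band":
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.label}: need 0 < low < high")
        return self


#: Conventional clinical band set, used as the default scan grid.
DEFAULT_BANDS = [
    Band(label="delta", low=1.0, high=4.0),
    Band(label="theta", low=4.0, high=8.0),
    Band(label="alpha", low=8.0, high=13.0),
    Band(label="beta", low=13.0, high=30.0),
    Band(label="gamma", low=30.0, high=60.0),
]


class SenseConfig(BaseModel):
    """On-device spectral sensing parameters.

    ``update_interval`` is the time between successive FFT outputs; it may
    exceed the window duration (sparse FFTs for minutes-scale control).
    ``window_length`` must be a power of two, matching embedded FFT sizes.
    """

    model_config = ConfigDict(extra="forbid")

    window_length: int = 256  # samples
    window: str = "hann"
    update_interval: float = 0.5  # s
    bands: list[Band] = Field(default_factory=lambda: list(DEFAULT_BANDS))
    channels: list[str] | None = None  # None = all channels in the recording
    aggregate: Literal["mean", "sum"] = "mean"

    @model_validator(mode="after")
    def _check(self) -> "SenseConfig":
        n = self.window_length
        if n < 2 or n & (n - 1):
            raise ValueError("window_length must be a power of two >= 2")
        if self.update_interval <= 0:
            raise ValueError("update_interval must be positive")
        if not self.bands:
            raise ValueError("at least one band required")
        return self


@dataclass
class FeatureStream:
    """Band-power features on the FFT update clock.

    ``values`` has shape (n_updates, n_features); ``names`` are
    ``"<channel>:<band label>"``.
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str]
    config: SenseConfig
    channel_index: dict[str, int] = field(default_factory=dict)
    normalized: bool = False  # z-scored streams may go negative

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), len(self.names)):
            raise ValueError("values must be (n_updates, n_features)")
        if not self.normalized and np.any(self.values < 0):
            raise ValueError("band powers must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.names.index(name)]
        except ValueError:
            raise KeyError(f"feature {name!r} not in stream ({self.names})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.times, name="time"),
                            columns=self.names)


@dataclass
class FeatureRanking:
    """Features ordered by |correlation| with the symptom score."""

    table: pd.DataFrame  # columns: feature, channel, band_low, correlation, importance
    method: str
    degenerate: list[str] = field(default_factory=list)

    @property
    def top(self) -> str:
        return str(self.table.iloc[0]["feature"])

    @property
    def top_importance(self) -> float:
        return float(self.table.iloc[0]["importance"])


def window_band_power(
    windows: np.ndarray, fs: float, cfg: SenseConfig
) -> np.ndarray:
    """Band powers for stacked analysis windows.

    ``windows``: (..., window_length) array.  Returns (..., n_bands) with
    power-spectrum ('spectrum' scaling) bins aggregated per band.
    """
    freqs, pxx = signal.periodogram(
        windows, fs=fs, window=cfg.window, scaling="spectrum", axis=-1,
        detrend=False,
    )
    out = np.empty(windows.shape[:-1] + (len(cfg.bands),))
    nyq = fs / 2
    for bi, band in enumerate(cfg.bands):
        if band.high > nyq:
            raise ValueError(f"band {band.label} [{band.low},{band.high}) exceeds "
                             f"Nyquist {nyq} Hz")
        mask = (freqs >= band.low) & (freqs < band.high)
        if not mask.any():
            raise ValueError(
                f"band {band.label} contains no periodogram bins at "
                f"resolution {fs / cfg.window_length:.3g} Hz"
            )
        agg = np.mean if cfg.aggregate == "mean" else np.sum
        out[..., bi] = agg(pxx[..., mask], axis=-1)
    return out


def band_bin_counts(fs: float, cfg: SenseConfig) -> np.ndarray:
    """Number of periodogram bins each configured band aggregates over."""
    freqs = np.fft.rfftfreq(cfg.window_length, 1.0 / fs)
    return np.array(
        [int(np.sum((freqs >= b.low) & (freqs < b.high))) for b in cfg.bands]
    )


def compute_band_power(rec: LFPRecording, cfg: SenseConfig) -> FeatureStream:
    """Extract band-power features from a recording at the FFT update rate.

    Each output at time t_k = k * update_interval is computed from the
    trailing ``window_length`` samples ending at t_k; the first output occurs
    once a full window is available.
    """
    n_win = cfg.window_length
    if rec.n_samples < n_win:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one window ({n_win})"
        )
    ch_names = cfg.channels if cfg.channels is not None else list(rec.channels)
    ch_idx = [rec.channels.index(c) for c in ch_names]

    k_first = int(np.ceil(n_win / rec.fs / cfg.update_interval - 1e-12))
    ks = []
    k = k_first
    while True:
        end = int(round(k * cfg.update_interval * rec.fs))
        if end > rec.n_samples:
            break
        ks.append((k, end))
        k += 1
    if not ks:
        raise ValueError("recording too short for one update")
    times = np.array([k * cfg.update_interval for k, _ in ks])
    sub = rec.samples[ch_idx]  # copy once; windows below are views of it
    windows = np.stack(
        [sub[:, end - n_win : end] for _, end in ks]
    )  # (n_updates, n_ch, n_win)
    powers = window_band_power(windows, rec.fs, cfg)  # (n_updates, n_ch, n_bands)
    n_upd = len(ks)
    values = powers.reshape(n_upd, len(ch_idx) * len(cfg.bands))
    names = [f"{c}:{b.label}" for c in ch_names for b in cfg.bands]
    channel_index = {c: rec.channels.index(c) for c in ch_names}
    return FeatureStream(times, values, names, cfg, channel_index)


def rank_features(
    stream: FeatureStream,
    trace: SymptomTrace,
    method: Literal["pearson", "spearman"] = "pearson",
) -> FeatureRanking:
    """Rank (channel, band) features by |correlation| with the symptom score.

    The symptom score is resampled to the feature clock by previous-value
    hold (a pain report stays valid until the next).  Zero-variance features
    get importance 0 and are flagged.  Ties break by (channel index, band
    low edge).
    """
    if stream.times[-1] < trace.times[0] or stream.times[0] > trace.times[-1]:
        raise ValueError("feature and symptom time supports do not overlap")
    score = trace.score_at(stream.times)

    rows, degenerate = [], []
    band_by_label = {b.label: b for b in stream.config.bands}
    for j, name in enumerate(stream.names):
        ch, band_label = name.split(":")
        x = stream.values[:, j]
        # relative tolerance: numerically-constant features count as flat
        if np.std(x) <= 1e-12 * (abs(np.mean(x)) + 1e-300) or np.std(score) == 0:
            r = np.nan
            degenerate.append(name)
        elif method == "pearson":
            r = float(np.corrcoef(x, score)[0, 1])
        else:
            r = float(stats.spearmanr(x, score).statistic)
        rows.append(
            {
                "feature": name,
                "channel": ch,
                "channel_index": stream.channel_index.get(ch, 0),
                "band_low": band_by_label[band_label].low,
                "correlation": r,
                "importance": 0.0 if np.isnan(r) else abs(r),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["importance", "channel_index", "band_low"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return FeatureRanking(table, method, degenerate)


def select_window(
    rec: LFPRecording,
    trace: SymptomTrace,
    candidate_lengths: Sequence[int],
    base_cfg: SenseConfig | None = None,
    fraction: float = 0.95,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[int, pd.DataFrame]:
    """Pick the smallest FFT window that keeps near-best biomarker strength.

    For each candidate window length the top-feature importance is computed;
    the smallest window whose top importance reaches ``fraction`` of the best
    across candidates is returned, together with a per-candidate report.
    Smaller windows mean coarser frequency resolution but faster, cheaper
    on-device updates, so the smallest acceptable window wins ties.
    """
    if len(candidate_lengths) < 2 and len(candidate_lengths) != 1:
        raise ValueError("at least one candidate window length required")
    base = base_cfg or SenseConfig()
    rows = []
    for n_win in sorted(set(int(n) for n in candidate_lengths)):
        cfg = base.model_copy(update={"window_length": n_win})
        try:
            stream = compute_band_power(rec, cfg)
            ranking = rank_features(stream, trace, method)
            rows.append(
                {
                    "window_length": n_win,
                    "resolution_hz": rec.fs / n_win,
                    "top_feature": ranking.top,
                    "top_importance": ranking.top_importance,
                }
            )
        except ValueError:
            rows.append(
                {
                    "window_length": n_win,
                    "resolution_hz": rec.fs / n_win,
                    "top_feature": None,
                    "top_importance": np.nan,
                }
            )
    report = pd.DataFrame(rows)
    if report["top_importance"].isna().all() or (
        report["top_importance"].fillna(0) < 1e-12
    ).all():
        raise ValueError("all candidate windows are degenerate")
    best = report["top_importance"].max()
    ok = report[report["top_importance"] >= fraction * best]
    chosen = int(ok["window_length"].min())
    return chosen, report
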