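"""Synthetic symptom and LFP generation.

Produces the two data streams a closed-loop DBS programming session works
from: a continuous symptom (pain) score with a dichotomized high/low state,
and multichannel local field potentials whose band power in configurable
frequency bands tracks the symptom state.  Common recording artifact
classes (EKG volume conduction, movement, elevated 0 mA noise floor, and
stimulation-locked artifacts) can be layered on, so every downstream stage
of the pipeline is exercisable without any real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import signal

__all__ = [
    "SymptomDynamics",
    "SymptomTrace",
    "BiomarkerSpec",
    "ArtifactSpec",
    "LFPRecording",
    "generate_symptom_trace",
    "generate_lfp",
    "inject_stim_artifacts",
    "LfpSynthesizer",
]

ArtifactKind = Literal[
    "stim_transient", "ekg", "movement", "zero_mA_noise", "cross_region_stim"
]

# Artifact kinds that are driven by the stimulation amplitude series; they
# contribute nothing during stimulation-free synthesis.
STIM_TRIGGERED_KINDS = frozenset({"stim_transient", "cross_region_stim"})


class SymptomDynamics(BaseModel):
    """Generative model of a chronic-pain score over time.

    Score = baseline + diurnal sinusoid + two-state telegraph episodes +
    white observation noise, clipped to the 0-10 numeric rating scale.
    The telegraph term produces abrupt episode on/offsets; the sinusoid the
    slow time-of-day drift pain patients commonly report.
    """

    model_config = ConfigDict(extra="forbid")

    baseline: float = 4.0
    diurnal_amplitude: float = 1.5
    diurnal_period: float = 86400.0  # s
    diurnal_phase: float = 0.0  # radians
    transition_rate: float = 1.0 / 600.0  # telegraph switch rate, 1/s
    transition_amplitude: float = 3.0  # score added during an episode
    noise_sd: float = 0.3  # score units

    @model_validator(mode="after")
    def _check(self) -> "SymptomDynamics":
        if self.diurnal_period <= 0:
            raise ValueError("diurnal_period must be positive")
        if self.transition_rate < 0 or self.noise_sd < 0:
            raise ValueError("transition_rate and noise_sd must be >= 0")
        return self


@dataclass(frozen=True)
class SymptomTrace:
    """Pain score on a uniform time grid with its dichotomized state.

    ``state`` is 1 wherever ``score >= cutoff`` (high-pain) and 0 otherwise.
    """

    times: np.ndarray  # s, uniform grid
    score: np.ndarray  # 0-10 continuous
    state: np.ndarray  # 0/1 int
    cutoff: float

    def __post_init__(self) -> None:
        t, s = np.asarray(self.times, float), np.asarray(self.score, float)
        if t.ndim != 1 or t.shape != s.shape or self.state.shape != t.shape:
            raise ValueError("times, score, state must be 1-D and equal length")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing and uniform")
        if np.any(s < 0) or np.any(s > 10):
            raise ValueError("scores must lie in [0, 10]")
        if not np.array_equal(self.state, (s >= self.cutoff).astype(int)):
            raise ValueError("state must equal (score >= cutoff)")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 1.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + self.dt

    def state_at(self, t: np.ndarray | float) -> np.ndarray:
        """Previous-value-hold resampling of the binary state."""
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        return self.state[idx]

    def score_at(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        return self.score[idx]


class BiomarkerSpec(BaseModel):
    """A symptom-tracking spectral feature on one sensing channel.

    Band power (variance of the narrowband component, µV²) switches between
    ``power_low`` and ``power_high`` with the symptom state.  With
    ``correlation_sign = -1`` the mapping inverts (power falls during
    high-symptom states), as for biomarkers that desynchronize with symptoms.
    """

    model_config = ConfigDict(extra="forbid")

    channel: int
    band: tuple[float, float]  # [low, high] Hz
    power_low: float  # µV², band power in state 0
    power_high: float  # µV², band power in state 1
    correlation_sign: Literal[-1, 1] = 1

    @model_validator(mode="after")
    def _check(self) -> "BiomarkerSpec":
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if self.power_low < 0 or self.power_high < 0:
            raise ValueError("band powers must be >= 0")
        if self.channel < 0:
            raise ValueError("channel index must be >= 0")
        return self

    def power_for_state(self, state: int) -> float:
        high = self.power_high if self.correlation_sign > 0 else self.power_low
        low = self.power_low if self.correlation_sign > 0 else self.power_high
        return high if state else low


class ArtifactSpec(BaseModel):
    """One artifact class contaminating the recording.

    ``rate`` is events/s for ekg and movement; ignored for zero_mA_noise
    (continuous).  ``channels=None`` affects every channel.
    stim_transient / cross_region_stim specs only take effect when a
    stimulation amplitude series is applied (see ``inject_stim_artifacts``).
    """

    model_config = ConfigDict(extra="forbid")

    kind: ArtifactKind
    amplitude: float  # µV scale
    rate: float | None = None  # events/s where applicable
    channels: tuple[int, ...] | None = None

    @model_validator(mode="after")
    def _check(self) -> "ArtifactSpec":
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rate is not None and self.rate < 0:
            raise ValueError("rate must be >= 0")
        return self

    def default_rate(self) -> float:
        if self.rate is not None:
            return self.rate
        return {"ekg": 1.2, "movement": 0.05}.get(self.kind, 0.0)


@dataclass
class LFPRecording:
    """Multichannel sensed time series in µV with an artifact event log."""

    fs: float  # Hz
    channels: list[str]
    samples: np.ndarray  # (n_channels, n_samples) µV
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("one sample row per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "LFPRecording":
        return LFPRecording(
            self.fs, list(self.channels), self.samples.copy(), list(self.events)
        )


def generate_symptom_trace(
    duration: float,
    dynamics: SymptomDynamics | None = None,
    cutoff: float = 5.0,
    seed: int | np.random.Generator = 0,
    *,
    dt: float = 1.0,
    require_both_states: bool = False,
    max_retries: int = 20,
) -> SymptomTrace:
    """Simulate a pain-score trace and dichotomize it at ``cutoff``.

    Parameters
    ----------
    duration : float
        Length of the trace in seconds.
    dynamics : SymptomDynamics, optional
        Generative parameters; defaults model diurnal drift plus episodic
        pain flares.
    cutoff : float
        Dichotomization level on the 0-10 scale; state 1 means score >= cutoff.
    require_both_states : bool
        If True, redraw (up to ``max_retries`` times) until both states occur,
        raising if the dynamics cannot produce both.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 < cutoff < 10:
        raise ValueError("cutoff must lie in (0, 10)")
    dyn = dynamics or SymptomDynamics()
    rng = np.random.default_rng(seed)

    times = np.arange(0.0, duration, dt)
    for _ in range(max_retries):
        score = _draw_score(times, dyn, rng, dt)
        state = (score >= cutoff).astype(int)
        if not require_both_states or (state.min() == 0 and state.max() == 1):
            return SymptomTrace(times, score, state, cutoff)
    raise RuntimeError(
        f"could not produce both symptom states in {max_retries} draws; "
        "dynamics are degenerate for this cutoff"
    )


def _draw_score(
    times: np.ndarray, dyn: SymptomDynamics, rng: np.random.Generator, dt: float
) -> np.ndarray:
    n = len(times)
    score = dyn.baseline + dyn.diurnal_amplitude * np.sin(
        2 * np.pi * times / dyn.diurnal_period + dyn.diurnal_phase
    )
    if dyn.transition_amplitude > 0 and dyn.transition_rate >= 0:
        p_switch = min(dyn.transition_rate * dt, 1.0)
        switches = rng.random(n) < p_switch
        telegraph = np.empty(n, dtype=int)
        s = int(rng.integers(0, 2))
        for i in range(n):
            if switches[i]:
                s = 1 - s
            telegraph[i] = s
        score = score + dyn.transition_amplitude * telegraph
    if dyn.noise_sd > 0:
        score = score + rng.normal(0.0, dyn.noise_sd, n)
    return np.clip(score, 0.0, 10.0)


# ---------------------------------------------------------------------------
# LFP synthesis


def _pink_fir(fs: float, exponent: float, n_taps: int = 513) -> np.ndarray:
    """FIR shaping filter giving a ~1/f^exponent power spectrum, unit output
    variance for unit-variance white input."""
    f = np.linspace(0.0, 1.0, 256)
    f_hz = f * fs / 2
    f_floor = 0.5  # flatten below 0.5 Hz to bound low-frequency energy
    mag = (np.maximum(f_hz, f_floor) / f_floor) ** (-exponent / 2.0)
    taps = signal.firwin2(n_taps, f, mag)
    return taps / np.sqrt(np.sum(taps**2))


def _band_sos(band: tuple[float, float], fs: float):
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # white-noise variance gain of the filter, for unit-power normalization
    _, h = signal.sosfreqz(sos, worN=4096, fs=fs)
    gain = float(np.mean(np.abs(h) ** 2))
    return sos, np.sqrt(gain)


def _ekg_template(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic spike ~60 ms long resembling a volume-conducted QRS."""
    t = np.arange(int(0.06 * fs)) / fs
    pos = np.exp(-(((t - 0.015) / 0.004) ** 2))
    neg = -0.5 * np.exp(-(((t - 0.030) / 0.007) ** 2))
    return amplitude * (pos + neg)


class LfpSynthesizer:
    """Streaming multichannel LFP synthesizer with persistent filter state.

    Renders the recording chunk-by-chunk so the closed-loop simulator can
    interleave synthesis with stimulation feedback; a single full-duration
    render (``generate_lfp``) uses exactly the same path.
    """

    def __init__(
        self,
        fs: float,
        n_channels: int,
        biomarkers: Sequence[BiomarkerSpec] = (),
        artifacts: Sequence[ArtifactSpec] = (),
        *,
        background_rms: float = 1.0,
        background_exponent: float = 1.0,
        rng: np.random.Generator | int = 0,
    ) -> None:
        if fs <= 0:
            raise ValueError("fs must be positive")
        for bm in biomarkers:
            if bm.band[1] * 2 >= fs:
                raise ValueError(
                    f"fs={fs} must exceed 2x biomarker band edge {bm.band[1]}"
                )
            if bm.channel >= n_channels:
                raise ValueError("biomarker channel index out of range")
        self.fs = fs
        self.n_channels = n_channels
        self.biomarkers = list(biomarkers)
        self.artifacts = [a for a in artifacts if a.kind not in STIM_TRIGGERED_KINDS]
        self.background_rms = background_rms
        self.rng = np.random.default_rng(rng)
        self.t = 0.0  # running clock, s

        self._pink = _pink_fir(fs, background_exponent)
        self._pink_zi = [
            np.zeros(len(self._pink) - 1) for _ in range(n_channels)
        ]
        self._bm_filters = []
        for bm in self.biomarkers:
            sos, gain = _band_sos(bm.band, fs)
            self._bm_filters.append(
                {"sos": sos, "gain": gain, "zi": np.zeros((sos.shape[0], 2))}
            )
        # per-channel waveform tails extending past a chunk boundary
        self._overhang = [np.zeros(0) for _ in range(n_channels)]
        self._next_event_t = {}
        for a in self.artifacts:
            if a.kind in ("ekg", "movement"):
                rate = a.default_rate()
                self._next_event_t[id(a)] = (
                    self.rng.exponential(1.0 / rate) if rate > 0 else np.inf
                )
        self.events: list[tuple[float, str]] = []

    def _add_event(
        self, out: np.ndarray, ch: int, start_idx: int, wave: np.ndarray
    ) -> None:
        n = out.shape[1]
        head = wave[: max(0, n - start_idx)]
        out[ch, start_idx : start_idx + len(head)] += head
        tail = wave[len(head) :]
        if len(tail):
            cur = self._overhang[ch]
            if len(cur) < len(tail):
                cur = np.concatenate([cur, np.zeros(len(tail) - len(cur))])
            cur[: len(tail)] += tail
            self._overhang[ch] = cur

    def render(self, n: int, state: int | np.ndarray) -> np.ndarray:
        """Render ``n`` samples given the symptom state (scalar, or per-sample
        array) over the chunk.  Returns a (n_channels, n) µV array."""
        state_arr = np.broadcast_to(np.asarray(state, int), (n,))
        out = np.empty((self.n_channels, n))
        for ch in range(self.n_channels):
            white = self.rng.standard_normal(n)
            bg, self._pink_zi[ch] = signal.lfilter(
                self._pink, 1.0, white, zi=self._pink_zi[ch]
            )
            out[ch] = self.background_rms * bg
        for bm, filt in zip(self.biomarkers, self._bm_filters):
            white = self.rng.standard_normal(n)
            nb, filt["zi"] = signal.sosfilt(filt["sos"], white, zi=filt["zi"])
            nb = nb / filt["gain"]  # unit-variance narrowband
            p_lo = bm.power_for_state(0)
            p_hi = bm.power_for_state(1)
            amp = np.sqrt(np.where(state_arr == 1, p_hi, p_lo))
            out[bm.channel] += amp * nb
        self._render_artifacts(out, n)
        # flush overhangs from events in earlier chunks
        for ch in range(self.n_channels):
            oh = self._overhang[ch]
            if len(oh):
                m = min(len(oh), n)
                out[ch, :m] += oh[:m]
                self._overhang[ch] = oh[m:]
        self.t += n / self.fs
        return out

    def _render_artifacts(self, out: np.ndarray, n: int) -> None:
        t_end = self.t + n / self.fs
        for a in self.artifacts:
            chans = (
                list(range(self.n_channels)) if a.channels is None else list(a.channels)
            )
            if a.kind == "zero_mA_noise":
                for ch in chans:
                    out[ch] += a.amplitude * self.rng.standard_normal(n)
                continue
            rate = a.default_rate()
            if rate <= 0:
                continue
            while self._next_event_t[id(a)] < t_end:
                te = self._next_event_t[id(a)]
                idx = int(round((te - self.t) * self.fs))
                if a.kind == "ekg":
                    wave = _ekg_template(self.fs, a.amplitude)
                else:  # movement: slow large-amplitude burst, Hann envelope
                    dur = self.rng.uniform(0.5, 2.0)
                    m = max(int(dur * self.fs), 8)
                    slow = signal.lfilter(
                        *signal.butter(2, 3.0, fs=self.fs),
                        self.rng.standard_normal(m),
                    )
                    sd = np.std(slow)
                    wave = a.amplitude * np.hanning(m) * slow / (sd if sd > 0 else 1.0)
                for ch in chans:
                    self._add_event(out, ch, idx, wave)
                self.events.append((float(te), a.kind))
                self._next_event_t[id(a)] = te + self.rng.exponential(1.0 / rate)


def generate_lfp(
    trace: SymptomTrace,
    biomarkers: Sequence[BiomarkerSpec],
    artifacts: Sequence[ArtifactSpec] = (),
    fs: float = 250.0,
    seed: int | np.random.Generator = 0,
    *,
    n_channels: int | None = None,
    background_rms: float = 1.0,
    background_exponent: float = 1.0,
) -> LFPRecording:
    """Synthesize a multichannel LFP whose biomarker band powers track
    ``trace.state``.

    Each channel is 1/f-shaped broadband background noise; channels named in
    ``biomarkers`` additionally carry state-gated band-limited Gaussian noise
    whose variance equals the BiomarkerSpec band power for the current state.
    """
    if n_channels is None:
        n_channels = max((bm.channel for bm in biomarkers), default=-1) + 1
        n_channels = max(n_channels, 1)
    synth = LfpSynthesizer(
        fs,
        n_channels,
        biomarkers,
        artifacts,
        background_rms=background_rms,
        background_exponent=background_exponent,
        rng=seed,
    )
    n = int(round(trace.duration * fs))
    sample_states = trace.state_at(np.arange(n) / fs)
    samples = synth.render(n, sample_states)
    channels = [f"ch{i + 1}" for i in range(n_channels)]
    return LFPRecording(fs, channels, samples, list(synth.events))


def inject_stim_artifacts(
    rec: LFPRecording,
    amplitude: np.ndarray,
    gains: dict[str, list[tuple[float, float]]],
    *,
    transient_magnitude: float = 0.0,
    transient_decay_s: float = 0.1,
) -> LFPRecording:
    """Superimpose stimulation-locked artifacts on a recording (pure function).

    Parameters
    ----------
    amplitude : array
        Stimulation amplitude in mA, one value per recording sample.
    gains : dict
        Per-channel list of ``(frequency_hz, gain_uV_per_mA)`` tonic artifact
        components; the sensed artifact power scales with the instantaneous
        amplitude.
    transient_magnitude, transient_decay_s :
        Exponentially decaying broadband transient added on every 0 -> nonzero
        amplitude step, across all channels.
    """
    amplitude = np.asarray(amplitude, float)
    if amplitude.shape != (rec.n_samples,):
        raise ValueError(
            f"amplitude series length {amplitude.shape} does not match "
            f"recording length ({rec.n_samples},)"
        )
    out = rec.copy()
    t = rec.times
    for ch_name, comps in gains.items():
        ci = rec.channels.index(ch_name)
        for freq, gain in comps:
            out.samples[ci] += gain * amplitude * np.sin(2 * np.pi * freq * t)
    if transient_magnitude > 0:
        prev = np.concatenate([[0.0], amplitude[:-1]])
        onsets = np.flatnonzero((prev == 0) & (amplitude > 0))
        for idx in onsets:
            tail = t[idx:] - t[idx]
            wave = transient_magnitude * np.exp(-tail / transient_decay_s)
            out.samples[:, idx:] += wave
            out.events.append((float(t[idx]), "stim_transient"))
    return out
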