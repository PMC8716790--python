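"""Stimulation control, closed-loop simulation, and the energy proxy.

Maps detector states to stimulation amplitudes with slew-rate-limited
ramping, feeds the delivered amplitude back into sensing as artifact, and
models the patient's symptom response with first-order wash-in / wash-out
dynamics, closing the loop:

    LFP synthesis -> band power -> LD -> detector -> ramped amplitude
        ^                                                   |
        +------ stimulation artifact & symptom relief ------+

The ramp worked example: with a 2 s ramp and a 1 s dwell in the
stimulation-on state, the effective amplitude peaks at 50% of target before
ramping back down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .detector import Detector, DetectorConfig, StateTrace
from .discriminant import LDComputer, LDConfig
from .sensing import SenseConfig, window_band_power
from .synthetic import (
    ArtifactSpec,
    BiomarkerSpec,
    LfpSynthesizer,
    SymptomTrace,
)

__all__ = [
    "StimConfig",
    "PatientModel",
    "ClosedLoopTrace",
    "apply_ramp",
    "simulate_closed_loop",
    "energy_delivered",
]


class StimConfig(BaseModel):
    """Per-state stimulation targets, ramping, and sensing-artifact coupling.

    ``ramp_s`` is the time to traverse the full range from 0 to the largest
    state target, so the slew rate is ``max(target)/ramp_s`` mA/s; 0 means
    instant steps.  ``artifact_gains`` maps sense-channel name to a list of
    ``(frequency_hz, gain_uV_per_mA)`` tonic components the delivered
    amplitude couples into that channel.
    """

    model_config = ConfigDict(extra="forbid")

    state_targets: dict[int, float]  # state -> mA
    ramp_s: float = 2.0
    ramp_mode: str = "linear"  # "linear" | "step"
    frequency_hz: float = 150.0  # stimulation pulse frequency (metadata)
    pulse_width_us: float = 80.0  # metadata for the energy proxy
    artifact_gains: dict[str, list[tuple[float, float]]] = Field(
        default_factory=dict
    )
    transient_magnitude: float = 0.0  # µV transient on each 0 -> on step
    transient_decay_s: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "StimConfig":
        if not self.state_targets:
            raise ValueError("state_targets must be nonempty")
        if any(a < 0 for a in self.state_targets.values()):
            raise ValueError("amplitudes must be >= 0")
        if min(self.state_targets.values()) != 0:
            raise ValueError("a designated off state (amplitude 0) is required")
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be >= 0")
        if self.ramp_mode not in ("linear", "step"):
            raise ValueError("ramp_mode must be 'linear' or 'step'")
        return self

    @property
    def max_target(self) -> float:
        return max(self.state_targets.values())

    @property
    def slew_rate(self) -> float:
        """mA per second; inf for an instant (step) ramp."""
        if self.ramp_s == 0 or self.ramp_mode == "step":
            return np.inf
        return self.max_target / self.ramp_s

    def target_for(self, state: int) -> float:
        try:
            return self.state_targets[state]
        except KeyError:
            raise KeyError(f"no stimulation target configured for state {state}")


@dataclass
class PatientModel:
    """First-order symptom response to stimulation.

    The modeled pain score relaxes toward ``baseline(t) − relief · a/a_max``
    with time constant ``tau_in`` while the relief effect is deepening
    (target below current score) and ``tau_out`` while it is wearing off.
    ``baseline`` carries the dichotomization cutoff used for symptom states.
    """

    tau_in: float  # s
    tau_out: float  # s
    relief: float  # score units at full amplitude
    baseline: SymptomTrace

    def __post_init__(self) -> None:
        if self.tau_in <= 0 or self.tau_out <= 0:
            raise ValueError("time constants must be positive")
        if self.relief < 0:
            raise ValueError("relief must be >= 0")

    def step_score(
        self, score: float, baseline: float, amp_frac: float, dt: float
    ) -> float:
        target = baseline - self.relief * amp_frac
        tau = self.tau_in if target < score else self.tau_out
        new = target + (score - target) * np.exp(-dt / tau)
        return float(np.clip(new, 0.0, 10.0))


@dataclass
class ClosedLoopTrace:
    """Time-aligned record of one closed-loop run (one row per FFT update)."""

    times: np.ndarray
    ld: np.ndarray
    state: np.ndarray
    amp_cmd: np.ndarray  # commanded (state-target) amplitude, mA
    amp_eff: np.ndarray  # effective (ramped) amplitude at the update, mA
    score: np.ndarray  # modeled symptom score
    update_interval: float
    changes: list[tuple[float, int, int, str]] | None = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def state_trace(self) -> StateTrace:
        return StateTrace(self.times, self.state, self.changes or [],
                          self.update_interval)

    def symptom_trace(self, cutoff: float) -> SymptomTrace:
        """The modeled symptom score as a dichotomized trace (what the
        detector should be tracking)."""
        return SymptomTrace(
            self.times, self.score, (self.score >= cutoff).astype(int), cutoff
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "ld": self.ld,
                "state": self.state,
                "amp_cmd": self.amp_cmd,
                "amp_eff": self.amp_eff,
                "score": self.score,
            }
        )


def apply_ramp(
    states: StateTrace, cfg: StimConfig, dt: float, initial_amplitude: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Slew-rate-limited amplitude series for a detector state trace.

    Returns ``(times, amplitude)`` on a ``dt`` grid spanning the trace.  The
    amplitude moves toward the current state's target at the configured slew
    rate; a state change mid-ramp retargets from the current amplitude (no
    snap), so short dwells reach only part of the target.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    upd = states.update_interval or dt
    t0 = states.times[0]
    t_end = states.times[-1] + upd
    times = np.arange(t0, t_end - 1e-12, dt)
    targets = np.array([cfg.target_for(int(s)) for s in states.state])
    idx = np.clip(np.searchsorted(states.times, times, side="right") - 1, 0, None)
    tgt = targets[idx]
    amp = np.empty_like(times)
    a = float(initial_amplitude)
    max_step = cfg.slew_rate * dt
    for k in range(len(times)):
        delta = tgt[k] - a
        if np.isinf(max_step):
            a = tgt[k]
        else:
            a += np.clip(delta, -max_step, max_step)
        amp[k] = a
    return times, amp


def energy_delivered(
    amplitudes: np.ndarray, cfg: StimConfig, dt: float, per_hour: bool = False
) -> float:
    """TEED-style energy proxy: sum a(t)^2 · f · pulse_width · dt (unit
    impedance), in mA²·Hz·µs·s.  With ``per_hour`` the total is normalized
    to one hour of run time."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(amplitudes, float)
    total = float(np.sum(a**2) * cfg.frequency_hz * cfg.pulse_width_us * dt)
    if per_hour:
        duration_h = len(a) * dt / 3600.0
        return total / duration_h if duration_h > 0 else 0.0
    return total


def simulate_closed_loop(
    patient: PatientModel,
    biomarkers: list[BiomarkerSpec],
    sense_cfg: SenseConfig,
    ld_cfg: LDConfig,
    det_cfg: DetectorConfig,
    stim_cfg: StimConfig,
    duration: float,
    seed: int | np.random.Generator = 0,
    *,
    fs: float = 250.0,
    artifacts: list[ArtifactSpec] = [],
    background_rms: float = 1.0,
    background_exponent: float = 1.0,
    initial_state: int = 0,
) -> ClosedLoopTrace:
    """Run the full sense -> classify -> stimulate loop on synthetic data.

    Per FFT update the simulator: steps the patient model, synthesizes the
    next LFP chunk at the current symptom state, ramps the amplitude across
    the chunk and injects stimulation artifacts *into the time series* (so
    blanking and LD averaging interact with them realistically), extracts
    band powers from the trailing FFT window, computes the smoothed LD,
    steps the detector, and logs everything on a shared clock.
    """
    if abs(det_cfg.update_interval - sense_cfg.update_interval) > 1e-12:
        raise ValueError(
            "detector update_interval and sense update_interval must match "
            f"({det_cfg.update_interval} != {sense_cfg.update_interval})"
        )
    rng = np.random.default_rng(seed)
    upd = sense_cfg.update_interval
    chunk_n = int(round(upd * fs))
    if chunk_n < 1:
        raise ValueError("update interval shorter than one sample")
    n_updates = int(round(duration / upd))
    n_channels = max((bm.channel for bm in biomarkers), default=-1) + 1
    # make sure all sensed channels exist
    ch_names = [f"ch{i + 1}" for i in range(max(n_channels, 1))]
    if sense_cfg.channels:
        for c in sense_cfg.channels:
            if c not in ch_names:
                ch_names.append(c)
    synth = LfpSynthesizer(
        fs, len(ch_names), biomarkers, artifacts,
        background_rms=background_rms, background_exponent=background_exponent,
        rng=rng,
    )
    sense_channels = sense_cfg.channels or ch_names
    ch_idx = [ch_names.index(c) for c in sense_channels]
    feat_cols = []  # indices of ld features within the flattened feature block
    names = [f"{c}:{b.label}" for c in sense_channels for b in sense_cfg.bands]
    for f in ld_cfg.features:
        if f not in names:
            raise KeyError(f"LD feature {f!r} not produced by sense config")
        feat_cols.append(names.index(f))

    n_win = sense_cfg.window_length
    buf = np.zeros((len(ch_names), n_win))

    score = float(patient.baseline.score[0])
    cutoff = patient.baseline.cutoff
    a_max = stim_cfg.max_target
    amp = 0.0
    max_step = stim_cfg.slew_rate / fs
    ld_comp = LDComputer(ld_cfg)
    det = Detector(det_cfg, initial_state)
    state = det.state
    transient_tail = np.zeros(0)

    rows = np.empty((n_updates, 6))
    for k in range(n_updates):
        t_k = (k + 1) * upd
        baseline_now = float(patient.baseline.score_at(t_k))
        amp_frac = amp / a_max if a_max > 0 else 0.0
        score = patient.step_score(score, baseline_now, amp_frac, upd)
        sym_state = int(score >= cutoff)

        chunk = synth.render(chunk_n, sym_state)

        # ramp amplitude sample-by-sample toward the current state's target
        target = stim_cfg.target_for(state)
        if np.isinf(max_step):
            amp_samples = np.full(chunk_n, target)
        else:
            amp_samples = np.empty(chunk_n)
            a = amp
            for i in range(chunk_n):
                a += np.clip(target - a, -max_step, max_step)
                amp_samples[i] = a
        prev_amp = amp
        amp = float(amp_samples[-1])

        # stimulation artifact feedback into the sensed chunk
        t_samples = synth.t - chunk_n / fs + np.arange(chunk_n) / fs
        for ch_name, comps in stim_cfg.artifact_gains.items():
            if ch_name in ch_names:
                ci = ch_names.index(ch_name)
                for freq, gain in comps:
                    chunk[ci] += gain * amp_samples * np.sin(
                        2 * np.pi * freq * t_samples
                    )
        if stim_cfg.transient_magnitude > 0:
            full = np.concatenate([[prev_amp], amp_samples])
            onsets = np.flatnonzero((full[:-1] == 0) & (full[1:] > 0))
            for oi in onsets:
                tail_t = np.arange(chunk_n - oi) / fs
                chunk[:, oi:] += stim_cfg.transient_magnitude * np.exp(
                    -tail_t / stim_cfg.transient_decay_s
                )
                carry_t = (np.arange(chunk_n * 4) + (chunk_n - oi)) / fs
                carry = stim_cfg.transient_magnitude * np.exp(
                    -carry_t / stim_cfg.transient_decay_s
                )
                if len(transient_tail) < len(carry):
                    transient_tail = np.concatenate(
                        [transient_tail, np.zeros(len(carry) - len(transient_tail))]
                    )
                transient_tail[: len(carry)] += carry
        if len(transient_tail):
            m = min(len(transient_tail), chunk_n)
            chunk += transient_tail[:m]
            transient_tail = transient_tail[m:]

        if chunk_n < n_win:
            buf = np.concatenate([buf[:, chunk_n:], chunk], axis=1)
        else:
            buf = chunk[:, -n_win:]

        powers = window_band_power(buf[ch_idx], fs, sense_cfg).reshape(-1)
        ld_val = ld_comp.step(powers[feat_cols])
        state = det.step(t_k, ld_val)

        rows[k] = (t_k, ld_val, state, stim_cfg.target_for(state), amp, score)

    return ClosedLoopTrace(
        times=rows[:, 0],
        ld=rows[:, 1],
        state=rows[:, 2].astype(int),
        amp_cmd=rows[:, 3],
        amp_eff=rows[:, 4],
        score=rows[:, 5],
        update_interval=upd,
        changes=det.changes,
    )
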