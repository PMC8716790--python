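"""The embedded detector state machine.

The smoothed LD value is compared against one threshold (two device states)
or two thresholds (three states, the upper one usable as an artifact "catch"
state).  A state change requires the LD to stay on the qualifying side of
the relevant threshold for a configured number of *consecutive* FFT updates
(the onset / termination counters; duration in seconds = counter x FFT
update interval).  After every state change a blanking window suppresses
further counting, absorbing stimulation-switching artifacts.

Tie handling: a threshold comparison uses >= — an LD exactly at threshold
counts as above.  States form an ordered ladder; only adjacent transitions
occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .discriminant import LDStream

__all__ = [
    "DetectorConfig",
    "StateTrace",
    "Detector",
    "run_detector",
    "duty_cycle",
    "detect_lock",
    "LockEpisode",
]


class DetectorConfig(BaseModel):
    """Threshold-comparison and state-change timing parameters.

    ``counter_overrides`` optionally gives per-threshold (onset, termination)
    counters keyed by threshold index (0 = lower); by default both thresholds
    share ``onset_counter`` / ``termination_counter``.

    With ``strict_blanking`` the counters are additionally cleared when the
    blanking window ends (the stronger reading of "stops the classifier from
    changing state"); by default blanked updates are simply ignored for
    counting and the counters resume where they left off.
    """

    model_config = ConfigDict(extra="forbid")

    thresholds: list[float] = [0.0]
    onset_counter: int = 1
    termination_counter: int = 1
    blanking: float = 0.0  # s
    update_interval: float = 0.5  # s, shared FFT clock
    counter_overrides: dict[int, tuple[int, int]] = {}
    strict_blanking: bool = False

    @model_validator(mode="after")
    def _check(self) -> "DetectorConfig":
        if not 1 <= len(self.thresholds) <= 2:
            raise ValueError("1 or 2 thresholds required")
        if len(self.thresholds) == 2 and not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly ascending")
        if self.onset_counter < 1 or self.termination_counter < 1:
            raise ValueError("counters must be >= 1")
        if self.blanking < 0:
            raise ValueError("blanking must be >= 0")
        if self.update_interval <= 0:
            raise ValueError("update_interval must be positive")
        for i, (a, b) in self.counter_overrides.items():
            if i not in range(len(self.thresholds)) or a < 1 or b < 1:
                raise ValueError("invalid counter override")
        return self

    @property
    def n_states(self) -> int:
        return len(self.thresholds) + 1

    @property
    def onset_duration(self) -> float:
        """Effective rise time in seconds: counter x FFT update interval."""
        return self.onset_counter * self.update_interval

    @property
    def termination_duration(self) -> float:
        return self.termination_counter * self.update_interval

    def counters_for(self, threshold_index: int) -> tuple[int, int]:
        return self.counter_overrides.get(
            threshold_index, (self.onset_counter, self.termination_counter)
        )


@dataclass
class StateTrace:
    """Detector state per FFT update, with a transition log.

    ``changes`` entries are (time, from_state, to_state, cause) where cause
    names the threshold crossed, e.g. ``"onset@t1"``.
    """

    times: np.ndarray
    state: np.ndarray
    changes: list[tuple[float, int, int, str]] = field(default_factory=list)
    update_interval: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.state):
            raise ValueError("times and state must align")
        if self.update_interval is None and len(self.times) > 1:
            self.update_interval = float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


class Detector:
    """Incremental state machine; one ``step`` per FFT update."""

    def __init__(self, cfg: DetectorConfig, initial_state: int = 0) -> None:
        if not 0 <= initial_state < cfg.n_states:
            raise ValueError("initial state out of range")
        self.cfg = cfg
        self.state = initial_state
        self.up_count = 0
        self.down_count = 0
        self.blank_until = -np.inf
        self.changes: list[tuple[float, int, int, str]] = []

    def step(self, t: float, ld: float) -> int:
        cfg = self.cfg
        if t <= self.blank_until + 1e-12:
            return self.state  # blanked: ignored for counting
        if cfg.strict_blanking and self.blank_until > -np.inf:
            # first update after blanking ends clears the counters
            self.up_count = self.down_count = 0
            self.blank_until = -np.inf

        can_rise = self.state < cfg.n_states - 1
        can_fall = self.state > 0
        if can_rise:
            if ld >= cfg.thresholds[self.state]:
                self.up_count += 1
            else:
                self.up_count = 0
        if can_fall:
            if ld < cfg.thresholds[self.state - 1]:
                self.down_count += 1
            else:
                self.down_count = 0

        if can_rise:
            onset_c, _ = cfg.counters_for(self.state)
            if self.up_count >= onset_c:
                self._change(t, self.state + 1, f"onset@t{self.state + 1}")
                return self.state
        if can_fall:
            _, term_c = cfg.counters_for(self.state - 1)
            if self.down_count >= term_c:
                self._change(t, self.state - 1, f"termination@t{self.state}")
        return self.state

    def _change(self, t: float, new_state: int, cause: str) -> None:
        self.changes.append((float(t), self.state, new_state, cause))
        self.state = new_state
        self.up_count = self.down_count = 0
        if self.cfg.blanking > 0:
            self.blank_until = t + self.cfg.blanking
        elif self.cfg.strict_blanking:
            self.blank_until = -np.inf


def run_detector(
    ld: LDStream | np.ndarray,
    cfg: DetectorConfig,
    initial_state: int = 0,
    times: np.ndarray | None = None,
) -> StateTrace:
    """Run the detector over an LD stream (pure function of its inputs)."""
    if isinstance(ld, LDStream):
        values, times = ld.ld, ld.times
    else:
        values = np.asarray(ld, float)
        if times is None:
            times = np.arange(len(values)) * cfg.update_interval
    if len(values) == 0:
        raise ValueError("empty LD stream")
    det = Detector(cfg, initial_state)
    states = np.empty(len(values), dtype=int)
    for k, (t, v) in enumerate(zip(times, values)):
        states[k] = det.step(float(t), float(v))
    return StateTrace(np.asarray(times, float), states, det.changes,
                      cfg.update_interval)


def duty_cycle(trace: StateTrace) -> dict[int, float]:
    """Fraction of update-grid time spent in each state (fractions sum to 1)."""
    if len(trace) == 0:
        raise ValueError("empty state trace")
    states, counts = np.unique(trace.state, return_counts=True)
    return {int(s): float(c) / len(trace) for s, c in zip(states, counts)}


@dataclass(frozen=True)
class LockEpisode:
    """A dwell in a stimulation-delivering state exceeding the allowed time."""

    start: float
    end: float
    state: int
    ongoing: bool  # True if the episode runs to the end of the trace

    @property
    def dwell(self) -> float:
        return self.end - self.start


def detect_lock(
    trace: StateTrace, max_dwell: float, stim_states: tuple[int, ...] = (1,)
) -> list[LockEpisode]:
    """Find episodes where a stimulation-on state persists beyond ``max_dwell``.

    An empty list means the configuration never locked.  ``stim_states``
    names the states that deliver stimulation (for a three-state "catch"
    configuration, typically just state 1).
    """
    if max_dwell <= 0:
        raise ValueError("max_dwell must be positive")
    if len(trace) == 0:
        return []
    dt = trace.update_interval or 1.0
    episodes: list[LockEpisode] = []
    s = trace.state
    t = trace.times
    start = 0 if s[0] in stim_states else None
    for k in range(1, len(s) + 1):
        boundary = k == len(s) or s[k] != s[k - 1]
        if boundary and start is not None and s[k - 1] in stim_states:
            end_t = t[k - 1] + dt if k == len(s) else t[k]
            dwell = end_t - t[start]
            if dwell > max_dwell:
                episodes.append(
                    LockEpisode(float(t[start]), float(end_t), int(s[k - 1]),
                                ongoing=(k == len(s)))
                )
            start = None
        if k < len(s) and s[k] != s[k - 1]:
            start = k if s[k] in stim_states else None
    return episodes
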