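"""Programming heuristics as executable procedures.

Clinicians tune closed-loop detectors with a handful of data-driven rules:
pick thresholds as percentiles of the historical LD distribution (a
threshold at the 50th percentile leaves future LD values above and below it
about half the time each), sweep control-parameter combinations in a grid
search scored on detection agreement / energy / lock behavior, and
characterize the patient's wash-in and wash-out time constants from
open-loop stimulation steps.  This module implements each of those.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .detector import StateTrace, detect_lock, run_detector
from .discriminant import LDStream
from .stimulation import PatientModel, energy_delivered
from .synthetic import SymptomTrace

__all__ = [
    "ThresholdReport",
    "select_threshold",
    "GridSearchResult",
    "grid_search",
    "washin_washout",
    "evaluate_detection",
]

PERCENTILE_CONVENTION = "linear interpolation between order statistics"


@dataclass
class ThresholdReport:
    """Audit record for percentile-based threshold selection."""

    bin_edges: np.ndarray
    counts: np.ndarray
    percentiles: list[float]
    thresholds: list[float]
    predicted_duty: list[float]  # expected above-threshold fraction per threshold
    reference: dict[float, float]  # 25/50/75th percentile LD values
    convention: str = PERCENTILE_CONVENTION


def select_threshold(
    ld: LDStream | np.ndarray,
    percentiles: float | Sequence[float],
    n_bins: int = 50,
) -> tuple[list[float], ThresholdReport]:
    """Thresholds as empirical percentiles of the LD distribution.

    The percentile of a threshold is inversely related to how often the
    device sits in a higher state: a single threshold at percentile p leaves
    the LD above it a fraction (100 − p)/100 of the time on stationary data
    (the report's ``predicted_duty``).
    """
    values = ld.ld if isinstance(ld, LDStream) else np.asarray(ld, float)
    if len(values) < 100:
        raise ValueError(f"need >= 100 LD updates, got {len(values)}")
    ps = [float(p) for p in np.atleast_1d(percentiles)]
    if any(not 0 < p <= 100 for p in ps):
        raise ValueError("percentiles must lie in (0, 100]")
    if any(b <= a for a, b in zip(ps, ps[1:])):
        raise ValueError("percentiles must be strictly increasing")
    thresholds = [float(np.percentile(values, p)) for p in ps]
    counts, edges = np.histogram(values, bins=n_bins)
    report = ThresholdReport(
        bin_edges=edges,
        counts=counts,
        percentiles=ps,
        thresholds=thresholds,
        predicted_duty=[1.0 - p / 100.0 for p in ps],
        reference={p: float(np.percentile(values, p)) for p in (25, 50, 75)},
    )
    return thresholds, report


def evaluate_detection(
    states: StateTrace,
    trace: SymptomTrace,
    positive_states: tuple[int, ...] = (1, 2),
    latency_window: int = 10,
) -> dict[str, float]:
    """Compare detector states to symptom states on the update grid.

    The symptom state is resampled by previous-value hold.  Detection is
    positive when the detector is in any of ``positive_states``.  Latency is
    the lag (in seconds, positive = detector late) maximizing agreement over
    ± ``latency_window`` updates; among equally good lags the smallest in
    magnitude wins.
    """
    if states.times[-1] < trace.times[0] or states.times[0] > trace.times[-1]:
        raise ValueError("detector and symptom time supports do not overlap")
    det = np.isin(states.state, positive_states).astype(int)
    sym = trace.state_at(states.times)
    agreement = float(np.mean(det == sym))
    pos = sym == 1
    sensitivity = float(np.mean(det[pos])) if pos.any() else np.nan
    fpr = float(np.mean(det[~pos])) if (~pos).any() else np.nan

    upd = states.update_interval or (
        float(states.times[1] - states.times[0]) if len(states) > 1 else 1.0
    )
    best_lag, best_agree = 0, -1.0
    for lag in range(-latency_window, latency_window + 1):
        if lag >= 0:
            a = det[lag:] if lag else det
            b = sym[: len(sym) - lag] if lag else sym
        else:
            a, b = det[:lag], sym[-lag:]
        if len(a) == 0:
            continue
        score = float(np.mean(a == b))
        if score > best_agree + 1e-12 or (
            abs(score - best_agree) <= 1e-12 and abs(lag) < abs(best_lag)
        ):
            best_agree, best_lag = score, lag
    return {
        "agreement": agreement,
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "latency": best_lag * upd,
    }


@dataclass
class GridSearchResult:
    """Outcome of a control-parameter grid search."""

    table: pd.DataFrame  # one row per cell: parameters + metrics + score
    chosen: dict  # parameter values of the selected cell
    objective_weights: dict[str, float] = field(default_factory=dict)

    @property
    def chosen_row(self) -> pd.Series:
        return self.table.loc[self.table["score"].idxmin()]


DEFAULT_OBJECTIVE = {"miss": 1.0, "energy": 0.2, "lock": 10.0}


def grid_search(
    run_cell: Callable[[dict, int], dict],
    grid: dict[str, Sequence],
    seed: int = 0,
    objective_weights: dict[str, float] | None = None,
    cell_cap: int = 500,
) -> GridSearchResult:
    """Systematic sweep over control-parameter combinations.

    ``run_cell(params, seed)`` must run the closed loop for one parameter
    combination and return a metrics dict with keys ``agreement``,
    ``energy`` and ``locks`` (lock-episode count).  The same seed is passed
    to every cell (common random numbers), so comparisons across cells see
    identical symptom and noise realizations.  Cells are scored by

        w_miss · (1 − agreement) + w_energy · energy/max(energy) + w_lock · 1[locks > 0]

    and the lowest score wins (earliest cell on ties).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must have at least one candidate per axis")
    names = list(grid)
    cells = list(itertools.product(*(grid[n] for n in names)))
    if len(cells) > cell_cap:
        raise ValueError(f"{len(cells)} cells exceed the cap ({cell_cap})")
    weights = dict(DEFAULT_OBJECTIVE, **(objective_weights or {}))

    rows = []
    for values in cells:
        params = dict(zip(names, values))
        metrics = run_cell(params, seed)
        rows.append({**params, **metrics})
    table = pd.DataFrame(rows)
    e = table["energy"].to_numpy(float)
    e_norm = e / e.max() if e.max() > 0 else np.zeros_like(e)
    table["score"] = (
        weights["miss"] * (1.0 - table["agreement"].to_numpy(float))
        + weights["energy"] * e_norm
        + weights["lock"] * (table["locks"].to_numpy(float) > 0)
    )
    best = int(table["score"].idxmin())
    chosen = {n: table.loc[best, n] for n in names}
    return GridSearchResult(table, chosen, weights)


def _exp_relax(t, tau, s0, s_inf):
    return s_inf + (s0 - s_inf) * np.exp(-t / tau)


def washin_washout(
    patient: PatientModel,
    protocol: tuple[np.ndarray, np.ndarray],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    amp_max: float | None = None,
) -> dict:
    """Estimate wash-in / wash-out time constants from an open-loop step test.

    ``protocol`` is ``(times, amplitude)`` containing one 0 -> on step and
    one on -> 0 step.  The patient model is simulated along the protocol
    with observation noise, and a single-exponential relaxation is fitted by
    least squares to each post-step segment.

    Returns a dict with ``tau_in``, ``tau_out``, residual RMS per segment,
    and convergence flags.
    """
    times, amps = (np.asarray(a, float) for a in protocol)
    if times.shape != amps.shape or len(times) < 4:
        raise ValueError("protocol must be aligned (times, amplitude) series")
    rng = np.random.default_rng(seed)
    a_max = amp_max or (amps.max() if amps.max() > 0 else 1.0)
    dt = float(times[1] - times[0])

    score = float(patient.baseline.score_at(times[0]))
    sim = np.empty_like(times)
    for i, t in enumerate(times):
        b = float(patient.baseline.score_at(t))
        score = patient.step_score(score, b, amps[i] / a_max, dt)
        sim[i] = score
    obs = sim + rng.normal(0.0, noise_sd, len(sim)) if noise_sd > 0 else sim

    prev = np.concatenate([[amps[0]], amps[:-1]])
    on_steps = np.flatnonzero((prev == 0) & (amps > 0))
    off_steps = np.flatnonzero((prev > 0) & (amps == 0))
    if len(on_steps) == 0 or len(off_steps) == 0:
        raise ValueError("protocol needs one on-step and one off-step")

    out: dict = {}
    for label, start, true_tau in (
        ("in", on_steps[0], patient.tau_in),
        ("out", off_steps[0], patient.tau_out),
    ):
        later = [i for i in np.concatenate([on_steps, off_steps]) if i > start]
        stop = min(later) if later else len(times)
        seg_t = times[start:stop] - times[start]
        seg_y = obs[start:stop]
        p0 = (max(seg_t[-1] / 3.0, dt), seg_y[0], seg_y[-1])
        converged = True
        try:
            popt, _ = curve_fit(_exp_relax, seg_t, seg_y, p0=p0, maxfev=10000)
            tau_hat = abs(float(popt[0]))
            resid = float(np.sqrt(np.mean((_exp_relax(seg_t, *popt) - seg_y) ** 2)))
        except RuntimeError:
            converged = False
            tau_hat, resid = np.nan, np.nan
        out[f"tau_{label}"] = tau_hat
        out[f"residual_rms_{label}"] = resid
        out[f"converged_{label}"] = converged
    return out
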