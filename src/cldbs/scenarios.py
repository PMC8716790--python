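"""Packaged end-to-end scenarios.

Bundles a patient model, biomarkers, and device configuration into ready-to-
run closed-loop setups used throughout the examples and tests:

* ``high_snr_scenario`` — a strong theta biomarker, no stimulation artifact:
  the tuned detector should track the symptom state closely.
* ``artifact_lock_scenario`` — stimulation artifact couples straight into
  the biomarker band, so a plain single-threshold detector locks into a
  perpetual stimulation-delivering state; two countermeasures are available:
  a third "catch" state (second threshold with stimulation off) or a
  negatively weighted second feature tracking stimulation-band power.

Calibration mirrors clinical practice: an open-loop (stimulation-free)
recording of the same patient supplies the normalization constants, LD
weights, class LD levels, and the LD distribution that percentile-based
threshold selection draws from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .detector import DetectorConfig, detect_lock
from .discriminant import LDConfig, fit_lda, ld_output, normalize
from .sensing import Band, SenseConfig, compute_band_power
from .stimulation import (
    ClosedLoopTrace,
    PatientModel,
    StimConfig,
    energy_delivered,
    simulate_closed_loop,
)
from .synthetic import (
    ArtifactSpec,
    BiomarkerSpec,
    SymptomDynamics,
    generate_lfp,
    generate_symptom_trace,
    inject_stim_artifacts,
)
from .tuning import evaluate_detection, select_threshold

__all__ = [
    "Scenario",
    "calibrate_ld",
    "high_snr_scenario",
    "artifact_lock_scenario",
    "closed_loop_cell_runner",
]

THETA = Band(label="theta", low=4.0, high=8.0)
STIM_BAND = Band(label="stim", low=30.0, high=34.0)


@dataclass
class Scenario:
    """Everything needed to run (and re-run) one closed-loop experiment."""

    patient: PatientModel
    biomarkers: list[BiomarkerSpec]
    sense_cfg: SenseConfig
    ld_cfg: LDConfig
    det_cfg: DetectorConfig
    stim_cfg: StimConfig
    duration: float
    fs: float = 250.0
    background_rms: float = 0.5
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    calibration_ld: np.ndarray | None = None  # open-loop LD sample for tuning
    max_dwell: float = 30.0  # lock-detection allowance, s

    def run(self, seed: int = 0) -> ClosedLoopTrace:
        return simulate_closed_loop(
            self.patient,
            self.biomarkers,
            self.sense_cfg,
            self.ld_cfg,
            self.det_cfg,
            self.stim_cfg,
            self.duration,
            seed,
            fs=self.fs,
            artifacts=self.artifacts,
            background_rms=self.background_rms,
        )


def calibrate_ld(
    trace,
    biomarkers,
    sense_cfg: SenseConfig,
    features: list[str],
    seed: int,
    *,
    fs: float = 250.0,
    background_rms: float = 0.5,
    weights: list[float] | None = None,
    avg_len: int = 1,
) -> tuple[LDConfig, np.ndarray, np.ndarray]:
    """Fit LD parameters from an open-loop (stimulation-free) recording.

    Generates a stimulation-free recording of the patient's symptom trace,
    extracts features, fits the default normalization, fits Fisher weights
    (unless supplied), and places a single threshold midway between the two
    class LD means.  Returns (ld_cfg, calibration LD values, labels).
    """
    rec = generate_lfp(
        trace, biomarkers, fs=fs, seed=seed, background_rms=background_rms
    )
    stream = compute_band_power(rec, sense_cfg)
    cols = [stream.names.index(f) for f in features]
    sub_means = stream.values[:, cols].mean(axis=0)
    sub_sds = stream.values[:, cols].std(axis=0, ddof=1)
    if np.any(sub_sds == 0):
        raise ValueError("zero-variance calibration feature")
    z = (stream.values[:, cols] - sub_means) / sub_sds
    labels = trace.state_at(stream.times)
    if weights is None:
        w = fit_lda(z, labels)
    else:
        w = np.asarray(weights, float)
        w = w / np.linalg.norm(w)
    cfg = LDConfig(
        features=features,
        weights=[float(v) for v in w],
        norm_mean=[float(v) for v in sub_means],
        norm_sd=[float(v) for v in sub_sds],
        thresholds=[0.0],  # placeholder, replaced below
        avg_len=avg_len,
    )
    ld = ld_output(stream, cfg).ld
    mu0, mu1 = ld[labels == 0].mean(), ld[labels == 1].mean()
    cfg = cfg.model_copy(update={"thresholds": [float((mu0 + mu1) / 2)]})
    return cfg, ld, labels


def high_snr_scenario(seed: int = 0, duration: float = 600.0) -> Scenario:
    """Strong biomarker, artifact-free sensing: the well-behaved case.

    Theta band power jumps 1 -> 10 µV² with the symptom state against a
    0.5 µV RMS pink background, so the LD classes separate cleanly and the
    detector state should closely follow the symptom state.
    """
    rng = np.random.default_rng(seed)
    dyn = SymptomDynamics(
        baseline=4.0,
        diurnal_amplitude=0.0,
        transition_rate=1.0 / 120.0,
        transition_amplitude=3.0,
        noise_sd=0.2,
    )
    trace = generate_symptom_trace(
        duration, dyn, cutoff=5.0, seed=int(rng.integers(2**31)),
        require_both_states=True,
    )
    biomarkers = [
        BiomarkerSpec(channel=0, band=(4.0, 8.0), power_low=1.0, power_high=10.0)
    ]
    sense_cfg = SenseConfig(
        window_length=256, update_interval=0.5, bands=[THETA], channels=["ch1"]
    )
    ld_cfg, cal_ld, _ = calibrate_ld(
        trace, biomarkers, sense_cfg, ["ch1:theta"],
        seed=int(rng.integers(2**31)), avg_len=4,
    )
    det_cfg = DetectorConfig(
        thresholds=ld_cfg.thresholds,
        onset_counter=3,
        termination_counter=3,
        blanking=1.0,
        update_interval=0.5,
    )
    stim_cfg = StimConfig(state_targets={0: 0.0, 1: 2.0}, ramp_s=2.0)
    patient = PatientModel(tau_in=30.0, tau_out=30.0, relief=0.5, baseline=trace)
    # genuine sustained stimulation during a long pain episode is not a
    # lock, so the dwell allowance spans the whole recording here
    return Scenario(
        patient, biomarkers, sense_cfg, ld_cfg, det_cfg, stim_cfg,
        duration, calibration_ld=cal_ld, max_dwell=duration,
    )


def artifact_lock_scenario(
    countermeasure: str | None = None,
    seed: int = 0,
    duration: float = 600.0,
    artifact_gain: float = 3.0,
) -> Scenario:
    """Stimulation artifact inside the biomarker band; optionally defended.

    The symptom follows a deterministic slow cycle (high mid-recording, low
    afterwards).  Stimulation couples a 6 Hz tonic artifact into the sensed
    theta band at ``artifact_gain`` µV/mA, so once stimulation turns on the
    LD stays above threshold regardless of the true biomarker.

    countermeasure:
        None — plain single-threshold detector; locks on.
        "catch" — second threshold with a stimulation-off third state.
        "negative_weight" — second LD input tracking 30-34 Hz
            stimulation-band power with a negative weight.
    """
    if countermeasure not in (None, "catch", "negative_weight"):
        raise ValueError(f"unknown countermeasure {countermeasure!r}")
    rng = np.random.default_rng(seed)
    dyn = SymptomDynamics(
        baseline=4.0,
        diurnal_amplitude=2.0,
        diurnal_period=duration,
        transition_rate=0.0,
        transition_amplitude=0.0,
        noise_sd=0.0,
    )
    trace = generate_symptom_trace(duration, dyn, cutoff=5.0, seed=0)
    biomarkers = [
        BiomarkerSpec(channel=0, band=(4.0, 8.0), power_low=1.0, power_high=10.0)
    ]
    stim_amp = 2.0
    gains = {"ch1": [(6.0, artifact_gain)]}
    bands = [THETA]
    features = ["ch1:theta"]
    weights = None
    if countermeasure == "negative_weight":
        gains["ch1"].append((32.0, artifact_gain))
        bands = [THETA, STIM_BAND]
        features = ["ch1:theta", "ch1:stim"]
        weights = [0.8, -0.6]
    sense_cfg = SenseConfig(
        window_length=256, update_interval=0.5, bands=bands, channels=["ch1"]
    )
    ld_cfg, cal_ld, labels = calibrate_ld(
        trace, biomarkers, sense_cfg, features,
        seed=int(rng.integers(2**31)), avg_len=2, weights=weights,
    )
    thresholds = list(ld_cfg.thresholds)
    if countermeasure == "catch":
        # Place t2 between the genuine high-symptom LD level and the
        # artifact-inflated level, measured from an open-loop recording
        # made *during* stimulation: features must be characterized under
        # the stimulation that will actually be used.
        rec = generate_lfp(
            trace, biomarkers, fs=250.0, seed=int(rng.integers(2**31)),
            background_rms=0.5,
        )
        rec_stim = inject_stim_artifacts(
            rec, np.full(rec.n_samples, stim_amp), gains
        )
        stream_stim = compute_band_power(rec_stim, sense_cfg)
        ld_stim = ld_output(stream_stim, ld_cfg).ld
        labels_stim = trace.state_at(stream_stim.times)
        ld_artifact_low = float(ld_stim[labels_stim == 0].mean())
        ld_high = float(cal_ld[labels == 1].mean())
        thresholds = [thresholds[0], float((ld_high + ld_artifact_low) / 2)]
        ld_cfg = ld_cfg.model_copy(update={"thresholds": thresholds})
        state_targets = {0: 0.0, 1: stim_amp, 2: 0.0}
    else:
        state_targets = {0: 0.0, 1: stim_amp}
    # For the catch configuration, release from the stimulation-on state must
    # outrun the artifact re-entering the sensing window as stimulation ramps
    # back up, so t1 gets a 1-update termination counter and short blanking.
    overrides = {0: (2, 1), 1: (2, 2)} if countermeasure == "catch" else {}
    det_cfg = DetectorConfig(
        thresholds=thresholds,
        onset_counter=2,
        termination_counter=2,
        blanking=0.5 if countermeasure == "catch" else 1.0,
        counter_overrides=overrides,
        update_interval=0.5,
    )
    stim_cfg = StimConfig(
        state_targets=state_targets,
        ramp_s=2.0,
        artifact_gains=gains,
        transient_magnitude=20.0,
        transient_decay_s=0.05,
    )
    patient = PatientModel(tau_in=30.0, tau_out=30.0, relief=0.0, baseline=trace)
    return Scenario(
        patient, biomarkers, sense_cfg, ld_cfg, det_cfg, stim_cfg,
        duration, calibration_ld=cal_ld,
    )


def closed_loop_cell_runner(scenario: Scenario):
    """Adapter turning a Scenario into a ``grid_search`` cell function.

    Supported grid axes: ``onset_counter``, ``termination_counter``,
    ``blanking``, ``ramp_s``, ``percentile`` (threshold re-selected at that
    percentile of the scenario's open-loop calibration LD distribution).
    """

    def run_cell(params: dict, seed: int) -> dict:
        det = scenario.det_cfg
        stim = scenario.stim_cfg
        ld_cfg = scenario.ld_cfg
        det_updates = {
            k: params[k]
            for k in ("onset_counter", "termination_counter", "blanking")
            if k in params
        }
        if "percentile" in params:
            if scenario.calibration_ld is None:
                raise ValueError("scenario lacks calibration LD for percentiles")
            thr, _ = select_threshold(
                scenario.calibration_ld, params["percentile"]
            )
            det_updates["thresholds"] = thr
            ld_cfg = ld_cfg.model_copy(update={"thresholds": thr})
        if det_updates:
            det = det.model_copy(update=det_updates)
        if "ramp_s" in params:
            stim = stim.model_copy(update={"ramp_s": params["ramp_s"]})
        sc = replace(scenario, det_cfg=det, stim_cfg=stim, ld_cfg=ld_cfg)
        cl = sc.run(seed)
        metrics = evaluate_detection(
            cl.state_trace, cl.symptom_trace(scenario.patient.baseline.cutoff)
        )
        energy = energy_delivered(
            cl.amp_eff, stim, det.update_interval, per_hour=True
        )
        locks = detect_lock(cl.state_trace, scenario.max_dwell)
        return {
            "agreement": metrics["agreement"],
            "false_positive_rate": metrics["false_positive_rate"],
            "energy": energy,
            "locks": len(locks),
        }

    return run_cell
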