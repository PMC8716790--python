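# cldbs — closed-loop DBS simulation and tuning

`cldbs` is a desk-scale simulator and tuning toolkit for **closed-loop
(adaptive) deep brain stimulation** as practiced on sense-enabled implants
such as the Medtronic Activa PC+S and Summit RC+S. It is aimed at
researchers and engineers who program such devices for neuropsychiatric
indications (the packaged scenarios model chronic pain) and who want to
rehearse, stress-test, and tune the embedded detection pipeline without a
patient or a device — entirely on synthetic local field potential (LFP) and
symptom data.

## The pipeline it emulates

Sense-enabled implants run a fixed on-board chain:

1. **Band-power features.** At each FFT update (interval Δ seconds), the
   trailing window of the sensed LFP yields average spectral power in one or
   two configured bands (e.g. theta, 4–8 Hz), the *features* x.
2. **Linear discriminant (LD).** Features are z-scored against stored
   constants and combined with signed weights:

   LD = Σᵢ wᵢ · (xᵢ − μᵢ)/σᵢ,

   then smoothed by a trailing moving average of length L updates. Weights
   come from Fisher's discriminant, w ∝ S_w⁻¹(m₁ − m₀), fitted on labeled
   open-loop recordings; the default normalization gives each feature mean 0
   and standard deviation 1.
3. **Thresholded state machine.** The LD is compared against 1 threshold
   (2 device states) or 2 thresholds (3 states). A state change requires the
   LD to stay on the qualifying side for a configured number of
   *consecutive* updates, so the onset/termination **duration** equals
   counter × Δ; a post-change **blanking** window suppresses further
   counting.
4. **Ramped stimulation.** Each state maps to a target amplitude; the
   delivered amplitude slews linearly at `max(target)/ramp_s` mA/s (a 2 s
   ramp with a 1 s dwell reaches only 50% of target). Delivered energy is
   tracked with a TEED-style proxy Σ a(t)²·f·pw·Δt.
5. **Feedback.** Stimulation couples back into sensing as tonic and
   transient artifacts, and relieves the modeled symptom with first-order
   wash-in/wash-out dynamics — closing the loop, including its pathologies
   (the artifact-driven "lock", where stimulation never terminates, and the
   two published countermeasures: a third "catch" state and a negatively
   weighted stimulation-tracking feature).

The tuning module turns the standard programming heuristics into code:
percentile-based threshold selection (a threshold at the p-th percentile of
historical LD values leaves future values above it ≈ (100 − p)% of the
time), control-parameter grid search with common random numbers, and
wash-in/wash-out time-constant estimation from open-loop step tests.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_closed_loop_high_snr.py` simulates ten minutes of a
patient with a strong theta biomarker (band power 1 → 10 µV² across the
pain cutoff) under a calibrated single-threshold detector and prints:

```
10-minute closed-loop run, 1200 detector updates
detector/symptom agreement:  0.970
sensitivity:                 0.942
false-positive rate:         0.012
detection latency:           2.0 s
energy proxy:                6.31e+07 mA^2*Hz*us*s per hour
lock episodes:               0
```

Agreement is the fraction of FFT updates on which the detector state
matches the modeled symptom state; latency is the lag maximizing that
agreement (here: the 2 s implied by the onset counter × update interval);
the energy proxy is the battery-longevity surrogate. A companion script,
`examples/06_artifact_lock_countermeasures.py`, shows the same loop locking
into permanent stimulation when artifact enters the biomarker band, and
both countermeasures releasing it.

There is also a thin CLI mirroring the library
(`cldbs simulate | sense | fit-ld | ld-run | detect | run | tune-threshold |
grid-search | washin | fixtures | verify`), driven by a single YAML config
with one global seed; `cldbs verify` re-runs a configuration twice and
compares output hashes.

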