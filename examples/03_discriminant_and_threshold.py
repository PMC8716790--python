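"""Fit the embedded linear discriminant and pick thresholds by percentile.

The LD is a weighted sum of z-scored band powers; thresholds are chosen as
percentiles of the historical LD distribution, whose percentile directly
predicts the fraction of time the device will sit above threshold.
"""

import numpy as np

from cldbs import BiomarkerSpec, generate_symptom_trace, select_threshold
from cldbs.scenarios import calibrate_ld
from cldbs.sensing import Band, SenseConfig
from cldbs.synthetic import SymptomDynamics

dynamics = SymptomDynamics(baseline=4.0, diurnal_amplitude=0.0,
                           transition_rate=1 / 120, transition_amplitude=3.0,
                           noise_sd=0.2)
trace = generate_symptom_trace(900.0, dynamics, cutoff=5.0, seed=5,
                               require_both_states=True)
biomarker = BiomarkerSpec(channel=0, band=(4.0, 8.0), power_low=1.0,
                          power_high=10.0)
sense = SenseConfig(window_length=256, update_interval=0.5,
                    bands=[Band(label="theta", low=4, high=8)], channels=["ch1"])

ld_cfg, calibration_ld, labels = calibrate_ld(
    trace, [biomarker], sense, ["ch1:theta"], seed=6, avg_len=4
)
print(f"fitted weights: {ld_cfg.weights} on {ld_cfg.features}")
print(f"normalization: mean={ld_cfg.norm_mean[0]:.3f}, sd={ld_cfg.norm_sd[0]:.3f}")
print(f"class LD means: low={calibration_ld[labels == 0].mean():.2f}, "
      f"high={calibration_ld[labels == 1].mean():.2f}; "
      f"midpoint threshold {ld_cfg.thresholds[0]:.3f}")

thresholds, report = select_threshold(calibration_ld, (25.0, 75.0))
print(f"\npercentile thresholds: 25th -> {thresholds[0]:.3f}, "
      f"75th -> {thresholds[1]:.3f} ({report.convention})")
for p, duty in zip(report.percentiles, report.predicted_duty):
    above = np.mean(calibration_ld >= np.percentile(calibration_ld, p))
    print(f"  threshold at the {p:.0f}th percentile: predicted "
          f"{100 * duty:.0f}% of time above; observed {100 * above:.1f}%")
print("-> a lower percentile threshold means more time above threshold and")
print("   therefore more frequent (or higher-amplitude) stimulation.")
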