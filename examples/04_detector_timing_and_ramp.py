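"""Detector timing arithmetic and the ramp worked example.

Onset/termination durations are counter x FFT update interval; the ramp
rate bounds how much amplitude a short stimulation bout can deliver: with a
2 s ramp and a 1 s dwell the amplitude peaks at 50% of target.
"""

import numpy as np

from cldbs import DetectorConfig, StateTrace, StimConfig, apply_ramp, run_detector

upd = 0.5  # FFT update interval, s
det = DetectorConfig(thresholds=[0.5], onset_counter=4, termination_counter=2,
                     update_interval=upd)
print(f"onset counter {det.onset_counter} x {upd} s updates "
      f"= {det.onset_duration} s onset duration")

ld = np.r_[np.zeros(3), np.ones(7), np.zeros(5)]
trace = run_detector(ld, det)
t, frm, to, cause = trace.changes[0]
print(f"supra-threshold run starts at t=1.5 s; state rises {frm}->{to} at "
      f"t={t} s ({cause}): exactly the 4th consecutive supra-threshold update")

stim = StimConfig(state_targets={0: 0.0, 1: 2.0}, ramp_s=2.0)
states = StateTrace(np.arange(8) * upd, np.array([0, 0, 1, 1, 0, 0, 0, 0]),
                    [], upd)
_, amp = apply_ramp(states, stim, dt=0.005)
print(f"\nramp rate 2 s, stimulation-on dwell 1 s: peak effective amplitude "
      f"{amp.max():.2f} mA = {100 * amp.max() / 2.0:.0f}% of the 2.0 mA target")
print("-> ramps should reach target faster than the onset duration, or bouts")
print("   deliver only a fraction of the programmed dose.")
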