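"""Stimulation artifact in the biomarker band: the lock and its two fixes.

When stimulation couples into the sensed biomarker band, a plain single-
threshold detector sees an artifactually high LD forever and never turns
stimulation off ("lock"). Two countermeasures release it:
  * a third "catch" state above a second threshold, with stimulation off;
  * a second LD input tracking stimulation-band power with a negative weight.
"""

import numpy as np

from cldbs import artifact_lock_scenario, detect_lock

for label, countermeasure in [
    ("plain single threshold", None),
    ('three-state "catch"', "catch"),
    ("negative-weight stim feature", "negative_weight"),
]:
    scenario = artifact_lock_scenario(countermeasure, seed=17)
    cl = scenario.run(seed=18)
    locks = detect_lock(cl.state_trace, scenario.max_dwell)
    stim_frac = float(np.mean(cl.amp_eff > 0))
    print(f"{label:32s} lock episodes: {len(locks)}  "
          f"stim on {100 * stim_frac:5.1f}% of time  "
          f"final amplitude {cl.amp_eff[-1]:.1f} mA")

print("\n-> the plain detector stays locked on once the artifact appears;")
print("   both countermeasures terminate stimulation (no dwell beyond the")
print(f"   {artifact_lock_scenario(None).max_dwell:.0f} s allowance).")
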