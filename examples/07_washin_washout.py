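"""Characterize a patient's wash-in / wash-out response from step tests.

Open-loop stimulation is stepped on and then off; the modeled pain score
relaxes exponentially and the time constants are recovered by least-squares
fits. These estimates guide initial onset/termination durations.
"""

import numpy as np

from cldbs import PatientModel, washin_washout
from cldbs.synthetic import SymptomTrace

score = np.full(3000, 7.0)
baseline = SymptomTrace(np.arange(3000.0), score, (score >= 5).astype(int), 5.0)
patient = PatientModel(tau_in=120.0, tau_out=90.0, relief=3.0,
                       baseline=baseline)

times = np.arange(0.0, 3000.0, 1.0)
amplitude = np.where((times >= 300.0) & (times < 1500.0), 2.0, 0.0)

result = washin_washout(patient, (times, amplitude), noise_sd=0.3, seed=8)
print(f"true tau_in  = 120 s, estimated {result['tau_in']:6.1f} s "
      f"(fit residual RMS {result['residual_rms_in']:.3f})")
print(f"true tau_out =  90 s, estimated {result['tau_out']:6.1f} s "
      f"(fit residual RMS {result['residual_rms_out']:.3f})")
print("-> onset/termination durations shorter than these time constants")
print("   would switch stimulation faster than the patient can feel it.")
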