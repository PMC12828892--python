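"""Detect spontaneous and stimulation-evoked phasic pupil dilations.

The pupil trace is z-scored, upsampled 10 -> 100 Hz, and high-pass
filtered at 0.1 Hz.  A 10 s window slides in 0.01 s steps: its first 2 s
must stay below the 0.5 SD threshold, the first supra-threshold local
maximum is the dilation peak, and the trace must return below threshold
within 6 s.  Evoked peaks are the trace maxima within 6 s of each
stimulation onset.
"""

import numpy as np

from pupilstate import (SimConfig, detect_spontaneous_dilations,
                        locate_evoked_peaks, preprocess_pupil,
                        simulate_session)
from pupilstate.stats import interdilation_intervals

session = simulate_session(SimConfig(duration_s=600.0, seed=1))
trace = preprocess_pupil(session.pupil)

spont = detect_spontaneous_dilations(trace)
stim = np.asarray(session.stim_onsets)
# dilations peaking inside a stimulation-response window are evoked
spont = [e for e in spont
         if not np.any((stim < e.peak_time_s) & (e.peak_time_s <= stim + 6))]
evoked = locate_evoked_peaks(trace, stim)

print(f"spontaneous events detected: {len(spont)}")
print(f"evoked events detected:      {len(evoked)}")
iv = interdilation_intervals(spont)
print(f"interdilation interval:      mean {iv.mean_s:.1f} s, "
      f"median {iv.median_s:.1f} s")
for e in spont[:3]:
    print(f"  peak {e.peak_time_s:7.2f} s   baseline {e.baseline_z:+.2f} z"
          f"   amplitude {e.amplitude_z:+.2f} z")
# baseline = mean z over [-6, -4) s before the peak; amplitude = mean over
# [-2.5, 2.5) s around the peak minus that baseline
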