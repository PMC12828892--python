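"""Simulate one pupil+EEG session with known ground truth.

The generator plants phasic dilation events (difference-of-exponentials
kernel, unit peak) on slow pupil drift at 10 Hz, and builds EEG at
1000 Hz as a 1/f-with-knee background plus band-limited oscillations
whose envelopes follow the dilations with class-specific gains.
"""

from pupilstate import SimConfig, simulate_session

config = SimConfig(duration_s=600.0, seed=1)
session = simulate_session(config)

n_spont = sum(1 for _, lab in session.truth_events if lab == "spontaneous")
n_evoked = sum(1 for _, lab in session.truth_events if lab == "evoked")

print(f"session duration:      {config.duration_s:.0f} s")
print(f"stimulation onsets:    {len(session.stim_onsets)} "
      f"(every {config.stim_interval_s:.0f} s)")
print(f"spontaneous dilations: {n_spont}")
print(f"evoked dilations:      {n_evoked} "
      f"(peak {config.evoked_latency_s} s after each stimulation)")
print(f"pupil samples:         {session.pupil.n} at "
      f"{session.pupil.rate_hz:.0f} Hz")
print(f"EEG samples:           {session.eeg.n} at "
      f"{session.eeg.rate_hz:.0f} Hz")
# Each dilation peaks at its listed time; evoked events carry stronger
# gamma-band envelope gains than spontaneous ones by default.
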