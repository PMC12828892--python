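"""EEG band power on the pupil timebase and aperiodic spectral parameters.

EEG is low-pass filtered at 100 Hz (zero-phase, 6th order) and notch
filtered at 60 Hz; 1 s periodogram windows slide in 10 ms steps so the
band-power series (trapezoidal area under the PSD per canonical band)
shares the 100 Hz grid of the upsampled pupil signal.  The session
spectrum is parameterized as log10 P(f) = b - log10(k + f^chi) plus up to
three Gaussian peaks on 2-55 Hz.
"""

from pupilstate import (SimConfig, fit_aperiodic, preprocess_eeg,
                        session_normalized_psd, simulate_session,
                        sliding_band_power)

session = simulate_session(SimConfig(duration_s=600.0, seed=1))
eeg = preprocess_eeg(session.eeg)

series = sliding_band_power(eeg)
print(f"band-power series: {series[0].values.size} points at "
      f"{series[0].rate_hz:.0f} Hz per band")

spec, fractions = session_normalized_psd(eeg, n_segments=100, seed=2)
print("normalized power fraction per band (1-100 Hz total = 1):")
for name, frac in fractions.items():
    print(f"  {name:<10s} {frac:.3f}")

fit = fit_aperiodic(spec)
print(f"aperiodic fit: offset {fit.offset:.2f}, knee {fit.knee:.1f}, "
      f"exponent {fit.exponent:.2f} (R^2 = {fit.r_squared:.3f})")
print(f"oscillatory peaks: {len(fit.peaks)}")
for c, h, w in fit.peaks:
    print(f"  center {c:5.1f} Hz  height {h:.2f}  width {w:.1f} Hz")
# a smaller exponent means a flatter spectrum -- a more desynchronized,
# aroused cortical state
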