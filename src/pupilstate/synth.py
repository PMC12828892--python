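"""Synthetic pupil + EEG sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* the pupil is slow Gaussian drift (low-passed well below the analysis
  high-pass) plus phasic dilation events shaped as a difference of
  exponentials (fast rise, slower decay, unit peak), sampled at 10 Hz;
* spontaneous event times follow a Poisson process with a hard refractory
  interval so successive dilations are far enough apart for the
  return-to-baseline criterion to be meaningful; one evoked event follows
  each stimulation onset at a fixed latency;
* EEG is an aperiodic 1/f-with-knee background whose average periodogram
  follows ``log10 P(f) = b - log10(k + f**chi)``, plus band-limited
  Gaussian oscillations whose amplitude envelopes are ``1 + gain *
  kernel(t - peak + lag)`` with class-specific gains, sampled at 1000 Hz;
* stimulation onsets occur every ``stim_interval_s`` seconds starting at a
  random phase in the first interval.

Everything is deterministic given ``SimConfig.seed``: one master seed
spawns per-component child generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .pupil import ContractError, PupilTrace
from .spectral import BANDS, EEGTrace

#: default class-specific envelope gains (gain_spontaneous, gain_evoked, lag_s)
#: mimicking a shift of power from low to high frequencies around dilations,
#: stronger for stimulation-evoked events in the gamma bands.
DEFAULT_BAND_COUPLING = {
    "delta": (-0.2, -0.3, 0.0),
    "theta": (-0.3, -0.5, 0.0),
    "alpha": (-0.2, -0.5, 0.0),
    "beta": (0.1, -0.2, 0.0),
    "low_gamma": (0.4, 0.8, 0.0),
    "high_gamma": (0.5, 1.2, 0.0),
}


@dataclass(frozen=True)
class SimConfig:
    duration_s: float = 600.0
    pupil_rate_hz: float = 10.0
    eeg_rate_hz: float = 1000.0
    event_rate_per_s: float = 1.0 / 30.0
    refractory_s: float = 12.0
    kernel_rise_s: float = 0.5
    kernel_decay_s: float = 2.0
    event_amp_z: float = 2.0
    slow_noise_sd: float = 0.3
    slow_noise_cutoff_hz: float = 0.05
    stim_interval_s: float = 30.0
    stim_duration_s: float = 2.0
    evoked_latency_s: float = 2.5
    stim_exclusion_s: float = 10.0
    aperiodic_offset: float = 2.0
    aperiodic_knee: float = 10.0
    aperiodic_exponent: float = 2.0
    osc_strength: float = 1.0
    band_coupling: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_COUPLING))
    seed: int = 0

    def __post_init__(self):
        span = self.kernel_rise_s + self.kernel_decay_s
        if self.duration_s <= 20 * span:
            raise ContractError("duration must exceed 20 kernel spans")
        if self.pupil_rate_hz <= 0 or self.eeg_rate_hz <= 0:
            raise ContractError("sampling rates must be positive")
        if self.event_rate_per_s * self.duration_s < 1:
            raise ContractError("expected event count below 1")
        if self.aperiodic_exponent < 0 or self.aperiodic_knee < 0:
            raise ContractError("chi and knee must be non-negative")
        if self.event_amp_z < 0:
            raise ContractError("negative event amplitudes rejected")
        if self.refractory_s >= 1.0 / self.event_rate_per_s:
            raise ContractError("refractory interval exceeds the mean interval")
        for name, (gs, ge, _lag) in self.band_coupling.items():
            if gs < -1 or ge < -1:
                raise ContractError(
                    f"band {name}: envelope gains below -1 imply negative power")


@dataclass(frozen=True)
class SimSession:
    pupil: PupilTrace
    eeg: EEGTrace
    truth_events: tuple        # of (peak_time_s, label)
    stim_onsets: tuple         # seconds
    config: SimConfig


def _child_rngs(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4 + len(BANDS))
    names = ["events", "pupil_noise", "eeg_aperiodic", "spare"]
    rngs = {n: np.random.default_rng(k) for n, k in zip(names, kids[:4])}
    for band, k in zip(BANDS, kids[4:]):
        rngs[f"band_{band.name}"] = np.random.default_rng(k)
    return rngs


def dilation_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials dilation kernel, normalized to unit peak."""
    if decay_s <= rise_s:
        raise ContractError("decay must exceed rise")
    t = np.asarray(t, dtype=float)
    tp = np.clip(t, 0.0, None)
    k = np.where(t >= 0, np.exp(-tp / decay_s) - np.exp(-tp / rise_s), 0.0)
    t_peak = (rise_s * decay_s / (decay_s - rise_s)) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def kernel_peak_delay(rise_s: float, decay_s: float) -> float:
    """Time from kernel onset to its unit peak."""
    return (rise_s * decay_s / (decay_s - rise_s)) * np.log(decay_s / rise_s)


def _event_waveform(times: np.ndarray, event_times, amp: float,
                    rise_s: float, decay_s: float) -> np.ndarray:
    """Sum of peak-aligned kernels: each event's *peak* sits at its time."""
    out = np.zeros_like(times)
    delay = kernel_peak_delay(rise_s, decay_s)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    support = int(np.ceil((delay + 8 * decay_s) / dt))
    for te in event_times:
        onset = te - delay
        i0 = max(0, int(np.floor((onset - times[0]) / dt)))
        i1 = min(times.size, i0 + support)
        if i1 <= i0:
            continue
        out[i0:i1] += amp * dilation_kernel(times[i0:i1] - onset,
                                            rise_s, decay_s)
    return out


def _slow_noise(n: int, rate_hz: float, sd: float, cutoff_hz: float, rng):
    if sd == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    b, a = butter(4, cutoff_hz, btype="low", fs=rate_hz)
    x = filtfilt(b, a, x)
    s = np.std(x)
    return x * (sd / s) if s > 0 else x


def simulate_pupil(config: SimConfig, event_times) -> PupilTrace:
    """Pupil trace: slow drift plus unit-peak dilation kernels of amplitude
    ``event_amp_z`` peaking at each event time; 10 Hz; deterministic."""
    event_times = np.asarray(list(event_times), dtype=float)
    if event_times.size and (event_times.min() < 0
                             or event_times.max() > config.duration_s):
        raise ContractError("event times outside [0, duration_s]")
    rngs = _child_rngs(config.seed)
    n = int(round(config.duration_s * config.pupil_rate_hz))
    t = np.arange(n) / config.pupil_rate_hz
    x = _slow_noise(n, config.pupil_rate_hz, config.slow_noise_sd,
                    config.slow_noise_cutoff_hz, rngs["pupil_noise"])
    x += _event_waveform(t, event_times, config.event_amp_z,
                         config.kernel_rise_s, config.kernel_decay_s)
    return PupilTrace(values=x, rate_hz=config.pupil_rate_hz, t0_s=0.0,
                      state=("raw",))


def _aperiodic_noise(n: int, rate_hz: float, b: float, k: float, chi: float,
                     rng) -> np.ndarray:
    """Gaussian noise whose expected periodogram (density) is
    ``10**b / (k + f**chi)``."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate_hz)
    with np.errstate(divide="ignore"):
        psd = 10.0 ** b / (k + freqs ** chi)
    if not np.isfinite(psd[0]):
        psd[0] = 0.0
    amp = np.sqrt(psd * n * rate_hz / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    z /= np.sqrt(2.0)
    z[0] = rng.standard_normal()
    if n % 2 == 0:
        z[-1] = rng.standard_normal()
    return np.fft.irfft(z * amp, n=n)


def _band_power_aperiodic(config: SimConfig, band) -> float:
    f = np.linspace(band.f_lo, band.f_hi, 64)
    psd = 10.0 ** config.aperiodic_offset / (
        config.aperiodic_knee + f ** config.aperiodic_exponent)
    return float(np.trapezoid(psd, f))


def simulate_eeg(config: SimConfig, event_times, labels) -> EEGTrace:
    """EEG: aperiodic background plus per-band amplitude-modulated
    band-limited noise with class-specific envelope gains."""
    event_times = np.asarray(list(event_times), dtype=float)
    labels = list(labels)
    if len(labels) != event_times.size:
        raise ContractError("labels must align with event_times")
    rngs = _child_rngs(config.seed)
    n = int(round(config.duration_s * config.eeg_rate_hz))
    t = np.arange(n) / config.eeg_rate_hz
    x = _aperiodic_noise(n, config.eeg_rate_hz, config.aperiodic_offset,
                         config.aperiodic_knee, config.aperiodic_exponent,
                         rngs["eeg_aperiodic"])
    for band in BANDS:
        if band.name not in config.band_coupling:
            continue
        gs, ge, lag = config.band_coupling[band.name]
        rng = rngs[f"band_{band.name}"]
        w = rng.standard_normal(n)
        bb, ab = butter(4, (band.f_lo, band.f_hi), btype="band",
                        fs=config.eeg_rate_hz)
        w = filtfilt(bb, ab, w)
        w /= np.std(w)
        sigma = np.sqrt(config.osc_strength
                        * _band_power_aperiodic(config, band))
        env = np.ones(n)
        for te, lab in zip(event_times, labels):
            g = gs if lab == "spontaneous" else ge
            if g == 0:
                continue
            env += g * _peak_aligned_kernel(t, te - lag, config)
        env = np.clip(env, 0.0, None)
        x = x + sigma * w * env
    return EEGTrace(values=x, rate_hz=config.eeg_rate_hz, t0_s=0.0,
                    state="raw")


def _peak_aligned_kernel(t, peak_time, config: SimConfig):
    delay = kernel_peak_delay(config.kernel_rise_s, config.kernel_decay_s)
    return dilation_kernel(t - (peak_time - delay), config.kernel_rise_s,
                           config.kernel_decay_s)


def draw_stim_onsets(config: SimConfig, rng) -> np.ndarray:
    first = float(rng.uniform(0.0, config.stim_interval_s))
    if first == 0.0:
        first = config.stim_interval_s
    return np.arange(first, config.duration_s, config.stim_interval_s)


def draw_spontaneous_times(config: SimConfig, rng,
                           stim_onsets=()) -> np.ndarray:
    """Refractory Poisson event times, thinned so no event falls within
    ``stim_exclusion_s`` of a stimulation onset."""
    mean_gap = 1.0 / config.event_rate_per_s
    exp_mean = mean_gap - config.refractory_s
    times = []
    t = float(rng.exponential(mean_gap))
    while t < config.duration_s:
        times.append(t)
        t += config.refractory_s + float(rng.exponential(exp_mean))
    times = np.asarray(times)
    stim_onsets = np.asarray(list(stim_onsets), dtype=float)
    if stim_onsets.size:
        d = np.abs(times[:, None] - stim_onsets[None, :])
        times = times[d.min(axis=1) >= config.stim_exclusion_s]
    return times


def simulate_session(config: SimConfig) -> SimSession:
    """Full synthetic session with ground-truth events.

    Spontaneous times are a thinned refractory-Poisson process; each
    stimulation onset is followed by one evoked pupil peak at
    ``evoked_latency_s``.  Pupil and EEG are built from the union of event
    times with their class labels.
    """
    rngs = _child_rngs(config.seed)
    stim = draw_stim_onsets(config, rngs["events"])
    spont = draw_spontaneous_times(config, rngs["events"], stim)
    evoked = stim + config.evoked_latency_s
    evoked = evoked[evoked < config.duration_s]
    times = np.concatenate([spont, evoked])
    labels = ["spontaneous"] * spont.size + ["evoked"] * evoked.size
    order = np.argsort(times)
    times = times[order]
    labels = [labels[i] for i in order]
    pupil = simulate_pupil(config, times)
    eeg = simulate_eeg(config, times, labels)
    truth = tuple((float(t), lab) for t, lab in zip(times, labels))
    return SimSession(pupil=pupil, eeg=eeg, truth_events=truth,
                      stim_onsets=tuple(float(s) for s in stim),
                      config=config)
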