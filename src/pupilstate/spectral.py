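"""EEG filtering, sliding-window band power, and aperiodic parameterization.

EEG sampled at 1000 Hz is low-pass filtered at 100 Hz (zero-phase,
6th-order Butterworth) and 60 Hz notch filtered.  Power spectral densities
are computed on 1 s windows (1000 samples, plain FFT periodogram, density
normalization, 1 Hz grid) slid in 10 ms steps so the resulting band-power
series shares the 100 Hz grid of the upsampled pupil signal.  Band power is
the trapezoidal area under the PSD over each canonical band: delta (1-4),
theta (4-8), alpha (8-12), beta (12-30), low gamma (30-55) and high gamma
(65-100 Hz); the 55-65 Hz notch gap is excluded from every band.

The aperiodic (1/f-with-knee) backbone of a spectrum is parameterized as

    log10 PSD(f) = b - log10(k + f**chi) + sum of <=3 Gaussian peaks,

fit on 2-55 Hz with peak heights >= 0.1 log10-power and widths (2*sd)
bounded to [2, 10] Hz, following the standard spectral-parameterization
procedure: fit aperiodic, flatten, extract Gaussians iteratively, refit the
aperiodic on the peak-removed spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, filtfilt, iirnotch, periodogram

from .pupil import ContractError


@dataclass(frozen=True)
class EEGTrace:
    values: np.ndarray  # microvolts
    rate_hz: float = 1000.0
    t0_s: float = 0.0
    state: str = "raw"  # "raw" | "filtered"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ContractError("EEG trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("EEG trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ContractError("band edges must satisfy 0 < f_lo < f_hi")


#: canonical band set
BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("low_gamma", 30.0, 55.0),
    BandDefinition("high_gamma", 65.0, 100.0),
)
BAND_NAMES = tuple(b.name for b in BANDS)


@dataclass(frozen=True)
class SpectrumEstimate:
    freqs: np.ndarray       # Hz
    psd: np.ndarray         # uV^2/Hz (or normalized)
    window_span_s: float

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "psd", np.asarray(self.psd, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ContractError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ContractError("PSD must be non-negative")


@dataclass(frozen=True)
class BandPowerSeries:
    band: BandDefinition
    values: np.ndarray      # band AUC per window
    rate_hz: float = 100.0
    t0_s: float = 0.5       # center-of-window timestamp of the first window

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.rate_hz


@dataclass(frozen=True)
class AperiodicFit:
    offset: float           # b, log10 power
    knee: float             # k
    exponent: float         # chi
    peaks: tuple            # up to 3 (center_hz, height_log10, width_hz)
    r_squared: float
    fit_range: tuple[float, float] = (2.0, 55.0)
    converged: bool = True


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def preprocess_eeg(raw: EEGTrace, lowpass_hz: float = 100.0,
                   notch_hz: float = 60.0, notch_q: float = 30.0) -> EEGTrace:
    """Zero-phase 6th-order low-pass at 100 Hz followed by a narrow 60 Hz
    notch (2nd-order IIR, Q=30, zero-phase)."""
    if raw.duration_s < 5.0:
        raise ContractError("EEG trace shorter than 5 s rejected")
    b, a = butter(6, lowpass_hz, btype="low", fs=raw.rate_hz)
    x = filtfilt(b, a, raw.values)
    b, a = iirnotch(notch_hz, notch_q, fs=raw.rate_hz)
    x = filtfilt(b, a, x)
    return EEGTrace(values=x, rate_hz=raw.rate_hz, t0_s=raw.t0_s,
                    state="filtered")


# ---------------------------------------------------------------------------
# PSD and band power
# ---------------------------------------------------------------------------

WINDOW_SAMPLES = 1000
STEP_SAMPLES = 10


def window_psd(samples: np.ndarray, rate_hz: float = 1000.0) -> SpectrumEstimate:
    """One-sided rectangular-window periodogram of one 1 s window.

    Density normalization: ``trapz``-free Parseval identity
    ``sum(psd) * df == mean(x**2)`` holds to float precision (DC and
    Nyquist bins are not doubled).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size != WINDOW_SAMPLES:
        raise ContractError(f"window_psd requires exactly {WINDOW_SAMPLES} samples")
    freqs, psd = periodogram(samples, fs=rate_hz, window="boxcar",
                             detrend=False, scaling="density")
    return SpectrumEstimate(freqs=freqs, psd=psd,
                            window_span_s=samples.size / rate_hz)


def band_auc(spec: SpectrumEstimate, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi], endpoints included."""
    sel = (spec.freqs >= band.f_lo) & (spec.freqs <= band.f_hi)
    if sel.sum() < 2:
        raise ContractError(f"band {band.name} has no grid support")
    return float(np.trapezoid(spec.psd[sel], spec.freqs[sel]))


def _band_slices(freqs: np.ndarray, bands):
    out = []
    for band in bands:
        sel = np.flatnonzero((freqs >= band.f_lo) & (freqs <= band.f_hi))
        if sel.size < 2:
            raise ContractError(f"band {band.name} has no grid support")
        out.append((band, sel))
    return out


def sliding_band_power(eeg: EEGTrace, bands=BANDS,
                       chunk: int = 4096) -> list[BandPowerSeries]:
    """Band-power time series on the 100 Hz pupil grid.

    1 s windows stepped by 10 samples; for N EEG samples the series has
    ``(N - 1000)//10 + 1`` points, timestamped at window centers.
    """
    if eeg.state != "filtered":
        raise ContractError("sliding_band_power expects a filtered EEGTrace")
    v = eeg.values
    if v.size < WINDOW_SAMPLES:
        raise ContractError("EEG shorter than one analysis window")
    n_win = (v.size - WINDOW_SAMPLES) // STEP_SAMPLES + 1
    freqs = np.fft.rfftfreq(WINDOW_SAMPLES, 1.0 / eeg.rate_hz)
    slices = _band_slices(freqs, bands)
    out = np.empty((len(bands), n_win))
    scale = 2.0 / (eeg.rate_hz * WINDOW_SAMPLES)  # density periodogram
    windows = np.lib.stride_tricks.sliding_window_view(
        v, WINDOW_SAMPLES)[::STEP_SAMPLES]
    for lo in range(0, n_win, chunk):
        w = windows[lo:lo + chunk]
        spec = np.fft.rfft(w, axis=1)
        psd = (spec.real ** 2 + spec.imag ** 2) * scale
        psd[:, 0] /= 2.0
        psd[:, -1] /= 2.0
        for j, (band, sel) in enumerate(slices):
            out[j, lo:lo + w.shape[0]] = np.trapezoid(
                psd[:, sel], freqs[sel], axis=1)
    t0 = eeg.t0_s + (WINDOW_SAMPLES / eeg.rate_hz) / 2.0
    rate = eeg.rate_hz / STEP_SAMPLES
    return [BandPowerSeries(band=band, values=out[j], rate_hz=rate, t0_s=t0)
            for j, (band, sel) in enumerate(slices)]


def session_normalized_psd(eeg: EEGTrace, n_segments: int = 200,
                           segment_s: float = 2.0, seed=None,
                           bands=BANDS):
    """Session-level normalized spectrum from random 2 s segments.

    Draws ``n_segments`` non-overlapping segments (seeded), averages their
    periodograms, and divides by the total 1-100 Hz power so the normalized
    spectrum integrates to 1 over that range.  Returns the normalized
    spectrum and the per-band power fractions.
    """
    rng = np.random.default_rng(seed)
    seg = int(round(segment_s * eeg.rate_hz))
    n = eeg.n
    if n_segments * seg > n:
        raise ContractError("trace too short for the requested segments")
    # gap method: sorted draws plus cumulative segment lengths give
    # uniformly placed non-overlapping segments
    slack = n - n_segments * seg
    starts = (np.sort(rng.integers(0, slack + 1, size=n_segments))
              + np.arange(n_segments) * seg)
    acc = None
    for s in sorted(starts):
        freqs, psd = periodogram(eeg.values[s:s + seg], fs=eeg.rate_hz,
                                 window="boxcar", detrend=False,
                                 scaling="density")
        acc = psd if acc is None else acc + psd
    psd = acc / n_segments
    sel = (freqs >= 1.0) & (freqs <= 100.0)
    total = float(np.trapezoid(psd[sel], freqs[sel]))
    norm = psd / total
    spec = SpectrumEstimate(freqs=freqs, psd=norm, window_span_s=segment_s)
    fractions = {}
    for band in bands:
        bsel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        fractions[band.name] = float(np.trapezoid(norm[bsel], freqs[bsel]))
    return spec, fractions


# ---------------------------------------------------------------------------
# aperiodic parameterization
# ---------------------------------------------------------------------------

def _aperiodic_model(f, b, k, chi):
    return b - np.log10(k + f ** chi)


def _gaussian(f, center, height, sd):
    return height * np.exp(-((f - center) ** 2) / (2 * sd ** 2))


def _fit_aperiodic_curve(freqs, logpsd):
    """Bounded least squares of the knee model with multi-start."""
    best = None
    lo = (-np.inf, 0.0, 0.0)
    hi = (np.inf, np.inf, 10.0)
    for chi0 in (0.5, 1.0, 2.0):
        for k0 in (1e-3, 1.0, 10.0, 100.0):
            b0 = logpsd[0] + np.log10(k0 + freqs[0] ** chi0)
            try:
                popt, _ = curve_fit(_aperiodic_model, freqs, logpsd,
                                    p0=(b0, k0, chi0), bounds=(lo, hi),
                                    maxfev=5000)
            except RuntimeError:
                continue
            sse = float(np.sum((logpsd - _aperiodic_model(freqs, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise RuntimeError("aperiodic fit failed to converge")
    return best[1]


def _robust_aperiodic(freqs, logpsd):
    """Initial fit, then refit ignoring the most positive residuals
    (oscillatory peaks bias the backbone upward)."""
    popt = _fit_aperiodic_curve(freqs, logpsd)
    resid = logpsd - _aperiodic_model(freqs, *popt)
    thresh = np.percentile(resid, 97.5)
    keep = resid <= max(thresh, 0.0) + 1e-12
    if keep.sum() >= 5 and keep.sum() < freqs.size:
        popt = _fit_aperiodic_curve(freqs[keep], logpsd[keep])
    return popt


def fit_aperiodic(spec: SpectrumEstimate, fit_range=(2.0, 55.0),
                  max_n_peaks: int = 3, min_peak_height: float = 0.1,
                  peak_width_limits=(2.0, 10.0)) -> AperiodicFit:
    """Parameterize a spectrum into an aperiodic backbone plus Gaussians.

    Procedure: robust aperiodic fit -> flatten -> iterative Gaussian
    extraction (tallest first, up to ``max_n_peaks``, heights >= 0.1,
    widths 2*sd within [2, 10] Hz) -> joint Gaussian refinement ->
    aperiodic refit on the peak-removed spectrum.  Non-convergence returns
    a flagged fit with the goodness it achieved.
    """
    sel = (spec.freqs >= fit_range[0]) & (spec.freqs <= fit_range[1])
    freqs = spec.freqs[sel]
    psd = spec.psd[sel]
    if freqs.size < 8:
        raise ContractError("spectrum does not cover the fit range")
    if np.any(psd <= 0):
        raise ContractError("PSD must be positive on the fit range")
    logpsd = np.log10(psd)

    converged = True
    try:
        ap = _robust_aperiodic(freqs, logpsd)
    except RuntimeError:
        ap = np.array([logpsd.mean(), 0.0, 0.0])
        converged = False

    sd_lo, sd_hi = peak_width_limits[0] / 2.0, peak_width_limits[1] / 2.0
    flat = logpsd - _aperiodic_model(freqs, *ap)
    guesses = []
    work = flat.copy()
    for _ in range(max_n_peaks):
        i = int(np.argmax(work))
        h = work[i]
        if h < min_peak_height:
            break
        # sd guess from half-height extent
        half = h / 2.0
        j = i
        while j + 1 < work.size and work[j + 1] > half:
            j += 1
        sd0 = np.clip((freqs[min(j, work.size - 1)] - freqs[i]) / 1.18 + 1e-3,
                      sd_lo, sd_hi)
        guesses.append((freqs[i], h, float(sd0)))
        work = work - _gaussian(freqs, freqs[i], h, sd0)

    peaks = []
    if guesses:
        def multi_gauss(f, *params):
            out = np.zeros_like(f)
            for q in range(0, len(params), 3):
                out = out + _gaussian(f, params[q], params[q + 1], params[q + 2])
            return out

        p0, lo_b, hi_b = [], [], []
        for c, h, sd0 in guesses:
            p0 += [c, h, sd0]
            lo_b += [fit_range[0], 0.0, sd_lo]
            hi_b += [fit_range[1], np.inf, sd_hi]
        try:
            popt, _ = curve_fit(multi_gauss, freqs, flat, p0=p0,
                                bounds=(lo_b, hi_b), maxfev=5000)
            fitted = [tuple(popt[q:q + 3]) for q in range(0, len(popt), 3)]
        except RuntimeError:
            fitted = guesses
            converged = False
        peaks = [(float(c), float(h), float(2 * sd))
                 for c, h, sd in fitted if h >= min_peak_height]

    peak_model = np.zeros_like(freqs)
    for c, h, w in peaks:
        peak_model += _gaussian(freqs, c, h, w / 2.0)
    try:
        ap = _fit_aperiodic_curve(freqs, logpsd - peak_model)
    except RuntimeError:
        converged = False

    model = _aperiodic_model(freqs, *ap) + peak_model
    ss_res = float(np.sum((logpsd - model) ** 2))
    ss_tot = float(np.sum((logpsd - logpsd.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(offset=float(ap[0]), knee=float(ap[1]),
                        exponent=float(ap[2]),
                        peaks=tuple(sorted(peaks)), r_squared=r2,
                        fit_range=tuple(fit_range), converged=converged)
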