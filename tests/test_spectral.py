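"""EEG filtering, periodogram, band power, and aperiodic-fit contracts."""

import numpy as np
import pytest

from pupilstate.pupil import ContractError
from pupilstate.spectral import (BANDS, BandDefinition, EEGTrace,
                                 SpectrumEstimate, band_auc, fit_aperiodic,
                                 preprocess_eeg, session_normalized_psd,
                                 sliding_band_power, window_psd)

FS = 1000.0


def _sine(freq, duration_s=10.0, amp=1.0):
    t = np.arange(int(duration_s * FS)) / FS
    return EEGTrace(values=amp * np.sin(2 * np.pi * freq * t))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_150hz_sine_attenuated_per_sixth_order_response():
    out = preprocess_eeg(_sine(150.0)).values[2000:-2000]
    # zero-phase 6th-order low-pass: amplitude response is |H|^2
    h2 = 1.0 / (1.0 + (150.0 / 100.0) ** 12)
    assert np.sqrt(np.mean(out ** 2)) <= h2 * np.sqrt(0.5) * 1.2


def test_60hz_sine_removed_by_notch():
    raw = _sine(60.0)
    out = preprocess_eeg(raw).values[2000:-2000]
    rms_in = np.sqrt(np.mean(raw.values ** 2))
    assert np.sqrt(np.mean(out ** 2)) < 0.05 * rms_in


def test_white_noise_survives_filtering_with_zero_mean():
    rng = np.random.default_rng(0)
    out = preprocess_eeg(EEGTrace(values=rng.standard_normal(20_000)))
    assert abs(out.values.mean()) < 0.05
    assert out.state == "filtered"


def test_short_trace_rejected():
    with pytest.raises(ContractError):
        preprocess_eeg(EEGTrace(values=np.zeros(2000)))


# ---------------------------------------------------------------------------
# periodogram
# ---------------------------------------------------------------------------

def test_zero_window_gives_zero_spectrum():
    spec = window_psd(np.zeros(1000))
    assert np.all(spec.psd == 0)
    assert spec.freqs[0] == 0.0 and spec.freqs[-1] == 500.0


def test_unit_sine_concentrates_power_and_respects_parseval():
    t = np.arange(1000) / FS
    x = np.sin(2 * np.pi * 10.0 * t)
    spec = window_psd(x)
    df = spec.freqs[1] - spec.freqs[0]
    total = spec.psd.sum() * df
    assert total == pytest.approx(np.mean(x ** 2), rel=1e-9)
    assert total == pytest.approx(0.5, rel=1e-6)
    assert spec.psd[10] / spec.psd.sum() >= 0.99


def test_parseval_on_random_windows():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = rng.standard_normal(1000) * rng.uniform(0.1, 10)
        spec = window_psd(x)
        df = spec.freqs[1] - spec.freqs[0]
        assert spec.psd.sum() * df == pytest.approx(np.mean(x ** 2),
                                                    rel=1e-6)


def test_wrong_window_length_rejected():
    with pytest.raises(ContractError):
        window_psd(np.zeros(999))


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

def test_band_auc_zero_spectrum():
    spec = window_psd(np.zeros(1000))
    for band in BANDS:
        assert band_auc(spec, band) == 0.0


@pytest.mark.parametrize("freq,expected_band", [
    (2.0, "delta"), (6.0, "theta"), (10.0, "alpha"),
    (20.0, "beta"), (40.0, "low_gamma"), (70.0, "high_gamma"),
])
def test_sinusoids_land_in_their_canonical_bands(freq, expected_band):
    t = np.arange(1000) / FS
    spec = window_psd(np.sin(2 * np.pi * freq * t))
    total = band_auc(spec, BandDefinition("all", 1.0, 100.0))
    aucs = {b.name: band_auc(spec, b) for b in BANDS}
    assert max(aucs, key=aucs.get) == expected_band
    assert aucs[expected_band] >= 0.95 * total


def test_band_auc_additive_at_grid_points():
    rng = np.random.default_rng(2)
    spec = window_psd(rng.standard_normal(1000))
    whole = band_auc(spec, BandDefinition("w", 4.0, 30.0))
    parts = (band_auc(spec, BandDefinition("a", 4.0, 12.0))
             + band_auc(spec, BandDefinition("b", 12.0, 30.0)))
    assert whole == pytest.approx(parts, rel=1e-12)


# ---------------------------------------------------------------------------
# sliding series
# ---------------------------------------------------------------------------

def test_series_length_matches_window_arithmetic():
    eeg = preprocess_eeg(EEGTrace(values=np.random.default_rng(3)
                                  .standard_normal(61_000)))
    series = sliding_band_power(eeg)
    assert all(s.values.size == (61_000 - 1000) // 10 + 1 == 6001
               for s in series)
    t = series[0].times()
    assert t[0] == pytest.approx(0.5)
    assert np.allclose(np.diff(t), 0.01)


def test_amplitude_doubling_quadruples_alpha_power():
    t = np.arange(60_000) / FS
    amp = np.where(t < 30.0, 1.0, 2.0)
    eeg = EEGTrace(values=amp * np.sin(2 * np.pi * 10.0 * t),
                   state="filtered")
    alpha = next(s for s in sliding_band_power(eeg)
                 if s.band.name == "alpha")
    ts = alpha.times()
    before = alpha.values[(ts > 10) & (ts < 25)].mean()
    after = alpha.values[(ts > 35) & (ts < 50)].mean()
    assert after / before == pytest.approx(4.0, rel=0.05)


def test_zero_signal_zero_series():
    eeg = EEGTrace(values=np.zeros(20_000), state="filtered")
    for s in sliding_band_power(eeg):
        assert np.all(s.values == 0)


# ---------------------------------------------------------------------------
# session-normalized PSD
# ---------------------------------------------------------------------------

def test_band_fractions_bounded_and_scale_invariant():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(200_000)
    eeg = EEGTrace(values=x, state="filtered")
    spec1, frac1 = session_normalized_psd(eeg, n_segments=50, seed=5)
    assert sum(frac1.values()) <= 1.0 + 1e-9
    spec2, frac2 = session_normalized_psd(
        EEGTrace(values=10.0 * x, state="filtered"), n_segments=50, seed=5)
    assert np.allclose(spec1.psd, spec2.psd, rtol=1e-9)
    assert frac1 == pytest.approx(frac2)


def test_gamma_gain_raises_high_gamma_fraction():
    from pupilstate.synth import SimConfig, simulate_eeg
    base = {k: (0.0, 0.0, 0.0) for k in ("delta", "theta", "alpha", "beta",
                                         "low_gamma", "high_gamma")}
    cfg_lo = SimConfig(duration_s=120.0, band_coupling=base, seed=6)
    eeg_lo = preprocess_eeg(simulate_eeg(cfg_lo, [], []))
    cfg_hi = SimConfig(duration_s=120.0, band_coupling=base,
                       osc_strength=2.0, seed=6)
    # doubling oscillatory strength acts on every band; instead scale only
    # high gamma by regenerating with a dedicated config
    import dataclasses
    _, frac_lo = session_normalized_psd(eeg_lo, n_segments=40, seed=7)
    eeg_hi = preprocess_eeg(simulate_eeg(cfg_hi, [], []))
    _, frac_hi = session_normalized_psd(eeg_hi, n_segments=40, seed=7)
    # stronger oscillations shift mass away from the aperiodic low end
    assert frac_hi["high_gamma"] > frac_lo["high_gamma"]


def test_insufficient_data_rejected():
    eeg = EEGTrace(values=np.zeros(5000), state="filtered")
    with pytest.raises(ContractError):
        session_normalized_psd(eeg, n_segments=10)


# ---------------------------------------------------------------------------
# aperiodic parameterization
# ---------------------------------------------------------------------------

FREQS = np.arange(1.0, 101.0)


@pytest.mark.parametrize("chi", [0.5, 1.0, 1.5, 2.0])
@pytest.mark.parametrize("knee", [0.0, 10.0])
def test_noiseless_knee_model_recovered(chi, knee):
    psd = 10.0 ** 1.0 / (knee + FREQS ** chi)
    fit = fit_aperiodic(SpectrumEstimate(FREQS, psd, 1.0))
    assert abs(fit.exponent - chi) <= 0.1
    assert abs(fit.offset - 1.0) <= 0.1
    assert fit.r_squared > 0.999


def test_flat_spectrum_gives_zero_exponent():
    fit = fit_aperiodic(SpectrumEstimate(FREQS, np.full(100, 3.0), 1.0))
    assert fit.exponent == pytest.approx(0.0, abs=0.02)
    # flat limit: b - log10(k + 1) = log10(3); offset and knee trade off
    assert fit.offset - np.log10(fit.knee + 1.0) == pytest.approx(
        np.log10(3.0), abs=0.02)


def test_single_planted_gaussian_peak_recovered():
    logp = (1.0 - np.log10(10.0 + FREQS ** 2.0)
            + 0.5 * np.exp(-0.5 * ((FREQS - 10.0) / 1.5) ** 2))
    fit = fit_aperiodic(SpectrumEstimate(FREQS, 10.0 ** logp, 1.0))
    assert len(fit.peaks) == 1
    center, height, width = fit.peaks[0]
    assert center == pytest.approx(10.0, abs=0.5)
    assert height >= 0.1
    assert 2.0 <= width <= 10.0


def test_peak_width_and_height_limits_respected():
    rng = np.random.default_rng(8)
    logp = 1.0 - np.log10(FREQS ** 1.5) + rng.normal(0, 0.02, FREQS.size)
    fit = fit_aperiodic(SpectrumEstimate(FREQS, 10.0 ** logp, 1.0))
    for center, height, width in fit.peaks:
        assert height >= 0.1
        assert 2.0 <= width <= 10.0
        assert 2.0 <= center <= 55.0
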