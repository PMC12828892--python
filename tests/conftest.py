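"""Shared helpers: trace construction and the independent
brute-force dilation oracle."""

from __future__ import annotations

import numpy as np

from pupilstate.pupil import PupilTrace

PREPROCESSED = ("raw", "zscored", "upsampled", "highpassed")


def make_trace(values, rate_hz=100.0, t0_s=0.0) -> PupilTrace:
    """Wrap an array as an already-preprocessed 100 Hz trace so detection
    logic can be tested on constructed signals."""
    return PupilTrace(values=np.asarray(values, dtype=float), rate_hz=rate_hz,
                      t0_s=t0_s, state=PREPROCESSED)


def oracle_detect(values: np.ndarray, threshold: float,
                  rate_hz: float = 100.0, window_s: float = 10.0,
                  baseline_s: float = 2.0, return_s: float = 6.0,
                  halfspan_s: float = 6.0) -> list[int]:
    """Direct re-evaluation of the three printed detection criteria at
    every 0.01 s offset, written independently of the package detector.

    At each window start: (1) the first 2 s must stay continuously below
    the threshold; (2) the dilation peak is the first supra-threshold
    local maximum in the window (plateaus resolve to their first sample);
    (3) the trace must fall back below the threshold within 6 s after the
    peak.  On acceptance the scan resumes at that first sub-threshold
    sample; otherwise it advances one sample.  Peaks closer than the
    metric half-span to either trace edge are discarded but still consume
    their span.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    W = int(round(window_s * rate_hz))
    B = int(round(baseline_s * rate_hz))
    R = int(round(return_s * rate_hz))
    H = int(round(halfspan_s * rate_hz))
    below = v < threshold
    # first-sample-of-rise local maxima above threshold
    is_peak = np.zeros(n, dtype=bool)
    if n >= 3:
        is_peak[1:-1] = ((v[1:-1] > threshold)
                         & (v[:-2] < v[1:-1]) & (v[1:-1] >= v[2:]))
    peaks = []
    s = 0
    while s + W <= n:
        if not below[s:s + B].all():
            s += 1
            continue
        in_win = np.flatnonzero(is_peak[s:s + W])
        if in_win.size == 0:
            s += 1
            continue
        p = s + int(in_win[0])
        ret = np.flatnonzero(below[p + 1:p + R + 1])
        if ret.size == 0:
            s += 1
            continue
        r = p + 1 + int(ret[0])
        if p - H >= 0 and p + H <= n:
            peaks.append(p)
        s = r
    return peaks


def gaussian_bump(t, center, peak, sigma):
    return peak * np.exp(-0.5 * ((t - center) / sigma) ** 2)
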