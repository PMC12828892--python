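"""CSV/JSON readers and writers for session data and derived artifacts.

All tables are plain CSV with fixed float formatting so that re-running a
seeded pipeline reproduces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pupil import DilationEvent, PupilTrace
from .spectral import BandPowerSeries, EEGTrace

FLOAT_FMT = "%.8g"


def write_table(df: pd.DataFrame, path) -> Path:
    """Write any tidy table with the package's fixed float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


_write = write_table


# -- session signals --------------------------------------------------------

def write_pupil_csv(trace: PupilTrace, path) -> Path:
    return _write(pd.DataFrame({"time_s": trace.times(),
                                "pupil": trace.values}), path)


def read_pupil_csv(path) -> PupilTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t))
    return PupilTrace(values=df["pupil"].to_numpy(), rate_hz=round(rate, 6),
                      t0_s=float(t[0]), state=("raw",))


def write_eeg_csv(trace: EEGTrace, path) -> Path:
    return _write(pd.DataFrame({"time_s": trace.times(),
                                "eeg_uV": trace.values}), path)


def read_eeg_csv(path) -> EEGTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t))
    return EEGTrace(values=df["eeg_uV"].to_numpy(), rate_hz=round(rate, 6),
                    t0_s=float(t[0]), state="raw")


def write_events_csv(events, path) -> Path:
    return _write(pd.DataFrame({
        "peak_s": [e.peak_time_s for e in events],
        "label": [e.label for e in events],
        "baseline_z": [e.baseline_z for e in events],
        "amplitude_z": [e.amplitude_z for e in events],
    }), path)


def read_events_csv(path):
    df = pd.read_csv(path)
    return [DilationEvent(peak_time_s=float(r.peak_s), peak_index=-1,
                          label=str(r.label), baseline_z=float(r.baseline_z),
                          amplitude_z=float(r.amplitude_z))
            for r in df.itertuples()]


def write_stim_csv(onsets, duration_s, path) -> Path:
    return _write(pd.DataFrame({"onset_s": list(onsets),
                                "duration_s": [duration_s] * len(onsets)}),
                  path)


def read_stim_csv(path):
    df = pd.read_csv(path)
    return df["onset_s"].to_numpy(dtype=float)


def read_blinks_csv(path):
    df = pd.read_csv(path)
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


# -- derived artifacts ------------------------------------------------------

def write_band_power_csv(series_list, path) -> Path:
    cols = {"time_s": series_list[0].times()}
    for s in series_list:
        cols[s.band.name] = s.values
    return _write(pd.DataFrame(cols), path)


def write_spectrum_csv(spec, path) -> Path:
    return _write(pd.DataFrame({"freq_hz": spec.freqs, "psd": spec.psd}), path)


def write_aperiodic_csv(fits, path) -> Path:
    rows = []
    for name, fit in fits.items():
        row = {"spectrum": name, "offset": fit.offset, "knee": fit.knee,
               "exponent": fit.exponent, "r2": fit.r_squared,
               "converged": fit.converged}
        for i, (c, h, w) in enumerate(fit.peaks, start=1):
            row[f"peak{i}_cf"] = c
            row[f"peak{i}_height"] = h
            row[f"peak{i}_width"] = w
        rows.append(row)
    return _write(pd.DataFrame(rows), path)


def write_trials_csv(band, matrix, labels, rel_time_s, path) -> Path:
    df = pd.DataFrame(matrix,
                      columns=[f"t{t:+.2f}" for t in rel_time_s])
    df.insert(0, "label", list(labels))
    return _write(df, path)


def read_trials_csv(path):
    df = pd.read_csv(path)
    labels = df["label"].tolist()
    rel_t = np.array([float(c[1:]) for c in df.columns[1:]])
    return df.iloc[:, 1:].to_numpy(dtype=float), labels, rel_t


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


# -- key: value config text -------------------------------------------------

def write_config_text(mapping: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k}: {v}" for k, v in mapping.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config_text(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        out[key.strip()] = val.strip()
    return out
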