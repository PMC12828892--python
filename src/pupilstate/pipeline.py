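"""End-to-end orchestration: simulate or ingest a session, preprocess,
detect dilations, compute band power and spectra, run the peak-aligned
statistics, and evaluate the classifiers.

Every stage writes its artifacts into the output directory and registers
them in a manifest; identical configuration and master seed reproduce
byte-identical artifacts (all stochastic stages draw child seeds from the
master seed).  Trials for the pre/during/post statistics are extracted at
a 7.5 s half-span and the central 12 s is cropped for classification, so
both printed windows are served from one extraction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .classify import MODEL_KINDS, LABEL_CODES, TrialMatrix, band_accuracy_profile
from .pupil import (ContractError, DetectionConfig, align_to_peaks,
                    detect_spontaneous_dilations, locate_evoked_peaks,
                    preprocess_pupil)
from .spectral import BANDS, fit_aperiodic, preprocess_eeg, \
    session_normalized_psd, sliding_band_power
from .stats import (AlignedBandTrials, compare_event_metrics,
                    interdilation_intervals, pointwise_group_test,
                    window_band_power)
from .synth import SimConfig, simulate_session

log = logging.getLogger("pupilstate")

STAGES = ("ingest", "pupil", "detect", "spectra", "stats", "classify")


class PipelineError(RuntimeError):
    def __init__(self, stage, cause, partial_manifest):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.partial_manifest = partial_manifest


@dataclass
class RunConfig:
    out_dir: str
    sim: SimConfig | None = None
    pupil_path: str | None = None
    eeg_path: str | None = None
    stim_path: str | None = None
    blinks_path: str | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    stats_halfspan_s: float = 7.5
    classify_halfspan_s: float = 6.0
    models: tuple = MODEL_KINDS
    n_psd_segments: int = 100
    alpha: float = 0.05
    seed: int = 0
    cnn_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        simulate = self.sim is not None
        ingest = self.pupil_path is not None
        if simulate == ingest:
            raise ContractError(
                "provide exactly one of a SimConfig or input paths")


def _child_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0]
               % (2 ** 31))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "artifacts": {}, "counts": {},
                "parameters": _echo_config(cfg)}

    def register(name, path):
        manifest["artifacts"][name] = str(Path(path).relative_to(out))

    stage = "ingest"
    try:
        t_start = time.perf_counter()
        if cfg.sim is not None:
            sim = SimConfig(**{**asdict(cfg.sim), "seed":
                               _child_seed(cfg.seed, 0)})
            session = simulate_session(sim)
            pupil_raw, stim = session.pupil, np.asarray(session.stim_onsets)
            register("pupil_raw", psio.write_pupil_csv(pupil_raw,
                                                       out / "pupil_raw.csv"))
            register("stim", psio.write_stim_csv(stim, sim.stim_duration_s,
                                                 out / "stim.csv"))
            truth = [{"peak_s": t, "label": lab}
                     for t, lab in session.truth_events]
            register("truth_events",
                     psio.write_json(truth, out / "truth_events.json"))
            blinks = []
        else:
            session = None
            pupil_raw = psio.read_pupil_csv(cfg.pupil_path)
            stim = (psio.read_stim_csv(cfg.stim_path)
                    if cfg.stim_path else np.empty(0))
            blinks = (psio.read_blinks_csv(cfg.blinks_path)
                      if cfg.blinks_path else [])
        log.info("stage ingest done in %.2f s", time.perf_counter() - t_start)

        stage = "pupil"
        t0 = time.perf_counter()
        trace = preprocess_pupil(pupil_raw, blinks, cfg.detection)
        log.info("stage pupil done in %.2f s", time.perf_counter() - t0)

        stage = "detect"
        t0 = time.perf_counter()
        spont = detect_spontaneous_dilations(trace, cfg.detection)
        if stim.size:
            # the sliding-window detector is blind to stimulation; dilations
            # peaking inside a stimulation-response window are evoked, not
            # spontaneous, and are claimed by locate_evoked_peaks instead
            span = cfg.detection.align_halfspan_s
            spont = [e for e in spont
                     if not np.any((stim < e.peak_time_s)
                                   & (e.peak_time_s <= stim + span))]
            evoked = locate_evoked_peaks(trace, stim, cfg=cfg.detection)
        else:
            evoked = []
        events = sorted(spont + evoked, key=lambda e: e.peak_time_s)
        register("events", psio.write_events_csv(events, out / "events.csv"))
        manifest["counts"]["spontaneous"] = len(spont)
        manifest["counts"]["evoked"] = len(evoked)
        iv = interdilation_intervals(spont)
        register("interdilation", psio.write_json(
            {"mean_s": iv.mean_s, "median_s": iv.median_s,
             "n_intervals": int(iv.intervals_s.size)},
            out / "interdilation.json"))
        log.info("stage detect done in %.2f s (%d spont, %d evoked)",
                 time.perf_counter() - t0, len(spont), len(evoked))

        stage = "spectra"
        t0 = time.perf_counter()
        if session is not None:
            eeg_raw = session.eeg
        else:
            if cfg.eeg_path is None or not Path(cfg.eeg_path).exists():
                raise ContractError(f"EEG input not found: {cfg.eeg_path}")
            eeg_raw = psio.read_eeg_csv(cfg.eeg_path)
        eeg = preprocess_eeg(eeg_raw)
        band_series = sliding_band_power(eeg)
        register("band_power", psio.write_band_power_csv(
            band_series, out / "band_power.csv"))
        spec, fractions = session_normalized_psd(
            eeg, n_segments=cfg.n_psd_segments,
            seed=_child_seed(cfg.seed, 1))
        register("session_psd", psio.write_spectrum_csv(
            spec, out / "session_psd.csv"))
        register("band_fractions", psio.write_json(
            fractions, out / "band_fractions.json"))
        fit = fit_aperiodic(spec)
        register("aperiodic", psio.write_aperiodic_csv(
            {"session": fit}, out / "aperiodic.csv"))
        log.info("stage spectra done in %.2f s", time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        aligned, kept_events = _align_all_bands(
            band_series, events, cfg.stats_halfspan_s)
        ws_rows, pw_rows = [], []
        for band_name, trials in aligned.items():
            register(f"trials_{band_name}", psio.write_trials_csv(
                band_name, trials.matrix, trials.labels, trials.rel_time_s,
                out / f"trials_{band_name}.csv"))
            for label in ("spontaneous", "evoked"):
                sub = _subset(trials, label)
                if sub.n_trials == 0:
                    continue
                ws = window_band_power(sub)
                for period in ws.periods:
                    ws_rows.append({
                        "band": band_name, "label": label, "period": period,
                        "mean": ws.mean[period], "sem": ws.sem[period],
                        "n_trials": sub.n_trials})
            a = _subset(trials, "spontaneous")
            b = _subset(trials, "evoked")
            if a.n_trials >= 2 and b.n_trials >= 2:
                res = pointwise_group_test(a, b, alpha=cfg.alpha)
                pw_rows.append(pd.DataFrame({
                    "band": band_name,
                    "time_s": trials.rel_time_s,
                    "t": res.t_values, "p": res.p_values,
                    "significant": res.significant_mask.astype(int)}))
        register("window_stats", psio.write_table(pd.DataFrame(ws_rows),
                                             out / "window_stats.csv"))
        if pw_rows:
            register("pointwise_tests", psio.write_table(
                pd.concat(pw_rows, ignore_index=True),
                out / "pointwise_tests.csv"))
        ev_a = [e for e in kept_events if e.label == "spontaneous"]
        ev_b = [e for e in kept_events if e.label == "evoked"]
        if len(ev_a) >= 2 and len(ev_b) >= 2:
            cmp_ = compare_event_metrics(ev_a, ev_b)
            register("event_metric_comparison", psio.write_json(
                {m: {"test": c.test, "statistic": c.statistic,
                     "p_value": c.p_value, "mean_spontaneous": c.mean_a,
                     "mean_evoked": c.mean_b} for m, c in cmp_.items()},
                out / "event_metric_comparison.json"))
        log.info("stage stats done in %.2f s", time.perf_counter() - t0)

        stage = "classify"
        t0 = time.perf_counter()
        trials_by_band = _crop_for_classification(
            aligned, cfg.stats_halfspan_s, cfg.classify_halfspan_s,
            seed=_child_seed(cfg.seed, 2))
        profile = band_accuracy_profile(
            trials_by_band, kinds=cfg.models, seed=_child_seed(cfg.seed, 3),
            spec_overrides={"cnn": cfg.cnn_overrides} if cfg.cnn_overrides
            else None)
        register("accuracy", psio.write_table(profile, out / "accuracy.csv"))
        summary = (profile.groupby(["band", "model"])["accuracy"].mean()
                   .reset_index())
        register("accuracy_summary", psio.write_json(
            {f"{r.band}/{r.model}": round(float(r.accuracy), 6)
             for r in summary.itertuples()},
            out / "accuracy_summary.json"))
        log.info("stage classify done in %.2f s", time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineError(stage, exc, manifest) from exc

    psio.write_json(manifest, out / "manifest.json")
    log.info("pipeline done in %.2f s", time.perf_counter() - t_start)
    return manifest


def _echo_config(cfg: RunConfig) -> dict:
    echo = {"seed": cfg.seed, "models": list(cfg.models),
            "stats_halfspan_s": cfg.stats_halfspan_s,
            "classify_halfspan_s": cfg.classify_halfspan_s,
            "alpha": cfg.alpha, "n_psd_segments": cfg.n_psd_segments,
            "detection": asdict(cfg.detection)}
    if cfg.sim is not None:
        echo["sim"] = asdict(cfg.sim)
    else:
        echo["inputs"] = {"pupil": cfg.pupil_path, "eeg": cfg.eeg_path,
                          "stim": cfg.stim_path, "blinks": cfg.blinks_path}
    return echo


def _align_all_bands(band_series, events, halfspan_s):
    aligned = {}
    kept_events = None
    for series in band_series:
        mat, rel_t, _ = align_to_peaks(series.values, events,
                                       halfspan_s=halfspan_s,
                                       rate_hz=series.rate_hz,
                                       t0_s=series.t0_s)
        kept = [e for e in sorted(events, key=lambda e: e.peak_time_s)
                if _fits(e, series, halfspan_s)]
        labels = tuple(e.label for e in kept)
        aligned[series.band.name] = AlignedBandTrials(
            band=series.band.name, matrix=mat, labels=labels,
            rel_time_s=rel_t)
        kept_events = kept
    return aligned, (kept_events or [])


def _fits(ev, series, halfspan_s):
    p = int(round((ev.peak_time_s - series.t0_s) * series.rate_hz))
    h = int(round(halfspan_s * series.rate_hz))
    return p - h >= 0 and p + h <= series.values.size


def _subset(trials: AlignedBandTrials, label: str) -> AlignedBandTrials:
    keep = [i for i, l in enumerate(trials.labels) if l == label]
    return AlignedBandTrials(band=trials.band, matrix=trials.matrix[keep],
                             labels=tuple(trials.labels[i] for i in keep),
                             rel_time_s=trials.rel_time_s)


def _crop_for_classification(aligned, stats_halfspan_s, classify_halfspan_s,
                             seed):
    """Crop the central classification window and balance classes with one
    shared (label-driven) subsample so folds match across bands."""
    crop = None
    keep = None
    out = {}
    for band_name, trials in aligned.items():
        t = trials.rel_time_s
        sel = (t >= -classify_halfspan_s) & (t < classify_halfspan_s)
        y = np.array([LABEL_CODES[l] for l in trials.labels])
        if keep is None:
            rng = np.random.default_rng(seed)
            counts = {c: int((y == c).sum()) for c in (0, 1)}
            n_min = min(counts.values())
            idxs = []
            for c in (0, 1):
                idx = np.flatnonzero(y == c)
                if idx.size > n_min:
                    idx = np.sort(rng.choice(idx, n_min, replace=False))
                idxs.append(idx)
            keep = np.sort(np.concatenate(idxs))
            crop = sel
        out[band_name] = TrialMatrix(features=trials.matrix[keep][:, crop],
                                     labels=y[keep], band=band_name,
                                     balanced=True)
    return out


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

def build_synthetic_cohort(base_config: SimConfig, n_sessions: int,
                           seed: int = 0, halfspan_s: float = 6.0,
                           detection: DetectionConfig | None = None) -> dict:
    """Pool peak-aligned labeled trials from several simulated sessions.

    Each session is simulated with a child seed, preprocessed, and its
    dilations detected exactly as in the full pipeline (spontaneous
    detections inside stimulation-response windows are reassigned to the
    evoked detector).  Trials from all sessions are pooled per band and the
    majority class is subsampled once (seeded, identical rows across
    bands).  Returns ``{band_name: TrialMatrix}``.
    """
    detection = detection or DetectionConfig()
    from dataclasses import asdict as _asdict
    pooled = {b.name: [] for b in BANDS}
    labels_all = []
    for s_idx in range(n_sessions):
        sim = SimConfig(**{**_asdict(base_config),
                           "seed": _child_seed(seed, 100 + s_idx)})
        session = simulate_session(sim)
        trace = preprocess_pupil(session.pupil, (), detection)
        stim = np.asarray(session.stim_onsets)
        spont = detect_spontaneous_dilations(trace, detection)
        span = detection.align_halfspan_s
        spont = [e for e in spont
                 if not np.any((stim < e.peak_time_s)
                               & (e.peak_time_s <= stim + span))]
        evoked = locate_evoked_peaks(trace, stim, cfg=detection)
        events = sorted(spont + evoked, key=lambda e: e.peak_time_s)
        band_series = sliding_band_power(preprocess_eeg(session.eeg))
        kept_labels = None
        for series in band_series:
            mat, _, _ = align_to_peaks(series.values, events,
                                       halfspan_s=halfspan_s,
                                       rate_hz=series.rate_hz,
                                       t0_s=series.t0_s)
            pooled[series.band.name].append(mat)
            if kept_labels is None:
                kept_labels = [e.label for e in events
                               if _fits(e, series, halfspan_s)]
        labels_all.extend(kept_labels or [])
    y = np.array([LABEL_CODES[l] for l in labels_all])
    rng = np.random.default_rng(_child_seed(seed, 999))
    n_min = min(int((y == 0).sum()), int((y == 1).sum()))
    keep = np.sort(np.concatenate([
        np.sort(rng.choice(np.flatnonzero(y == c), n_min, replace=False))
        if (y == c).sum() > n_min else np.flatnonzero(y == c)
        for c in (0, 1)]))
    out = {}
    for band_name, mats in pooled.items():
        X = np.vstack(mats)
        out[band_name] = TrialMatrix(features=X[keep], labels=y[keep],
                                     band=band_name, balanced=True)
    return out


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(manifest_dir_a, manifest_dir_b, alpha: float = 0.05,
                   seed: int = 0) -> dict:
    """Compare two completed runs (e.g., control vs. manipulation).

    Returns per-band window-stat deltas (A minus B), per-band/per-class
    pointwise tests between the groups' aligned trials (classes balanced
    to the smaller group, seeded subsample), and the per-group
    band-by-model mean accuracies.
    """
    a_dir, b_dir = Path(manifest_dir_a), Path(manifest_dir_b)
    man_a = pd.read_json(a_dir / "manifest.json", typ="series").to_dict()
    man_b = pd.read_json(b_dir / "manifest.json", typ="series").to_dict()
    ws_a = pd.read_csv(a_dir / man_a["artifacts"]["window_stats"])
    ws_b = pd.read_csv(b_dir / man_b["artifacts"]["window_stats"])
    merged = ws_a.merge(ws_b, on=["band", "label", "period"],
                        suffixes=("_a", "_b"))
    merged["delta_mean"] = merged["mean_a"] - merged["mean_b"]
    deltas = merged[["band", "label", "period", "delta_mean"]]

    rng = np.random.default_rng(seed)
    pw = []
    for band in [b.name for b in BANDS]:
        key = f"trials_{band}"
        if key not in man_a["artifacts"] or key not in man_b["artifacts"]:
            continue
        Xa, la, ta = psio.read_trials_csv(a_dir / man_a["artifacts"][key])
        Xb, lb, tb = psio.read_trials_csv(b_dir / man_b["artifacts"][key])
        if ta.size != tb.size or not np.allclose(ta, tb):
            raise ContractError("incompatible aligned timebases")
        for label in ("spontaneous", "evoked"):
            ia = np.flatnonzero(np.asarray(la) == label)
            ib = np.flatnonzero(np.asarray(lb) == label)
            n = min(ia.size, ib.size)
            if n < 2:
                continue
            ia = np.sort(rng.choice(ia, n, replace=False))
            ib = np.sort(rng.choice(ib, n, replace=False))
            ta_ = AlignedBandTrials(band=band, matrix=Xa[ia],
                                    labels=(label,) * n, rel_time_s=ta)
            tb_ = AlignedBandTrials(band=band, matrix=Xb[ib],
                                    labels=(label,) * n, rel_time_s=tb)
            res = pointwise_group_test(ta_, tb_, alpha=alpha)
            pw.append({"band": band, "label": label,
                       "n_significant": res.n_significant,
                       "pct_significant": res.pct_significant,
                       "n_per_group": n})

    acc_a = pd.read_csv(a_dir / man_a["artifacts"]["accuracy"])
    acc_b = pd.read_csv(b_dir / man_b["artifacts"]["accuracy"])
    acc_a["group"] = "A"
    acc_b["group"] = "B"
    acc = (pd.concat([acc_a, acc_b], ignore_index=True)
           .groupby(["group", "band", "model"])["accuracy"].mean()
           .reset_index())
    return {"window_stat_deltas": deltas,
            "pointwise": pd.DataFrame(pw),
            "accuracy": acc}


# ---------------------------------------------------------------------------
# demo configuration
# ---------------------------------------------------------------------------

def demo_config(out_dir, seed: int = 0) -> RunConfig:
    """Small fully synthetic end-to-end run (about a minute of compute).

    One 600 s session with stimulation every 30 s and a spontaneous
    dilation rate high enough to give balanced trial counts for fivefold
    cross-validation.
    """
    sim = SimConfig(duration_s=600.0, event_rate_per_s=1.0 / 10.0,
                    refractory_s=8.0, seed=0)
    return RunConfig(out_dir=str(out_dir), sim=sim, seed=seed,
                     n_psd_segments=60)
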