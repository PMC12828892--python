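"""Peak-aligned statistical comparisons of band power and event metrics.

Band power around dilation peaks is compared in three 5 s windows —
pre [-7.5, -2.5), during [-2.5, 2.5), post [2.5, 7.5) seconds relative to
the peak — and pointwise across the aligned timebase with an unpaired
two-sided t test per time point (uncorrected by default; the reporting
mirrors "N significant time points, P% of time series").  Event baselines
and amplitudes are compared with Student's t tests, falling back to the
rank-sum test when normality fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .pupil import ContractError

#: pre/during/post spans (seconds relative to peak), half-open, left-inclusive
DEFAULT_PERIOD_SPANS = {
    "pre": (-7.5, -2.5),
    "during": (-2.5, 2.5),
    "post": (2.5, 7.5),
}


@dataclass(frozen=True)
class AlignedBandTrials:
    """Peak-aligned single-band power windows, one row per trial."""

    band: str
    matrix: np.ndarray          # n_trials x n_timepoints
    labels: tuple               # class per trial
    rel_time_s: np.ndarray      # shared relative timebase
    session_ids: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "rel_time_s",
                           np.asarray(self.rel_time_s, dtype=float))
        if m.ndim != 2 or m.shape[1] != self.rel_time_s.size:
            raise ContractError("matrix and timebase shapes disagree")
        if not np.all(np.isfinite(m)):
            raise ContractError("trial rows must be finite")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    def select(self, label: str) -> np.ndarray:
        keep = [i for i, l in enumerate(self.labels) if l == label]
        return self.matrix[keep]


@dataclass(frozen=True)
class WindowStats:
    band: str
    periods: tuple                       # period names in order
    per_trial: dict                      # period -> per-trial means
    mean: dict                           # period -> grand mean
    sem: dict                            # period -> standard error


@dataclass(frozen=True)
class PointwiseTestResult:
    t_values: np.ndarray
    p_values: np.ndarray
    significant_mask: np.ndarray
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.significant_mask.sum())

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.n_significant / self.significant_mask.size


def window_band_power(trials: AlignedBandTrials,
                      spans: dict = None) -> WindowStats:
    """Per-trial mean band power in each analysis period, with grand
    mean +/- s.e.m. across trials."""
    spans = dict(DEFAULT_PERIOD_SPANS) if spans is None else spans
    t = trials.rel_time_s
    per_trial, mean, sem = {}, {}, {}
    for name, (a, b) in spans.items():
        if a < t[0] - 1e-9 or b > t[-1] + (t[1] - t[0]) + 1e-9:
            raise ContractError(
                f"period {name} [{a}, {b}) outside the aligned window")
        sel = (t >= a) & (t < b)
        vals = trials.matrix[:, sel].mean(axis=1)
        per_trial[name] = vals
        mean[name] = float(vals.mean())
        sem[name] = float(sps.sem(vals)) if vals.size > 1 else float("nan")
    return WindowStats(band=trials.band, periods=tuple(spans),
                       per_trial=per_trial, mean=mean, sem=sem)


def pointwise_group_test(group_a: AlignedBandTrials,
                         group_b: AlignedBandTrials,
                         alpha: float = 0.05) -> PointwiseTestResult:
    """Two-sided unpaired t test at every time point (uncorrected)."""
    if group_a.matrix.shape[1] != group_b.matrix.shape[1]:
        raise ContractError("groups must share the aligned timebase")
    if group_a.n_trials < 2 or group_b.n_trials < 2:
        raise ContractError("need at least two trials per group")
    a, b = group_a.matrix, group_b.matrix
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals, pvals = sps.ttest_ind(a, b, axis=0)
    bad = ~np.isfinite(pvals)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance time points; p set to 1")
        pvals = np.where(bad, 1.0, pvals)
        tvals = np.where(bad, 0.0, tvals)
    mask = pvals < alpha
    return PointwiseTestResult(t_values=tvals, p_values=pvals,
                               significant_mask=mask, alpha=alpha)


def compare_periods(ws: WindowStats) -> dict:
    """Standard omnibus and pairwise tests across the analysis periods.

    Thin wrappers over the usual contracts: one-way ANOVA with Tukey's
    HSD across pre/during/post per-trial means, plus paired t and
    Wilcoxon signed-rank variants for each period pair (the trials are
    the repeated-measures unit).
    """
    groups = [np.asarray(ws.per_trial[p], dtype=float) for p in ws.periods]
    anova = sps.f_oneway(*groups)
    tukey = sps.tukey_hsd(*groups)
    out = {"anova": {"statistic": float(anova.statistic),
                     "p_value": float(anova.pvalue)},
           "pairwise": {}}
    for i, a in enumerate(ws.periods):
        for j, b in enumerate(ws.periods):
            if j <= i:
                continue
            paired_t = sps.ttest_rel(groups[i], groups[j])
            diff = groups[i] - groups[j]
            if np.allclose(diff, 0):
                wil_p = 1.0
            else:
                wil_p = float(sps.wilcoxon(groups[i], groups[j]).pvalue)
            out["pairwise"][f"{a}_vs_{b}"] = {
                "tukey_p": float(tukey.pvalue[i, j]),
                "paired_t_p": float(paired_t.pvalue),
                "wilcoxon_p": wil_p,
                "mean_diff": float(diff.mean()),
            }
    return out


@dataclass(frozen=True)
class MetricComparison:
    metric: str
    test: str                   # "t" or "ranksum"
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def _compare_samples(metric, a, b, normality_alpha=0.05):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    normal = True
    for x in (a, b):
        if x.size >= 3 and np.ptp(x) > 0:
            if sps.shapiro(x).pvalue < normality_alpha:
                normal = False
    if normal:
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test = "ranksum"
    return MetricComparison(metric=metric, test=test, statistic=stat,
                            p_value=p, mean_a=float(a.mean()),
                            mean_b=float(b.mean()))


def compare_event_metrics(events_a, events_b):
    """Compare baselines and amplitudes of two dilation-event cohorts.

    Uses Student's t tests, switching to the Mann-Whitney U test when a
    Shapiro normality check fails; returns one report per metric.
    """
    if len(events_a) < 2 or len(events_b) < 2:
        raise ContractError("need at least two events per side")
    out = {}
    for metric, attr in (("baseline", "baseline_z"),
                         ("amplitude", "amplitude_z")):
        a = [getattr(e, attr) for e in events_a]
        b = [getattr(e, attr) for e in events_b]
        out[metric] = _compare_samples(metric, a, b)
    return out


@dataclass(frozen=True)
class IntervalSummary:
    intervals_s: np.ndarray
    mean_s: float
    median_s: float


def interdilation_intervals(events) -> IntervalSummary:
    """Successive peak-time differences with mean/median summary."""
    peaks = sorted(e.peak_time_s for e in events)
    if len(peaks) < 2:
        empty = np.empty(0)
        return IntervalSummary(empty, float("nan"), float("nan"))
    iv = np.diff(peaks)
    return IntervalSummary(intervals_s=iv, mean_s=float(iv.mean()),
                           median_s=float(np.median(iv)))
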