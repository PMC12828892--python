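"""Dilation-type classification from single-band EEG power dynamics.

Each trial is one peak-aligned band-power window (12 s at 100 Hz -> 1200
features); labels are spontaneous (0) versus stimulation-evoked (1).
Six model families are evaluated under stratified fivefold
cross-validation with identical fold memberships across models and bands:
a small 1-D CNN, an RBF-kernel SVM (inner grid search over C and gamma),
a 500-tree random forest, LDA, elastic-net-penalized logistic regression,
and an MLP (two hidden layers, 128 and 64 units, Adam).  Feature
standardization statistics come from the training folds only, and the CNN
reserves a stratified validation slice of its training folds for early
stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._cnn import ConvNet1D
from .pupil import ContractError, align_to_peaks

MODEL_KINDS = ("cnn", "svm_rbf", "random_forest", "lda", "elastic_net", "mlp")

LABEL_CODES = {"spontaneous": 0, "evoked": 1}


@dataclass(frozen=True)
class TrialMatrix:
    features: np.ndarray        # n_trials x n_timepoints (single band)
    labels: np.ndarray          # 0 = spontaneous, 1 = evoked
    band: str
    balanced: bool = False
    standardized: bool = False  # per-feature standardization is applied
                                # inside cross-validation, never here

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ContractError("features and labels disagree in shape")
        if not np.all(np.isfinite(X)):
            raise ContractError("trial features must be finite")
        if self.balanced:
            n0, n1 = int((y == 0).sum()), int((y == 1).sum())
            if abs(n0 - n1) > 1:
                raise ContractError("balanced matrix has unequal classes")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "cnn"
    seed: int = 0
    # cnn
    conv_filters: tuple = (16, 32, 64)
    kernel_size: int = 7
    pool_size: int = 3
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.2
    # svm
    svm_c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_factors: tuple = (0.1, 1.0, 10.0)
    # random forest
    n_trees: int = 500
    min_samples_split: int = 10
    min_samples_leaf: int = 5
    # elastic net
    l1_ratio: float = 0.5
    penalty_c: float = 1.0
    # mlp
    hidden_sizes: tuple = (128, 64)

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ContractError(f"unknown model kind {self.kind!r}")


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple
    model: str
    band: str
    n_trials: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        accs = [a for a in self.fold_accuracies if np.isfinite(a)]
        return float(np.mean(accs)) if accs else float("nan")


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_trial_dataset(band_series, events, halfspan_s: float = 6.0,
                        balance: bool = True, seed=0) -> TrialMatrix:
    """Peak-aligned labeled trials from one band-power series.

    Rows come from ``align_to_peaks``; when ``balance`` is set the
    majority class is randomly subsampled (seeded) to the minority count.
    """
    events = sorted(events, key=lambda e: e.peak_time_s)
    mat, _, _ = align_to_peaks(band_series.values, events,
                               halfspan_s=halfspan_s,
                               rate_hz=band_series.rate_hz,
                               t0_s=band_series.t0_s)
    kept = [e for e in events
            if _in_bounds(e, band_series, halfspan_s)]
    y = np.array([LABEL_CODES[e.label] for e in kept], dtype=int)
    if mat.shape[0] != y.size:
        raise ContractError("alignment bookkeeping out of sync")
    if len(set(y.tolist())) < 2:
        raise ContractError("classification needs both dilation classes")
    if balance:
        rng = np.random.default_rng(seed)
        keep_idx = []
        counts = {c: int((y == c).sum()) for c in (0, 1)}
        n_min = min(counts.values())
        for c in (0, 1):
            idx = np.flatnonzero(y == c)
            if idx.size > n_min:
                idx = np.sort(rng.choice(idx, size=n_min, replace=False))
            keep_idx.append(idx)
        keep = np.sort(np.concatenate(keep_idx))
        mat, y = mat[keep], y[keep]
    return TrialMatrix(features=mat, labels=y, band=band_series.band.name,
                       balanced=balance)


def _in_bounds(ev, series, halfspan_s):
    p = int(round((ev.peak_time_s - series.t0_s) * series.rate_hz))
    h = int(round(halfspan_s * series.rate_hz))
    return p - h >= 0 and p + h <= series.values.size


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _standardize(train, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _make_sklearn_model(spec: ClassifierSpec, X_train, seed):
    if spec.kind == "svm_rbf":
        gamma_scale = 1.0 / (X_train.shape[1] * max(X_train.var(), 1e-12))
        grid = {
            "C": list(spec.svm_c_grid),
            "gamma": [gamma_scale * f for f in spec.svm_gamma_factors],
        }
        return GridSearchCV(SVC(kernel="rbf"), grid, cv=3)
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            min_samples_split=spec.min_samples_split,
            min_samples_leaf=spec.min_samples_leaf,
            max_features="sqrt", random_state=seed)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    if spec.kind == "elastic_net":
        return LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=spec.l1_ratio,
            C=spec.penalty_c, max_iter=2000, random_state=seed)
    if spec.kind == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=spec.hidden_sizes, activation="relu",
            solver="adam", batch_size=min(spec.batch_size, X_train.shape[0]),
            max_iter=spec.max_epochs, early_stopping=True,
            n_iter_no_change=spec.patience,
            validation_fraction=spec.validation_fraction,
            random_state=seed)
    raise ContractError(f"not a scikit-learn kind: {spec.kind}")


def _fit_predict_fold(spec, X_train, y_train, X_test, seed):
    X_train, X_test = _standardize(X_train, X_test)
    if spec.kind == "cnn":
        X_tr, X_val, y_tr, y_val = train_test_split(
            X_train, y_train, test_size=spec.validation_fraction,
            stratify=y_train, random_state=seed)
        net = ConvNet1D(conv_filters=spec.conv_filters,
                        kernel_size=spec.kernel_size,
                        pool_size=spec.pool_size,
                        dense_units=spec.dense_units, lr=spec.learning_rate,
                        batch_size=spec.batch_size,
                        max_epochs=spec.max_epochs, patience=spec.patience,
                        seed=seed)
        net.fit(X_tr, y_tr, X_val, y_val)
        return net.predict(X_test)
    model = _make_sklearn_model(spec, X_train, seed)
    model.fit(X_train, y_train)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X_test)[:, 1]
        return (proba > 0.5).astype(int)   # ties to class 0
    return np.asarray(model.predict(X_test), dtype=int)


def cv_splits(labels, n_splits: int = 5, seed: int = 0):
    """Stratified fold memberships; a pure function of labels and seed, so
    splits are identical across model kinds and bands for one cohort."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=seed % (2 ** 31))
    return list(skf.split(np.zeros((len(labels), 1)), labels))


def crossval_evaluate(data: TrialMatrix, spec: ClassifierSpec,
                      n_splits: int = 5) -> CVResult:
    """Stratified fivefold accuracy at threshold 0.5.

    Fold splits are seeded from ``spec.seed`` and depend only on the
    labels, so every model kind sees the same partition.  A fold that
    fails to fit is recorded as NaN and excluded from the mean.
    """
    y = data.labels
    for c in (0, 1):
        if (y == c).sum() < n_splits * 2:
            raise ContractError("need at least 10 trials per class")
    accs = []
    for fold, (tr, te) in enumerate(cv_splits(y, n_splits, spec.seed)):
        fold_seed = (spec.seed * 1000 + fold) % (2 ** 31)
        try:
            pred = _fit_predict_fold(spec, data.features[tr], y[tr],
                                     data.features[te], fold_seed)
            accs.append(float(np.mean(pred == y[te])))
        except (np.linalg.LinAlgError, ValueError):
            accs.append(float("nan"))
    return CVResult(fold_accuracies=tuple(accs), model=spec.kind,
                    band=data.band, n_trials=len(y), seed=spec.seed)


def band_accuracy_profile(trials_by_band: dict, kinds=MODEL_KINDS,
                          seed: int = 0, spec_overrides=None) -> pd.DataFrame:
    """Cross-validated accuracy for every (band, model) pair.

    All bands must hold identical trial sets (same labels in the same
    order) so the seeded folds coincide.  Returns a long-format table with
    columns band, model, fold, accuracy.
    """
    labels0 = None
    for band, tm in trials_by_band.items():
        if labels0 is None:
            labels0 = tm.labels
        elif not np.array_equal(labels0, tm.labels):
            raise ContractError("bands must share identical trial sets")
    rows = []
    overrides = spec_overrides or {}
    for band, tm in trials_by_band.items():
        for kind in kinds:
            spec = ClassifierSpec(kind=kind, seed=seed,
                                  **overrides.get(kind, {}))
            res = crossval_evaluate(tm, spec)
            for fold, acc in enumerate(res.fold_accuracies):
                rows.append({"band": band, "model": kind, "fold": fold,
                             "accuracy": acc})
    return pd.DataFrame(rows)
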