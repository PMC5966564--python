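"""Single-trial working-memory-load classification with a per-subject linear SVM.

Every sample of a filtered 30 s trial is a feature: with 16 optodes, two
chromophores and 2 Hz sampling a trial is a 1920-dimensional vector (960 for
the 4-optode / 4 Hz profile).  Because the feature count dwarfs the 10
training trials, the model is a soft-margin *linear* SVM whose
regularization parameter C is selected per subject by 5-fold
cross-validation on the phase A trials over the grid 1e-3 ... 1e4 (eight
decades).  The trained hyperplane then labels each phase C trial online, as
soon as its window closes.

High load is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .hemodynamics import DeviceProfile, HemoStream
from .macd import MacdConfig, MacdFilter
from .protocol import SessionProtocol, TrialSpec, TrialTensor, segment_trial

__all__ = [
    "C_GRID",
    "WMClassifier",
    "PredictionRecord",
    "SessionMetrics",
    "vectorize",
    "unvectorize",
    "make_cv_folds",
    "select_C",
    "train",
    "predict",
    "run_online_session",
    "compute_metrics",
]

# Regularization grid: 1e-3 to 1e4 in decade steps (8 candidates).
C_GRID: np.ndarray = 10.0 ** np.arange(-3, 5)

_LABEL_TO_INT = {"low": 0, "high": 1}
_INT_TO_LABEL = {v: k for k, v in _LABEL_TO_INT.items()}


def vectorize(trial: TrialTensor, profile: DeviceProfile | None = None) -> np.ndarray:
    """Flatten a trial tensor to a feature vector.

    Order is optode-major, then chromophore (HbO2 before hHb), then time —
    i.e. a C-order reshape of the (optode, chromophore, sample) tensor.  The
    flattening is invertible (:func:`unvectorize`).
    """
    if profile is not None:
        expected = (profile.n_optodes, 2, round(30 * profile.sampling_rate))
        if trial.values.shape != expected:
            raise ValueError(
                f"tensor shape {trial.values.shape} does not match profile {expected}"
            )
    return trial.values.reshape(-1)


def unvectorize(features: np.ndarray, n_optodes: int, n_samples: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: recover the (optode, 2, sample) tensor."""
    features = np.asarray(features, dtype=float)
    expected = n_optodes * 2 * n_samples
    if features.size != expected:
        raise ValueError(f"feature length {features.size} != {expected}")
    return features.reshape(n_optodes, 2, n_samples)


@dataclass
class WMClassifier:
    """Trained per-subject workload classifier: a linear max-margin separator."""

    weights: np.ndarray
    bias: float
    selected_C: float
    cv_accuracy: float
    cv_accuracy_per_C: dict[float, float]
    n_train: int
    n_features: int
    training_accuracy: float

    def decision_value(self, features: np.ndarray) -> float:
        """Signed distance proxy w.x + b; positive side is high load."""
        features = np.asarray(features, dtype=float)
        if features.shape != (self.n_features,):
            raise ValueError(
                f"feature length {features.shape} does not match model ({self.n_features})"
            )
        return float(self.weights @ features + self.bias)


@dataclass(frozen=True)
class PredictionRecord:
    """One phase C decision: predicted vs true load and the decision margin."""

    trial_index: int
    predicted_load: str
    true_load: str | None
    decision_margin: float


@dataclass
class SessionMetrics:
    """Phase C performance in percent, with high load as positive class.

    ``precision`` is NaN when no trial was predicted high (undefined ratio).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    n: int
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


def make_cv_folds(
    labels: list[str], n_folds: int = 5, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Stratified folds over the phase A trials: one trial per class per fold.

    Trials are grouped per class in presentation order; the seed permutes
    the order *within* each class only, so every fold always contains both
    loads and every training split keeps both classes represented.
    """
    y = np.array([_LABEL_TO_INT[l] for l in labels])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_class = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise ValueError(f"class {_INT_TO_LABEL[cls]!r} absent from training set")
        if idx.size % n_folds:
            raise ValueError(
                f"class {_INT_TO_LABEL[cls]!r} count {idx.size} not divisible by {n_folds} folds"
            )
        per_class.append(rng.permutation(idx))
    per_fold = len(per_class[0]) // n_folds
    folds = []
    for f in range(n_folds):
        sel = np.concatenate(
            [cls_idx[f * per_fold : (f + 1) * per_fold] for cls_idx in per_class]
        )
        folds.append(np.sort(sel))
    return folds


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    # Deterministic dual solver on hinge loss with L2 penalty.
    model = SVC(kernel="linear", C=C, tol=1e-6)
    model.fit(X, y)
    return model


def select_C(
    X: np.ndarray,
    labels: list[str],
    grid: np.ndarray = C_GRID,
    seed: int | np.random.Generator = 0,
    n_folds: int = 5,
) -> tuple[float, dict[float, float]]:
    """Pick C by cross-validated accuracy; ties resolve to the smallest C.

    Returns the winning C and the mean fold accuracy for every grid point.
    """
    X = np.asarray(X, dtype=float)
    y = np.array([_LABEL_TO_INT[l] for l in labels])
    folds = make_cv_folds(labels, n_folds=n_folds, seed=seed)
    cv_acc: dict[float, float] = {}
    for C in np.sort(np.asarray(grid, dtype=float)):
        accs = []
        for fold in folds:
            train_idx = np.setdiff1d(np.arange(len(y)), fold)
            model = _fit_svm(X[train_idx], y[train_idx], C)
            accs.append(float(np.mean(model.predict(X[fold]) == y[fold])))
        cv_acc[float(C)] = float(np.mean(accs))
    best = min((C for C in cv_acc), key=lambda C: (-cv_acc[C], C))
    return best, cv_acc


def train(
    tensors: list[TrialTensor],
    grid: np.ndarray = C_GRID,
    seed: int | np.random.Generator = 0,
) -> WMClassifier:
    """Train the per-subject model on the complete phase A block.

    Selects C by cross-validation, then refits on all labeled trials at the
    winning C.  Deterministic given the seed.
    """
    labels = [t.load for t in tensors]
    for cls in ("low", "high"):
        if labels.count(cls) < 2:
            raise ValueError(f"need at least 2 {cls!r} trials to train")
    X = np.stack([vectorize(t) for t in tensors])
    y = np.array([_LABEL_TO_INT[l] for l in labels])
    best_C, cv_acc = select_C(X, labels, grid=grid, seed=seed)
    model = _fit_svm(X, y, best_C)
    train_acc = float(np.mean(model.predict(X) == y)) * 100.0
    return WMClassifier(
        weights=model.coef_.ravel().copy(),
        bias=float(model.intercept_[0]),
        selected_C=best_C,
        cv_accuracy=cv_acc[best_C] * 100.0,
        cv_accuracy_per_C={C: a * 100.0 for C, a in cv_acc.items()},
        n_train=len(tensors),
        n_features=X.shape[1],
        training_accuracy=train_acc,
    )


def predict(
    model: WMClassifier,
    features: np.ndarray,
    trial_index: int = 0,
    true_load: str | None = None,
) -> PredictionRecord:
    """Classify one trial from its feature vector.

    The label is the sign of the decision value; an exact zero resolves to
    *low* load (the documented tie-break).  Stateless.
    """
    margin = model.decision_value(features)
    label = "high" if margin > 0 else "low"
    return PredictionRecord(
        trial_index=trial_index,
        predicted_load=label,
        true_load=true_load,
        decision_margin=margin,
    )


def compute_metrics(records: list[PredictionRecord]) -> SessionMetrics:
    """Accuracy / precision / recall / F1 in percent over prediction records.

    High load is the positive class.  With zero predicted positives the
    precision ratio is undefined and reported as NaN with a warning; F1
    follows suit.
    """
    if not records:
        raise ValueError("no prediction records")
    tp = sum(1 for r in records if r.predicted_load == "high" and r.true_load == "high")
    fp = sum(1 for r in records if r.predicted_load == "high" and r.true_load == "low")
    fn = sum(1 for r in records if r.predicted_load == "low" and r.true_load == "high")
    tn = sum(1 for r in records if r.predicted_load == "low" and r.true_load == "low")
    n = tp + fp + fn + tn
    if n != len(records):
        raise ValueError("records with missing truth labels cannot be scored")
    accuracy = 100.0 * (tp + tn) / n
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = 100.0 * tp / (tp + fp)
    recall = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return SessionMetrics(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        n=n, tp=tp, fp=fp, fn=fn, tn=tn,
    )


def run_online_session(
    stream_source,
    protocol: SessionProtocol,
    profile: DeviceProfile,
    macd_config: MacdConfig | None = None,
    apply_filter: bool = True,
    grid: np.ndarray = C_GRID,
    seed: int | np.random.Generator = 0,
) -> tuple[WMClassifier, list[PredictionRecord], SessionMetrics]:
    """Replay a session through the full online pipeline.

    ``stream_source`` is an iterable of ``(t, hbo_row, hhb_row)`` samples (see
    :func:`nirsbci.io.stream_player`) or a :class:`HemoStream` of
    concentration values.  Samples are consumed strictly in time order; each
    incoming sample is MACD-filtered (unless the stream is pre-filtered and
    ``apply_filter`` is False) and buffered.  A trial is segmented the moment
    its 30 s window is complete, so no decision ever depends on future
    samples.  Phase A trials accumulate as labeled tensors; the classifier is
    trained once, after trial ``n/2`` closes; every phase C trial yields a
    prediction record.  Trials whose window is not fully covered by the
    stream (a gap or truncation) are skipped with a warning and excluded
    from the metrics.
    """
    if macd_config is None:
        macd_config = MacdConfig(sampling_rate=profile.sampling_rate)
    if isinstance(stream_source, HemoStream):
        stream_iter = zip(stream_source.time, stream_source.hbo, stream_source.hhb)
    else:
        stream_iter = iter(stream_source)

    n_ch = profile.n_optodes
    filt = MacdFilter(macd_config, 2 * n_ch) if apply_filter else None
    times: list[float] = []
    hbo_rows: list[np.ndarray] = []
    hhb_rows: list[np.ndarray] = []

    phase_a_tensors: list[TrialTensor] = []
    model: WMClassifier | None = None
    records: list[PredictionRecord] = []
    n_phase_a = len(protocol.phase_a)
    pending = list(protocol.trials)

    def flush_closed(now: float | None) -> None:
        nonlocal model
        while pending and (now is None or pending[0].end <= now):
            trial = pending.pop(0)
            buffered = HemoStream(
                time=np.array(times), hbo=np.array(hbo_rows), hhb=np.array(hhb_rows)
            )
            try:
                tensor = segment_trial(buffered, trial, profile)
            except ValueError as exc:
                warnings.warn(f"skipping trial {trial.index}: {exc}", stacklevel=2)
                if trial.index <= n_phase_a:
                    raise ValueError(
                        f"phase A trial {trial.index} not covered; cannot train"
                    ) from exc
                continue
            if trial.index <= n_phase_a:
                phase_a_tensors.append(tensor)
                if len(phase_a_tensors) == n_phase_a:
                    model = train(phase_a_tensors, grid=grid, seed=seed)
            else:
                if model is None:
                    raise RuntimeError("phase C reached before training completed")
                records.append(
                    predict(model, vectorize(tensor), trial.index, trial.load)
                )

    for t, hbo_row, hhb_row in stream_iter:
        hbo_row = np.asarray(hbo_row, dtype=float)
        hhb_row = np.asarray(hhb_row, dtype=float)
        if filt is not None:
            out = filt.update(np.concatenate([hbo_row, hhb_row]))
            hbo_row, hhb_row = out[:n_ch], out[n_ch:]
        times.append(float(t))
        hbo_rows.append(hbo_row)
        hhb_rows.append(hhb_row)
        flush_closed(float(t))
    # a trial whose window ends exactly at the final sample time + dt is complete
    flush_closed(None)

    if model is None:
        raise ValueError("stream ended before phase A completed")
    metrics = compute_metrics(records) if records else SessionMetrics(
        accuracy=float("nan"), precision=float("nan"), recall=float("nan"),
        f1=float("nan"), n=0,
    )
    return model, records, metrics
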