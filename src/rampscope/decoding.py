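"""Frame-level decoding of locomotion phase from population activity.

Workflow: build a frame dataset ([0,1]-normalized traces, phase labels,
trial membership) → split trials into ~equal random train/test halves →
tune a margin classifier (linear SVM, one-vs-rest) by trial-grouped
cross-validation → score per-class and overall accuracy on held-out trials
against a shuffle null that destroys the signal–label alignment by circular
time shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

RAW_LABELS = ("uphill", "downhill", "flat", "others")
EVAL_LABELS = ("uphill", "downhill", "others")

__all__ = [
    "FrameDataset",
    "DecodeResult",
    "make_frame_dataset",
    "split_trials",
    "train_and_tune",
    "evaluate_decoder",
    "RAW_LABELS",
    "EVAL_LABELS",
]


@dataclass
class FrameDataset:
    """Per-frame features and labels for decoding.

    ``features`` is (frames × neurons) with each neuron min-max scaled to
    [0, 1] over the session; ``labels_raw`` keeps the four-way labeling
    (uphill, downhill, flat, others) and ``labels_eval`` the three
    evaluation classes with flat collapsed into others.  Frames outside any
    complete trial are dropped; ``frame_index`` maps rows back to session
    frames.
    """

    features: np.ndarray
    labels_raw: np.ndarray
    labels_eval: np.ndarray
    trial_ids: np.ndarray
    frame_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.features)
        for arr in (self.labels_raw, self.labels_eval, self.trial_ids,
                    self.frame_index):
            if len(arr) != n:
                raise ValueError("all per-frame arrays must share the length")


def make_frame_dataset(
    traces: np.ndarray,
    phases: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float = 30.0,
) -> FrameDataset:
    """Build the decoding dataset from traces, phase labels, and trials.

    Traces are scaled per neuron to [0, 1] over the whole session
    (constant-trace neurons become all-zero, with a warning).  Raw labels
    map uphill/downhill/flat phases to themselves and everything else to
    'others'; evaluation labels collapse flat into 'others'.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    phases = np.asarray(phases)
    n, T = traces.shape
    if T != len(phases):
        raise ValueError("traces and phases must share the time base")

    lo = traces.min(axis=1, keepdims=True)
    hi = traces.max(axis=1, keepdims=True)
    span = hi - lo
    const = span.ravel() <= 0
    if const.any():
        logger.warning("%d constant-trace neurons scaled to all-zeros",
                       int(const.sum()))
    span[span <= 0] = 1.0
    X = ((traces - lo) / span).T  # frames × neurons

    t = np.arange(T) / frame_rate
    trial_of_frame = np.full(T, -1, dtype=int)
    comp = trials[trials["complete"].astype(bool)]
    for _, tr in comp.iterrows():
        trial_of_frame[(t >= tr.t_trial_start) & (t < tr.t_reward)] = int(tr.trial_id)

    keep = trial_of_frame >= 0
    raw = np.where(np.isin(phases, ("uphill", "downhill", "flat")),
                   phases, "others").astype("<U8")
    ev = np.where(raw == "flat", "others", raw).astype("<U8")
    return FrameDataset(
        features=X[keep],
        labels_raw=raw[keep],
        labels_eval=ev[keep],
        trial_ids=trial_of_frame[keep],
        frame_index=np.flatnonzero(keep),
    )


def split_trials(
    trial_ids: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split trials into two disjoint ~equal halves.

    All frames of a trial stay together; the two halves differ in size by at
    most one trial.
    """
    uniq = np.unique(np.asarray(trial_ids))
    if len(uniq) < 2:
        raise ValueError("need at least 2 trials to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    half = len(perm) // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def train_and_tune(
    ds: FrameDataset,
    train_trials: np.ndarray,
    cv_folds: int = 10,
    param_grid: dict | None = None,
    seed: int = 0,
    kernel: str = "linear",
    use_eval_labels: bool = True,
):
    """Grid-search a one-vs-rest SVM with trial-grouped cross-validation.

    Folds group frames by trial so no trial contributes to both the fit and
    the validation split of a fold.  Returns the refit best estimator; the
    chosen parameters are in ``clf.best_params_``.
    """
    if param_grid is None:
        param_grid = {"C": [0.01, 0.1, 1.0, 10.0]}
        if kernel == "rbf":
            param_grid["gamma"] = ["scale", 0.1, 1.0]
    mask = np.isin(ds.trial_ids, train_trials)
    X = ds.features[mask]
    y = (ds.labels_eval if use_eval_labels else ds.labels_raw)[mask]
    groups = ds.trial_ids[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    n_groups = len(np.unique(groups))
    if n_groups < cv_folds:
        raise ValueError(
            f"{n_groups} training trials < {cv_folds} cross-validation folds"
        )
    base = SVC(kernel=kernel, decision_function_shape="ovr",
               random_state=seed, cache_size=200)
    search = GridSearchCV(
        base, param_grid, cv=GroupKFold(n_splits=cv_folds),
        scoring="accuracy", n_jobs=1, refit=True,
    )
    search.fit(X, y, groups=groups)
    logger.info("tuned SVM: %s (CV accuracy %.3f)",
                search.best_params_, search.best_score_)
    return search


@dataclass
class DecodeResult:
    """Decoding accuracies with their shuffle null."""

    accuracy: float
    per_class: dict[str, float]
    best_params: dict
    null_accuracy: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_per_class: dict[str, np.ndarray] = field(default_factory=dict)
    p_overall: float = float("nan")
    p_per_class: dict[str, float] = field(default_factory=dict)
    n_shuffle: int = 0


def _class_accuracies(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    out = {}
    for cls in EVAL_LABELS:
        m = y_true == cls
        out[cls] = float((y_pred[m] == cls).mean()) if m.any() else float("nan")
    return out


def evaluate_decoder(
    clf,
    ds: FrameDataset,
    test_trials: np.ndarray,
    n_shuffle: int = 1000,
    seed: int = 0,
    shuffle_mode: str = "circular",
) -> DecodeResult:
    """Score the decoder on held-out trials against a shuffle null.

    Accuracy = correctly labeled frames / labeled frames (overall and per
    class).  The null re-scores the same trained classifier after
    destroying the signal–label alignment ``n_shuffle`` times: a random
    circular time shift of the test feature matrix per shuffle (preserving
    autocorrelation; ``shuffle_mode='permute'`` permutes frames instead).
    Empirical p = fraction of null accuracies ≥ the observed one (add-one
    smoothed).  A test class with no frames has NaN accuracy (flagged).
    """
    mask = np.isin(ds.trial_ids, test_trials)
    X = ds.features[mask]
    y = ds.labels_eval[mask]
    if len(X) == 0:
        raise ValueError("empty test set")
    pred = clf.predict(X)
    acc = float((pred == y).mean())
    per_class = _class_accuracies(y, pred)
    for cls, v in per_class.items():
        if np.isnan(v):
            logger.warning("test set has no %s frames; accuracy undefined", cls)

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    null_pc = {cls: np.empty(n_shuffle) for cls in EVAL_LABELS}
    T = len(X)
    for k in range(n_shuffle):
        if shuffle_mode == "circular":
            shift = int(rng.integers(1, T))
            Xs = np.roll(X, shift, axis=0)
        elif shuffle_mode == "permute":
            Xs = X[rng.permutation(T)]
        else:
            raise ValueError(f"unknown shuffle_mode {shuffle_mode!r}")
        pred_s = clf.predict(Xs)
        null[k] = float((pred_s == y).mean())
        for cls, v in _class_accuracies(y, pred_s).items():
            null_pc[cls][k] = v

    p_overall = float((1 + (null >= acc).sum()) / (1 + n_shuffle))
    p_pc = {}
    for cls in EVAL_LABELS:
        obs = per_class[cls]
        if np.isnan(obs):
            p_pc[cls] = float("nan")
        else:
            p_pc[cls] = float((1 + (null_pc[cls] >= obs).sum()) / (1 + n_shuffle))

    params = getattr(clf, "best_params_", {})
    return DecodeResult(
        accuracy=acc, per_class=per_class, best_params=dict(params),
        null_accuracy=null, null_per_class=null_pc,
        p_overall=p_overall, p_per_class=p_pc, n_shuffle=n_shuffle,
    )
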