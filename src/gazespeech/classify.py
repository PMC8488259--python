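"""Classifiers, correlation feature selection and late fusion.

The classification architecture trains, per cross-validation fold, one
model per (task, modality) for each of three algorithm families —
logistic regression (L2), Gaussian naive Bayes, and a 10-tree random
forest — then fuses patient-class probabilities by unweighted averaging:
first across modalities within a task, then across the four tasks.
Participants without usable gaze data contribute (and receive) language
probabilities only.

Correlation feature selection (applied for LR and GNB, never RF) runs on
the training fold alone: features whose absolute Pearson correlation with
the label is below ``r_label`` are dropped; among surviving pairs with
absolute mutual correlation at or above ``r_pair`` the member with the
lower label correlation is dropped (ties keep the earlier schema column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

from .errors import ContractViolationError, StratificationError

ALGORITHMS = ("GNB", "LR", "RF")


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm family with the study's fixed hyperparameters."""

    algorithm: str  # "LR" | "GNB" | "RF"
    lr_inverse_regularization: float = 1.0  # library-default L2 strength
    rf_n_trees: int = 10
    rf_min_samples_split: int = 2
    r_pair: float = 0.85
    r_label: float = 0.2

    @property
    def apply_selection(self) -> bool:
        # the forest performs implicit feature selection; the correlation
        # filter applies to LR and GNB only
        return self.algorithm != "RF"

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ContractViolationError(f"unknown algorithm {self.algorithm!r}")


# ---------------------------------------------------------------------------
# correlation feature selection
# ---------------------------------------------------------------------------


def _label_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column with the binary label; constants -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    return np.abs(np.nan_to_num(r, nan=0.0))


def _cfs_select_indices(
    Xv: np.ndarray, y: np.ndarray, r_pair: float, r_label: float
) -> list:
    """Array core of the correlation filter; returns kept column indices."""
    rlab = _label_correlations(Xv, np.asarray(y, dtype=float))
    surviving = np.flatnonzero(rlab >= r_label)
    if surviving.size == 0:
        return []
    # greedy keep in decreasing |label correlation| (schema order on ties):
    # a candidate is kept unless it correlates at >= r_pair with a feature
    # already kept, which by construction has label correlation >= its own
    order = sorted(surviving, key=lambda i: (-rlab[i], i))
    sub = Xv[:, surviving]
    with np.errstate(divide="ignore", invalid="ignore"):
        cm = np.corrcoef(sub, rowvar=False)
    cm = np.abs(np.nan_to_num(np.atleast_2d(cm), nan=0.0))
    pos = {int(col_i): k for k, col_i in enumerate(surviving)}
    kept: list = []
    for i in order:
        if all(cm[pos[int(i)], pos[j]] < r_pair for j in kept):
            kept.append(int(i))
    return sorted(kept)


def cfs_select(
    X: pd.DataFrame,
    y: np.ndarray,
    r_pair: float = 0.85,
    r_label: float = 0.2,
) -> list:
    """Correlation-based feature selection on a training fold.

    Returns the selected column names in schema order; the list may be
    empty (the caller decides how to handle an empty selection).
    """
    cols = list(X.columns)
    kept = _cfs_select_indices(X.to_numpy(dtype=float), y, r_pair, r_label)
    return [cols[i] for i in kept]


# ---------------------------------------------------------------------------
# per-fold fit/predict
# ---------------------------------------------------------------------------


def _make_estimator(spec: ModelSpec, seed: int):
    if spec.algorithm == "LR":
        # L2 penalty (the library default) at the default strength
        return LogisticRegression(
            C=spec.lr_inverse_regularization, solver="lbfgs", max_iter=5000
        )
    if spec.algorithm == "GNB":
        return GaussianNB()  # priors estimated from the data
    return RandomForestClassifier(
        n_estimators=spec.rf_n_trees,
        min_samples_split=spec.rf_min_samples_split,
        criterion="gini",
        max_depth=None,
        random_state=seed,
    )


def prepare_fold(
    X_train: pd.DataFrame,
    X_test: pd.DataFrame,
    y_train: np.ndarray,
    spec: ModelSpec,
):
    """Train-fold-only imputation and feature selection.

    Missing values are imputed with the training-fold median; columns with
    no observed training value are dropped.  Returns the processed train
    and test matrices (test statistics are never consulted).
    """
    cols = np.asarray(X_train.columns, dtype=object)
    Xtr = X_train.to_numpy(dtype=float, copy=True)
    Xte = X_test.to_numpy(dtype=float, copy=True)
    observed = ~np.all(np.isnan(Xtr), axis=0)
    cols, Xtr, Xte = cols[observed], Xtr[:, observed], Xte[:, observed]
    med = np.nanmedian(Xtr, axis=0) if Xtr.size else np.array([])
    for M in (Xtr, Xte):
        holes = np.where(np.isnan(M))
        M[holes] = np.take(med, holes[1])
    if spec.apply_selection:
        kept = _cfs_select_indices(Xtr, y_train, spec.r_pair, spec.r_label)
        cols, Xtr, Xte = cols[kept], Xtr[:, kept], Xte[:, kept]
    return (
        pd.DataFrame(Xtr, index=X_train.index, columns=cols),
        pd.DataFrame(Xte, index=X_test.index, columns=cols),
    )


def fit_predict_unimodal(
    spec: ModelSpec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Patient-class probabilities for the test fold of one unimodal model.

    When feature selection leaves nothing, the model degrades to a flat,
    uninformative probability of 0.5 rather than failing the fold.  (A
    train-prevalence constant would differ between the eye and language
    training subsets and, averaged in fusion, leak fold-composition
    information into the ranking.)
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise StratificationError("training fold contains a single class")
    X_tr, X_te = prepare_fold(X_train, X_test, y_train, spec)
    if X_tr.shape[1] == 0:
        return np.full(len(X_te), 0.5)
    est = _make_estimator(spec, seed)
    with warnings.catch_warnings():
        # features stay in raw units (odds ratios per unit, as reported);
        # lbfgs may stop at max_iter on ms-scale columns without affecting
        # the probability ranking
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(X_tr.to_numpy(), y_train)
    patient_col = int(np.flatnonzero(est.classes_ == 1)[0])
    return est.predict_proba(X_te.to_numpy())[:, patient_col]


# ---------------------------------------------------------------------------
# late fusion
# ---------------------------------------------------------------------------


def fuse_modalities(eye: pd.Series | None, lang: pd.Series) -> pd.Series:
    """Average eye and language probabilities per participant.

    Participants absent from the eye model (rejected gaze) pass through
    with their language probability unchanged.
    """
    if eye is None or len(eye) == 0:
        return lang.copy()
    fused = {}
    for pid, lp in lang.items():
        fused[pid] = (eye[pid] + lp) / 2.0 if pid in eye.index else lp
    extra = [pid for pid in eye.index if pid not in lang.index]
    for pid in extra:  # eye-only participants keep their eye probability
        fused[pid] = eye[pid]
    return pd.Series(fused)


def fuse_tasks(task_probs: dict, algorithm: str | None = None,
               algorithms: dict | None = None) -> pd.Series:
    """Average each participant's available per-task probabilities.

    ``task_probs`` maps task name -> Series of probabilities indexed by
    participant.  All inputs must come from the same algorithm family;
    passing ``algorithms`` (task -> algorithm name) enforces that contract.
    A participant lacking a task (e.g. no pupil-calibration model after
    gaze rejection) is averaged over the tasks it has.
    """
    if algorithms is not None:
        distinct = set(algorithms.values())
        if len(distinct) > 1:
            raise ContractViolationError(
                f"cross-algorithm task fusion is not allowed: {sorted(distinct)}"
            )
        if algorithm is not None and distinct and algorithm not in distinct:
            raise ContractViolationError("algorithm mismatch in task fusion")
    frame = pd.DataFrame(task_probs)
    fused = frame.mean(axis=1, skipna=True)
    return fused.dropna()
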