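"""Leave-one-subject-out evaluation with heuristic forward feature selection.

Subjects are rows of the feature table, so leave-one-subject-out (LOSO) is a
leave-one-out split over rows.  The wrapper selection starts from the single
feature with the highest LOSO accuracy and greedily grows the set while the
accuracy strictly improves, with ties broken by higher sensitivity and then
lower catalogue index.

Two selection modes:

* ``pooled`` (default): a candidate set is scored by its LOSO accuracy over
  *all* subjects, yielding one global feature set and one trajectory — the
  reporting style of the original analysis.  Pooled scores are optimistically
  biased because every subject participates in the selection.
* ``nested``: selection is rerun inside each training fold of an outer LOSO
  and only hold-out predictions are aggregated — an honest generalisation
  estimate.  The outer loop wraps :class:`ForwardSelectingClassifier`, a
  scikit-learn estimator whose ``fit`` performs the selection on the
  training data only.

For the tree ensemble, candidate scoring uses a reduced forest (25 trees)
and the winning set is rescored with the full forest (100 trees); linear
models are cheap enough to score directly.  Candidate scoring prunes a
fold loop as soon as the candidate can no longer reach the incumbent's
accuracy, which is exact (the incumbent is only replaced on a strict
lexicographic improvement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import sklearn
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIERS = ("max_margin", "logistic", "tree_ensemble")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family, normalization, hyperparameters and selection mode."""

    classifier: str = "tree_ensemble"
    normalize: Optional[bool] = None  # None = family default
    hyperparams: Dict[str, object] = field(default_factory=dict)
    seed: int = 0
    selection_mode: str = "pooled"  # "pooled" | "nested"
    max_features: Optional[int] = None

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.selection_mode not in ("pooled", "nested"):
            raise ValueError("selection_mode must be 'pooled' or 'nested'")
        if self.classifier in ("max_margin", "logistic") and self.normalize is False:
            raise ValueError(
                f"{self.classifier} requires standardization (normalize=True)"
            )

    @property
    def normalize_effective(self) -> bool:
        if self.normalize is None:
            return self.classifier in ("max_margin", "logistic")
        return self.normalize


def _make_estimator(spec: ModelSpec, scoring: bool = False):
    hp = spec.hyperparams
    if spec.classifier == "max_margin":
        clf = SVC(kernel=hp.get("kernel", "linear"), C=hp.get("C", 1.0))
    elif spec.classifier == "logistic":
        clf = LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
    else:
        n_est = hp.get("scoring_estimators", 25) if scoring else hp.get(
            "n_estimators", 100)
        clf = RandomForestClassifier(
            n_estimators=int(n_est),
            max_depth=hp.get("max_depth"),
            random_state=spec.seed,
        )
    if spec.normalize_effective:
        return make_pipeline(StandardScaler(), clf)
    return clf


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class EvaluationResult:
    """LOSO predictions, metrics, the selected features and the trajectory."""

    per_subject: pd.DataFrame  # columns subject_id, y_true, y_pred
    accuracy: float
    sensitivity: float
    specificity: float
    selected_features: List[str]
    trajectory: List[Tuple[int, str, float]]  # (step, feature added, score)
    mode: str = "pooled"
    fold_selections: Optional[List[List[str]]] = None

    def to_dict(self) -> Dict[str, object]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "selected_features": list(self.selected_features),
            "trajectory": [list(t) for t in self.trajectory],
            "mode": self.mode,
            "per_subject": self.per_subject.to_dict(orient="records"),
            "fold_selections": self.fold_selections,
        }


def compute_metrics(y_true, y_pred=None) -> Metrics:
    """Accuracy / sensitivity / specificity with faller (label 1) positive.

    Accepts either two label arrays or a per-subject prediction frame with
    ``y_true``/``y_pred`` columns.  A metric whose class is absent is
    undefined and reported as NaN, never as 0.
    """
    if y_pred is None:
        frame = y_true
        y_true = np.asarray(frame["y_true"])
        y_pred = np.asarray(frame["y_pred"])
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n = tp + fn + tn + fp
    acc = (tp + tn) / n if n else math.nan
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return Metrics(accuracy=acc, sensitivity=sens, specificity=spec)


# --------------------------------------------------------------------------
# fast LOSO machinery
# --------------------------------------------------------------------------


def _check_classes(y: np.ndarray) -> None:
    pos, neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if pos < 2 or neg < 2:
        raise ValueError(
            f"LOSO needs >= 2 subjects per class in every training fold "
            f"(have {pos} fallers / {neg} non-fallers)"
        )


def _loso_predictions(X: np.ndarray, y: np.ndarray, cols: Sequence[int],
                      estimator) -> np.ndarray:
    n = len(y)
    preds = np.empty(n, dtype=int)
    cols = np.asarray(cols, dtype=int)
    for i in range(n):
        tr = np.concatenate([np.arange(0, i), np.arange(i + 1, n)])
        est = clone(estimator)
        est.fit(X[np.ix_(tr, cols)], y[tr])
        preds[i] = int(est.predict(X[i, cols][None, :])[0])
    return preds


def _loso_score_pruned(X: np.ndarray, y: np.ndarray, cols: Sequence[int],
                       estimator, best_acc: float
                       ) -> Optional[Tuple[float, float]]:
    """(accuracy, sensitivity) of a LOSO run, or None once the candidate can
    no longer reach ``best_acc`` (exact pruning)."""
    n = len(y)
    npos = int(np.sum(y == 1))
    cols = np.asarray(cols, dtype=int)
    correct = tp = 0
    for i in range(n):
        if (correct + (n - i)) / n < best_acc:
            return None
        tr = np.concatenate([np.arange(0, i), np.arange(i + 1, n)])
        est = clone(estimator)
        est.fit(X[np.ix_(tr, cols)], y[tr])
        if int(est.predict(X[i, cols][None, :])[0]) == y[i]:
            correct += 1
            tp += int(y[i] == 1)
    return correct / n, (tp / npos if npos else math.nan)


def _split_table(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[str], List[str]]:
    if "label" not in table.columns:
        raise ValueError("feature table must carry a 'label' column")
    feat_cols = [c for c in table.columns if c != "label"]
    X = np.ascontiguousarray(table[feat_cols].to_numpy(dtype=float))
    y = table["label"].to_numpy(dtype=int)
    ids = [str(s) for s in table.index]
    return X, y, feat_cols, ids


def loso_predict(table: pd.DataFrame, features: Sequence[str],
                 spec: ModelSpec) -> pd.DataFrame:
    """Leave-one-subject-out predictions for a fixed feature set.

    Standardization parameters are estimated on the training rows of each
    fold only (the scaler lives inside the per-fold pipeline).
    """
    if len(features) == 0:
        raise ValueError("features must be nonempty")
    X, y, feat_cols, ids = _split_table(table)
    _check_classes(y)
    missing = [f for f in features if f not in feat_cols]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    cols = [feat_cols.index(f) for f in features]
    with sklearn.config_context(assume_finite=True):
        preds = _loso_predictions(X, y, cols, _make_estimator(spec))
    return pd.DataFrame({"subject_id": ids, "y_true": y, "y_pred": preds})


# --------------------------------------------------------------------------
# greedy forward selection
# --------------------------------------------------------------------------


def _greedy_select(X: np.ndarray, y: np.ndarray, candidates: Sequence[int],
                   scorer_est, max_features: Optional[int]
                   ) -> Tuple[List[int], List[Tuple[int, int, float]]]:
    """Greedy forward selection scored by leave-one-out accuracy on (X, y).

    Returns the selected column indices (in selection order) and the
    trajectory as (step, column, score).  Tie-break: higher accuracy, then
    higher sensitivity, then lower column index.  Candidates are scanned in
    decreasing |point-biserial correlation| purely as a pruning aid; the
    outcome is order-independent.
    """
    selected: List[int] = []
    remaining = list(candidates)
    trajectory: List[Tuple[int, int, float]] = []
    current_acc = -1.0
    limit = max_features if max_features is not None else len(candidates)
    ymean = y.mean()
    ysd = y.std() or 1.0

    def corr_strength(j: int) -> float:
        xj = X[:, j]
        sd = xj.std()
        if sd == 0:
            return 0.0
        return abs(float(np.mean((xj - xj.mean()) * (y - ymean))) / (sd * ysd))

    with sklearn.config_context(assume_finite=True):
        while len(selected) < limit and remaining:
            order = sorted(remaining, key=corr_strength, reverse=True)
            best: Tuple[float, float] = (-1.0, -1.0)
            best_j: Optional[int] = None
            for j in order:
                if best == (1.0, 1.0) and (best_j is not None and j > best_j):
                    continue  # only a lower-index tie could still win
                res = _loso_score_pruned(X, y, selected + [j],
                                         clone(scorer_est), best[0])
                if res is None:
                    continue
                if (res > best
                        or (res == best and (best_j is None or j < best_j))):
                    best, best_j = res, j
            if best_j is None or best[0] <= current_acc:
                break
            selected.append(best_j)
            remaining.remove(best_j)
            current_acc = best[0]
            trajectory.append((len(selected), best_j, best[0]))
            if current_acc >= 1.0:
                break
    return selected, trajectory


def forward_select(table: pd.DataFrame, spec: ModelSpec,
                   candidates: Optional[Sequence[str]] = None
                   ) -> EvaluationResult:
    """Run the wrapper selection and evaluate the chosen feature set.

    In pooled mode the winning set is rescored with the full estimator to
    produce the reported per-subject predictions and metrics; the trajectory
    keeps the selection-time scores.  In nested mode selection reruns inside
    every training fold and only hold-out predictions are aggregated.
    """
    X, y, feat_cols, ids = _split_table(table)
    _check_classes(y)
    if candidates is None:
        candidates = feat_cols
    missing = [c for c in candidates if c not in feat_cols]
    if missing:
        raise ValueError(f"unknown candidate features: {missing}")
    cand_idx = [feat_cols.index(c) for c in candidates]
    if not cand_idx:
        raise ValueError("candidate pool is empty")

    if spec.selection_mode == "nested":
        return _nested_evaluate(X, y, feat_cols, ids, cand_idx, spec)

    scorer = _make_estimator(spec, scoring=True)
    sel_idx, traj = _greedy_select(X, y, cand_idx, scorer, spec.max_features)
    if not sel_idx:  # degenerate: fall back to the single best candidate
        sel_idx = [cand_idx[0]]
        traj = [(1, cand_idx[0], math.nan)]
    with sklearn.config_context(assume_finite=True):
        preds = _loso_predictions(X, y, sel_idx, _make_estimator(spec))
    per_subject = pd.DataFrame({"subject_id": ids, "y_true": y, "y_pred": preds})
    m = compute_metrics(per_subject)
    return EvaluationResult(
        per_subject=per_subject,
        accuracy=m.accuracy, sensitivity=m.sensitivity, specificity=m.specificity,
        selected_features=[feat_cols[j] for j in sel_idx],
        trajectory=[(s, feat_cols[j], a) for (s, j, a) in traj],
        mode="pooled",
    )


def _nested_evaluate(X: np.ndarray, y: np.ndarray, feat_cols: List[str],
                     ids: List[str], cand_idx: List[int], spec: ModelSpec
                     ) -> EvaluationResult:
    n = len(y)
    preds = np.empty(n, dtype=int)
    fold_sel: List[List[str]] = []
    scorer = _make_estimator(spec, scoring=True)
    for i in range(n):
        tr = np.concatenate([np.arange(0, i), np.arange(i + 1, n)])
        Xtr, ytr = X[tr], y[tr]
        _check_classes(ytr)
        sel, _ = _greedy_select(Xtr, ytr, cand_idx, scorer, spec.max_features)
        if not sel:
            sel = [cand_idx[0]]
        est = _make_estimator(spec)
        with sklearn.config_context(assume_finite=True):
            est.fit(Xtr[:, sel], ytr)
            preds[i] = int(est.predict(X[i, sel][None, :])[0])
        fold_sel.append([feat_cols[j] for j in sel])
    per_subject = pd.DataFrame({"subject_id": ids, "y_true": y, "y_pred": preds})
    m = compute_metrics(per_subject)
    # summarize fold selections: rank features by how often folds chose them
    counts: Dict[str, int] = {}
    for sel in fold_sel:
        for name in sel:
            counts[name] = counts.get(name, 0) + 1
    ranked = sorted(counts, key=lambda k: (-counts[k], feat_cols.index(k)))
    median_size = int(np.median([len(s) for s in fold_sel])) if fold_sel else 0
    return EvaluationResult(
        per_subject=per_subject,
        accuracy=m.accuracy, sensitivity=m.sensitivity, specificity=m.specificity,
        selected_features=ranked[:max(median_size, 1)],
        trajectory=[],
        mode="nested",
        fold_selections=fold_sel,
    )


# --------------------------------------------------------------------------
# scikit-learn estimator
# --------------------------------------------------------------------------


class ForwardSelectingClassifier(BaseEstimator, ClassifierMixin):
    """Classifier with built-in greedy forward selection.

    ``fit`` scores candidate features by leave-one-out accuracy *within the
    training data*, grows the set greedily while accuracy strictly improves,
    then refits the final model on the selected features.  Wrapping this
    estimator in an outer leave-one-subject-out loop gives the nested
    selection mode.

    Parameters mirror :class:`ModelSpec`; fitted attributes carry trailing
    underscores (``selected_features_``, ``model_``, ``trajectory_``).
    """

    def __init__(self, classifier: str = "tree_ensemble",
                 normalize: Optional[bool] = None,
                 max_features: Optional[int] = None,
                 C: float = 1.0, kernel: str = "linear",
                 n_estimators: int = 100, scoring_estimators: int = 25,
                 max_depth: Optional[int] = None, random_state: int = 0):
        self.classifier = classifier
        self.normalize = normalize
        self.max_features = max_features
        self.C = C
        self.kernel = kernel
        self.n_estimators = n_estimators
        self.scoring_estimators = scoring_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            classifier=self.classifier, normalize=self.normalize,
            hyperparams={"C": self.C, "kernel": self.kernel,
                         "n_estimators": self.n_estimators,
                         "scoring_estimators": self.scoring_estimators,
                         "max_depth": self.max_depth},
            seed=self.random_state, max_features=self.max_features,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of subjects")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need both classes present to fit")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        spec = self._spec()
        sel, traj = _greedy_select(X, y, list(range(X.shape[1])),
                                   _make_estimator(spec, scoring=True),
                                   self.max_features)
        if not sel:
            sel = [0]
        self.selected_features_ = np.asarray(sel, dtype=int)
        self.trajectory_ = traj
        self.model_ = _make_estimator(spec)
        self.model_.fit(X[:, sel], y)
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise AttributeError("fit must be called before predict")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.model_.predict(X[:, self.selected_features_])


# --------------------------------------------------------------------------
# ablations
# --------------------------------------------------------------------------

ABLATION_MODES = ("full", "no_motion", "no_dual")


def ablation_candidates(columns: Sequence[str], mode: str) -> List[str]:
    from .features import CLINICAL_FEATURES

    cols = [c for c in columns if c != "label"]
    if mode == "full":
        return cols
    if mode == "no_motion":
        return [c for c in cols if c in CLINICAL_FEATURES]
    if mode == "no_dual":
        return [c for c in cols if not c.startswith("Dual_")]
    raise ValueError(f"mode must be one of {ABLATION_MODES}")


def run_ablation(table: pd.DataFrame, mode: str, spec: ModelSpec
                 ) -> EvaluationResult:
    """Rerun the full pipeline on a restricted candidate pool.

    ``no_motion`` keeps only the 8 clinical features; ``no_dual`` drops the
    42 dual-task columns; ``full`` uses everything.
    """
    return forward_select(table, spec,
                          candidates=ablation_candidates(table.columns, mode))
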