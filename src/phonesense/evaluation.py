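"""Leave-one-out cross-validated classification and confusion metrics.

Each participant-day is held out once; the five classic model families
(SVM, decision tree, k-nearest neighbours, Gaussian naive Bayes,
random forest) are fit on the remaining days and predict the held-out
one.  All preprocessing statistics — median imputation of missed
detections and standardization for the margin/distance-based models —
are computed on the training fold only, so no information leaks from
the test day.  Predictions are pooled into a single confusion matrix
per model; the mean per-fold 0/1 error is reported alongside.

Day-level folding follows the original protocol (the same participant
can appear in train and test); participant-grouped folding is offered
as a stricter alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_FAMILIES = ("SVM", "DT", "KNN", "NB", "RF")

#: families whose inputs are standardized per training fold
_SCALED = {"SVM", "KNN"}


def default_models(seed: int = 0, rf_trees: int = 100) -> dict:
    """Library-default classifiers for the five families."""
    return {
        "SVM": SVC(random_state=seed),
        "DT": DecisionTreeClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "NB": GaussianNB(),
        "RF": RandomForestClassifier(n_estimators=rf_trees, random_state=seed),
    }


@dataclass
class ModelResult:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    fold_errors: list = field(default_factory=list)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.fold_errors))

    def metrics(self):
        return confusion_metrics(self.tp, self.fp, self.tn, self.fn)


@dataclass
class EvaluationReport:
    per_model: dict                        # family -> ModelResult
    model_params: dict                     # family -> estimator params
    n_days: int = 0

    @property
    def ranking(self) -> list:
        """Model families ordered by decreasing pooled accuracy."""
        acc = {m: r.metrics()[0] for m, r in self.per_model.items()}
        return sorted(acc, key=lambda m: -acc[m])

    def as_table(self) -> str:
        lines = [f"{'Model':<6} {'Accuracy':>9} {'Precision':>10} "
                 f"{'Recall':>8} {'F1':>8}"]
        for m in self.ranking:
            a, p, r, f1 = self.per_model[m].metrics()

            def pct(x):
                return "   --" if x is None else f"{100 * x:6.2f}%"

            lines.append(f"{m:<6} {pct(a):>9} {pct(p):>10} "
                         f"{pct(r):>8} {pct(f1):>8}")
        return "\n".join(lines)


def loo_folds(n: int):
    """Leave-one-out folds: fold i tests sample i, trains on the rest."""
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def grouped_loo_folds(groups):
    """Leave-one-group-out folds (all of one participant's days held out)."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("grouped leave-one-out needs at least 2 groups")
    idx = np.arange(groups.size)
    return [(idx[groups != g], idx[groups == g]) for g in uniq]


def confusion_metrics(tp: int, fp: int, tn: int, fn: int):
    """(accuracy, precision, recall, F1) from pooled confusion counts.

    Undefined ratios (zero denominator) are returned as None.
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def _impute_train_test(X_train, X_test, pid_train, pid_test):
    """Median-impute NaNs using training-fold statistics only.

    A missing value is filled with the participant's training-fold
    median for that feature when available, else the training-fold
    cohort median, else 0 (a feature missing everywhere carries no
    information).
    """
    X_train = X_train.copy()
    X_test = X_test.copy()
    with np.errstate(all="ignore"):
        global_med = np.nanmedian(X_train, axis=0)
    global_med = np.where(np.isfinite(global_med), global_med, 0.0)

    pid_meds = {}
    for pid in np.unique(np.concatenate([pid_train, pid_test])):
        rows = X_train[pid_train == pid]
        if len(rows):
            with np.errstate(all="ignore"):
                med = np.nanmedian(rows, axis=0)
            pid_meds[pid] = np.where(np.isfinite(med), med, global_med)
        else:
            pid_meds[pid] = global_med

    for X, pids in ((X_train, pid_train), (X_test, pid_test)):
        nan_r, nan_c = np.where(~np.isfinite(X))
        for r, c in zip(nan_r, nan_c):
            X[r, c] = pid_meds[pids[r]][c]
    return X_train, X_test


def run_loo_evaluation(matrix, labels, participant_ids=None, models=None,
                       seed: int = 0, grouped: bool = False,
                       rf_trees: int = 100) -> EvaluationReport:
    """Fit and score all model families under leave-one-out folding.

    ``matrix`` is day x feature (NaN marks a missed detection);
    ``labels`` are the binary screening labels.  Reproducible for a
    given seed.
    """
    if hasattr(matrix, "to_numpy"):
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size or y.size < 2:
        raise ValueError("matrix rows must match labels, n >= 2")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    pids = (np.asarray(participant_ids) if participant_ids is not None
            else np.zeros(y.size, dtype=int))

    models = models or default_models(seed=seed, rf_trees=rf_trees)
    folds = grouped_loo_folds(pids) if grouped else loo_folds(y.size)

    results = {m: ModelResult() for m in models}
    for train_idx, test_idx in folds:
        Xtr, Xte = _impute_train_test(X[train_idx], X[test_idx],
                                      pids[train_idx], pids[test_idx])
        ytr, yte = y[train_idx], y[test_idx]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (Xte - mu) / sd
        for name, proto in models.items():
            est = clone(proto)
            if name in _SCALED:
                est.fit(Xtr_s, ytr)
                pred = est.predict(Xte_s)
            else:
                est.fit(Xtr, ytr)
                pred = est.predict(Xte)
            res = results[name]
            res.tp += int(np.sum((pred == 1) & (yte == 1)))
            res.fp += int(np.sum((pred == 1) & (yte == 0)))
            res.tn += int(np.sum((pred == 0) & (yte == 0)))
            res.fn += int(np.sum((pred == 0) & (yte == 1)))
            res.fold_errors.append(float(np.mean(pred != yte)))

    params = {m: models[m].get_params() for m in models}
    return EvaluationReport(per_model=results, model_params=params,
                            n_days=int(y.size))
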