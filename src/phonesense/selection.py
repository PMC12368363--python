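"""Pearson relevance/redundancy feature filtering.

Two-stage filter over a day-by-feature matrix against a continuous
severity label: (1) drop features whose |correlation| with the label is
below the relevance threshold (default 0.2); (2) walk the survivors in
descending |relevance| and drop any feature whose |correlation| with an
already-retained feature reaches the redundancy threshold (default
0.8), keeping the more label-relevant member of each redundant pair.

Absolute correlation is used throughout: a strongly *negative*
behavioral correlate (e.g. less evening activity at higher severity)
is as informative as a positive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RELEVANCE_THRESHOLD = 0.2
DEFAULT_REDUNDANCY_THRESHOLD = 0.8


@dataclass
class SelectionResult:
    relevance: dict                       # feature -> r with label
    retained: list
    dropped_low_relevance: list
    dropped_redundant: list = field(default_factory=list)  # (kept, dropped, r)


def pearson(x, y) -> float:
    """Pearson product-moment correlation.

    r = Σ(x_i − x̄)(y_i − ȳ) / sqrt(Σ(x_i − x̄)² · Σ(y_i − ȳ)²)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson needs two equal-length vectors, n >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = np.sum(dx * dx)
    syy = np.sum(dy * dy)
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.sum(dx * dy) / np.sqrt(sxx * syy))


def _safe_relevance(col, labels) -> float:
    """Label correlation, with constant/degenerate columns scored 0."""
    mask = np.isfinite(col) & np.isfinite(labels)
    if mask.sum() < 2:
        return 0.0
    try:
        return pearson(col[mask], labels[mask])
    except ValueError:
        return 0.0


def select_features(matrix, labels, feature_names=None,
                    rel_thresh: float = DEFAULT_RELEVANCE_THRESHOLD,
                    red_thresh: float = DEFAULT_REDUNDANCY_THRESHOLD
                    ) -> SelectionResult:
    """Apply the two-stage Pearson filter.

    ``matrix`` is day x feature (array or DataFrame); ``labels`` is the
    per-day severity score.  Missing values are ignored pairwise.
    Features tied on |relevance| keep their input order, which makes
    the procedure deterministic.
    """
    if hasattr(matrix, "columns"):        # DataFrame
        feature_names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("matrix rows must match label count")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 days")
    if np.all(y == y[0]):
        raise ValueError("labels are constant; relevance undefined")

    relevance = {name: _safe_relevance(X[:, j], y)
                 for j, name in enumerate(feature_names)}

    survivors = [n for n in feature_names if abs(relevance[n]) >= rel_thresh]
    dropped_low = [n for n in feature_names if n not in survivors]

    # stable sort: descending |relevance|, ties in input order
    order = sorted(survivors, key=lambda n: -abs(relevance[n]))

    col = {name: X[:, feature_names.index(name)] for name in feature_names}
    retained: list = []
    dropped_red: list = []
    for name in order:
        redundant_with = None
        for kept in retained:
            r = _safe_relevance(col[name], col[kept])
            if abs(r) >= red_thresh:
                redundant_with = (kept, name, r)
                break
        if redundant_with is None:
            retained.append(name)
        else:
            dropped_red.append(redundant_with)

    return SelectionResult(relevance=relevance, retained=retained,
                           dropped_low_relevance=dropped_low,
                           dropped_redundant=dropped_red)
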