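"""Greedy mRMR feature selection and post-selection kNN imputation.

Relevance is random-forest impurity importance (computed once from a seeded
reference forest); redundancy is the mean absolute Pearson correlation to the
features already selected.  The greedy criterion is the quotient
``relevance / max(redundancy, floor)`` — the common mRMR variant for
importance-based relevance.  Ties break on lexicographic feature name, so the
selection is invariant to column order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer

log = logging.getLogger(__name__)

REDUNDANCY_FLOOR = 1e-6


def redundancy_floor(n_samples: int) -> float:
    """Floor for the mean-|r| denominator of the greedy quotient.

    A sample Pearson correlation between independent variables has null
    scale ~ 1/sqrt(n); flooring at that scale stops a feature with a lucky
    near-zero redundancy estimate from dominating the quotient.
    """
    return max(REDUNDANCY_FLOOR, 1.0 / np.sqrt(max(n_samples, 2)))


@dataclass
class SelectionResult:
    """Ordered selection with the per-step greedy bookkeeping."""

    selected: list
    relevance: dict  # feature -> one-shot relevance
    steps: list = field(default_factory=list)  # (feature, relevance, redundancy, score)

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate features selected")


def _relevance(X: pd.DataFrame, y, seed: int, n_estimators: int = 200) -> pd.Series:
    Xf = X.fillna(X.mean()).fillna(0.0)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(Xf.to_numpy(), np.asarray(y))
    return pd.Series(rf.feature_importances_, index=X.columns)


def mrmr_select(X: pd.DataFrame, y, k: int, seed: int = 0) -> SelectionResult:
    """Greedy forward mRMR selection of ``k`` features.

    The first pick maximises relevance; each later step maximises
    relevance / max(mean |Pearson r| to the selected set, floor).
    Zero-variance features contribute zero redundancy (with a warning).
    """
    y = np.asarray(y)
    if pd.isna(y).any():
        raise ValueError("labels must not contain missing values")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    X = X[sorted(X.columns)]  # canonical order: invariant to input layout
    rel = _relevance(X, y, seed)
    if (X.std(ddof=0) == 0).any():
        warnings.warn("constant features present; their redundancy is 0", stacklevel=2)

    corr = X.corr().abs()  # pairwise-complete Pearson; NaN for constant cols
    corr = corr.fillna(0.0)
    floor = redundancy_floor(len(X))
    order = sorted(X.columns)  # lexicographic tie-break
    remaining = list(order)
    selected, steps = [], []
    for _ in range(k):
        best = None
        for f in remaining:
            r = float(rel[f])
            red = float(corr.loc[f, selected].mean()) if selected else 0.0
            score = r / max(red, floor) if selected else r
            if best is None or score > best[3]:
                best = (f, r, red, score)
        selected.append(best[0])
        steps.append(best)
        remaining.remove(best[0])
    return SelectionResult(selected, rel.to_dict(), steps)


def scan_feature_counts(
    X: pd.DataFrame,
    y,
    grid,
    seed: int = 0,
    replicates: int = 3,
    val_fraction: float = 0.3,
) -> pd.DataFrame:
    """Metric-vs-k scan: select k features, then score ``replicates`` seeded
    reference forests on a held-out fraction, for each k in the grid."""
    from sklearn.model_selection import train_test_split

    from tempheno.evaluate import binary_metrics

    grid = list(grid)
    if sorted(grid) != grid:
        raise ValueError("grid must be ascending")
    if grid[-1] > X.shape[1]:
        raise ValueError("grid exceeds the feature count")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    rows = []
    for k in grid:
        sel = mrmr_select(X, y, k, seed=seed)
        Xk = X[sel.selected].fillna(X[sel.selected].mean()).fillna(0.0)
        for rep in range(replicates):
            s = int(rng.integers(2**31))
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)), test_size=val_fraction, random_state=s,
                stratify=y,
            )
            clf = RandomForestClassifier(n_estimators=100, random_state=s)
            clf.fit(Xk.iloc[idx_tr], y[idx_tr])
            m = binary_metrics(clf.predict_proba(Xk.iloc[idx_va])[:, 1], y[idx_va])
            rows.append({"k": k, "replicate": rep, **m})
    return pd.DataFrame(rows)


def knn_impute(
    train: pd.DataFrame,
    apply_to: pd.DataFrame,
    k_neighbors: int = 5,
) -> pd.DataFrame:
    """Fill missing entries with the mean of the k nearest training rows
    (Euclidean distance over mutually observed features).

    Fit on the training matrix only; never updated from the matrix it is
    applied to.  Observed entries are returned untouched.
    """
    if list(train.columns) != list(apply_to.columns):
        raise ValueError("column sets must match")
    if train.isna().all(axis=0).any():
        raise ValueError("at least one fully observed value per column required")
    if apply_to.isna().all(axis=1).any():
        raise ValueError("a row with all features missing cannot be imputed")
    imputer = KNNImputer(n_neighbors=k_neighbors, weights="uniform")
    imputer.fit(train.to_numpy(dtype=float))
    filled = imputer.transform(apply_to.to_numpy(dtype=float))
    out = pd.DataFrame(filled, index=apply_to.index, columns=apply_to.columns)
    # guarantee observed entries pass through bit-identically
    mask = apply_to.notna()
    out = out.where(~mask, apply_to)
    out.attrs = dict(apply_to.attrs)
    return out.astype(float)
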