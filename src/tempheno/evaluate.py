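"""Pluggable classifiers, cross-validated evaluation, calibration, and the
rank-based statistical comparison machinery.

Every model is bound behind a small contract (fit / predict_scores /
importances) so the evaluation loops, the hyperparameter search, and the
interpretability comparisons are model-agnostic.  Class imbalance is handled
by inverse-frequency class weights where the model supports them and by
seeded 1:1 majority downsampling where it does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

METRICS = ("auroc", "auprc", "f1", "precision", "recall")


# ---------------------------------------------------------------------------
# class imbalance

def class_weights(labels) -> dict:
    """Inverse-frequency weights ``w_c = N / (2 * N_c)`` (two classes)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("two classes required")
    return {c: y.size / (2.0 * n) for c, n in zip(classes, counts)}


def downsample_majority(X, y, seed: int = 0):
    """Uniform without-replacement downsampling of the majority class to a
    1:1 ratio; the minority class is untouched."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    maj, mino = classes[np.argmax(counts)], classes[np.argmin(counts)]
    if counts.min() == counts.max():
        idx = np.arange(y.size)
    else:
        rng = np.random.default_rng(seed)
        maj_idx = np.flatnonzero(y == maj)
        keep = rng.choice(maj_idx, size=counts.min(), replace=False)
        idx = np.sort(np.concatenate([np.flatnonzero(y == mino), keep]))
    Xs = X.iloc[idx] if hasattr(X, "iloc") else np.asarray(X)[idx]
    return Xs, y[idx]


# ---------------------------------------------------------------------------
# classifier contract

class ClassifierContract:
    """Uniform facade: seeded fit with imbalance handling, probability-like
    scores in [0, 1], and feature importances when available."""

    name = "base"
    needs_downsample = False

    def fit(self, X, y, seed: int = 0):  # pragma: no cover - interface
        raise NotImplementedError

    def predict_scores(self, X) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def importances(self):
        return None  # "unavailable"


class _SklearnContract(ClassifierContract):
    def __init__(self, factory, name, **hyper):
        self._factory = factory
        self.name = name
        self.hyper = hyper
        self.model = None
        self._columns = None

    def fit(self, X, y, seed: int = 0):
        y = np.asarray(y)
        self._columns = list(X.columns) if hasattr(X, "columns") else None
        kwargs = dict(self.hyper)
        if self.needs_downsample:
            X, y = downsample_majority(X, y, seed=seed)
        else:
            kwargs.setdefault("class_weight", class_weights(y))
        self.model = self._factory(random_state=seed, **kwargs)
        self.model.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_scores(self, X) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def importances(self):
        est = self.model
        if isinstance(est, Pipeline):
            est = est[-1]
        if hasattr(est, "feature_importances_"):
            vals = est.feature_importances_
        elif hasattr(est, "coef_"):
            vals = est.coef_.ravel()
        else:
            return None
        if self._columns is not None:
            return pd.Series(vals, index=self._columns)
        return pd.Series(vals)


class _XGBContract(_SklearnContract):
    needs_downsample = True  # mirrors the downsampled-majority training route

    def fit(self, X, y, seed: int = 0):
        import xgboost as xgb

        y = np.asarray(y)
        self._columns = list(X.columns) if hasattr(X, "columns") else None
        X, y = downsample_majority(X, y, seed=seed)
        self.model = xgb.XGBClassifier(
            random_state=seed, eval_metric="logloss", **self.hyper
        )
        self.model.fit(np.asarray(X, dtype=float), y)
        return self


class _TGFNNContract(ClassifierContract):
    name = "tgfnn"

    def __init__(self, **hyper):
        self.hyper = hyper
        self.model = None

    def fit(self, X, y, seed: int = 0):
        from tempheno.tgfnn import TGFNNConfig, fit_tgfnn

        cfg = TGFNNConfig(**{**self.hyper, "seed": seed})
        cw = class_weights(np.asarray(y))
        self.model = fit_tgfnn(X, y, class_weights=cw, config=cfg)
        return self

    def predict_scores(self, X) -> np.ndarray:
        col = int(np.where(self.model.classes_ == 1)[0][0])
        return self.model.predict_proba(X)[:, col]

    def importances(self):
        bank = self.model.rule_bank()
        # per-variable importance aggregated over rules, weighted by the
        # rules' positive-class importance
        rho = bank.rule_importance[:, -1]
        vals = (bank.variable_importance * rho[:, None]).sum(axis=0)
        return pd.Series(vals, index=self.model.feature_names)


def _lr_factory(random_state=None, class_weight=None, **hyper):
    """L2-penalised logistic regression behind a standardising scaler."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(
                max_iter=2000, class_weight=class_weight,
                random_state=random_state, **hyper,
            )),
        ]
    )


_REGISTRY = {
    "dt": lambda **h: _SklearnContract(DecisionTreeClassifier, "dt", **h),
    "lr": lambda **h: _SklearnContract(_lr_factory, "lr", **h),
    "rf": lambda **h: _SklearnContract(
        RandomForestClassifier, "rf", **{"n_estimators": 200, **h}
    ),
    "xgb": lambda **h: _XGBContract(None, "xgb", **h),
    "tgfnn": lambda **h: _TGFNNContract(**h),
}


def available_models() -> list:
    names = ["dt", "lr", "rf", "tgfnn"]
    try:
        import xgboost  # noqa: F401

        names.insert(3, "xgb")
    except ImportError:  # documented degradation
        pass
    return names


def make_classifier(name: str, **hyper) -> ClassifierContract:
    if name not in _REGISTRY:
        raise KeyError(f"unknown model {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**hyper)


# ---------------------------------------------------------------------------
# metrics

def binary_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """AUROC (tie-corrected concordance), AUPRC (precision-recall step
    integral), and F1/precision/recall at ``threshold``."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("ranking metrics undefined for single-class labels")
    pred = (s >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(y, s)),
        "auprc": float(average_precision_score(y, s)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
    }


# ---------------------------------------------------------------------------
# calibration

@dataclass
class PlattCalibration:
    """Sigmoid recalibration ``p = 1 / (1 + exp(A*s + B))`` fit by maximum
    likelihood on training scores."""

    A: float
    B: float

    def transform(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return expit(-(self.A * s + self.B))


def platt_calibrate(scores, labels) -> PlattCalibration:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes required to calibrate")
    if np.ptp(s) < 1e-12:
        warnings.warn("degenerate (constant) scores; intercept-only fit",
                      stacklevel=2)
        prev = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        return PlattCalibration(A=0.0, B=float(-np.log(prev / (1 - prev))))

    def nll(ab):
        p = expit(-(ab[0] * s + ab[1]))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    def grad(ab):
        p = expit(-(ab[0] * s + ab[1]))
        d = y - p  # d nll / d(A*s + B), via dp/dt = -p(1-p)
        return np.array([np.sum(d * s), np.sum(d)])

    res = minimize(nll, x0=np.array([-1.0, 0.0]), jac=grad, method="BFGS")
    return PlattCalibration(A=float(res.x[0]), B=float(res.x[1]))


def reliability_bins(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability-curve data: mean predicted probability vs empirical
    positive rate in ``n_bins`` equal-width bins; empty bins omitted."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        rows.append(
            {"bin": b, "mean_prob": float(p[m].mean()),
             "frac_positive": float(np.mean(y[m] == 1)), "count": int(m.sum())}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical comparison

@dataclass
class FriedmanResult:
    statistic: float
    pvalue: float
    significant: bool
    mean_ranks: pd.Series
    nemenyi: pd.DataFrame | None = None
    tied_blocks: int = 0


def friedman_nemenyi(matrix, alpha: float = 0.01) -> FriedmanResult:
    """Friedman omnibus test on within-block ranks, with all-pairs Nemenyi
    post hoc (studentized-range distribution) when significant at ``alpha``.

    ``matrix`` is blocks x treatments (a DataFrame keeps treatment names).
    Ties receive average ranks; fully tied blocks are flagged.
    """
    M = pd.DataFrame(matrix)
    n, k = M.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 treatments and 2 blocks")
    ranks = M.rank(axis=1)  # average ranks on ties
    tied_blocks = int((M.nunique(axis=1) == 1).sum())
    if tied_blocks == n:
        return FriedmanResult(0.0, 1.0, False, ranks.mean(axis=0),
                              tied_blocks=tied_blocks)

    stat, p = stats.friedmanchisquare(*[M.iloc[:, j] for j in range(k)])
    mean_ranks = ranks.mean(axis=0)
    nemenyi = None
    if p < alpha:
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        q = np.abs(mean_ranks.to_numpy()[:, None] - mean_ranks.to_numpy()[None, :]) / se
        pv = stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf)
        np.fill_diagonal(pv, 1.0)
        nemenyi = pd.DataFrame(pv, index=M.columns, columns=M.columns)
    return FriedmanResult(float(stat), float(p), bool(p < alpha), mean_ranks,
                          nemenyi, tied_blocks)


def kendall_concordance(rankings) -> pd.DataFrame:
    """Pairwise Kendall tau-b matrix between importance rankings.

    ``rankings`` is raters x features (rows are models/replicates, columns a
    common feature set; values are importance scores or ranks).
    """
    M = pd.DataFrame(rankings)
    if M.shape[1] < 2:
        raise ValueError("need at least two features to rank")
    n = M.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau = stats.kendalltau(M.iloc[i], M.iloc[j], variant="b").statistic
            out[i, j] = out[j, i] = tau
    return pd.DataFrame(out, index=M.index, columns=M.index)


def permutation_importance(
    model: ClassifierContract, X, y, n_repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Mean AUROC drop over seeded column shuffles (model-agnostic)."""
    Xv = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)
    cols = list(X.columns) if hasattr(X, "columns") else list(range(Xv.shape[1]))
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    base = binary_metrics(model.predict_scores(Xv), y)["auroc"]
    drops = np.zeros(Xv.shape[1])
    for j in range(Xv.shape[1]):
        acc = 0.0
        for _ in range(n_repeats):
            Xp = Xv.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            acc += base - binary_metrics(model.predict_scores(Xp), y)["auroc"]
        drops[j] = acc / n_repeats
    return pd.Series(drops, index=cols)


# ---------------------------------------------------------------------------
# hyperparameter search and cross-validated evaluation

def _sample_grid(grid: dict, rng) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in grid.items()}


def random_search(
    model_name: str,
    grid: dict,
    n_draws: int,
    X,
    y,
    folds: int = 3,
    seed: int = 0,
) -> dict:
    """Random hyperparameter search scored by mean F1 over stratified CV.

    The draw with the highest mean validation F1 wins; ties keep the first
    drawn.  Returns ``{"best": params, "results": tidy frame}``.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best, best_f1 = None, -np.inf
    rows = []
    for d in range(n_draws):
        params = _sample_grid(grid, rng)
        f1s = []
        for fold, (tr, va) in enumerate(skf.split(np.zeros(y.size), y)):
            Xtr = X.iloc[tr] if hasattr(X, "iloc") else X[tr]
            Xva = X.iloc[va] if hasattr(X, "iloc") else X[va]
            clf = make_classifier(model_name, **params).fit(Xtr, y[tr], seed=seed + fold)
            f1s.append(binary_metrics(clf.predict_scores(Xva), y[va])["f1"])
        mean_f1 = float(np.mean(f1s))
        rows.append({"draw": d, **params, "mean_f1": mean_f1})
        if mean_f1 > best_f1:
            best, best_f1 = params, mean_f1
    return {"best": best, "best_f1": best_f1, "results": pd.DataFrame(rows)}


def kfold_evaluate(
    model_name: str,
    hyper: dict,
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold evaluation: each fold's model is scored on its own
    validation fold and (when given) on the fixed test set."""
    y_train = np.asarray(y_train)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(y_train.size), y_train)):
        if np.unique(y_train[va]).size < 2:
            raise ValueError(f"fold {fold} validation split has one class")
        Xtr = X_train.iloc[tr] if hasattr(X_train, "iloc") else X_train[tr]
        Xva = X_train.iloc[va] if hasattr(X_train, "iloc") else X_train[va]
        clf = make_classifier(model_name, **hyper).fit(Xtr, y_train[tr], seed=seed + fold)
        rec = {"model": model_name, "fold": fold, "eval": "validation",
               **binary_metrics(clf.predict_scores(Xva), y_train[va])}
        rows.append(rec)
        if X_test is not None:
            rows.append(
                {"model": model_name, "fold": fold, "eval": "test",
                 **binary_metrics(clf.predict_scores(X_test), np.asarray(y_test))}
            )
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per (model, eval) in the published table layout."""
    g = cv.groupby(["model", "eval"])[list(METRICS)]
    return g.agg(["mean", "std"])
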