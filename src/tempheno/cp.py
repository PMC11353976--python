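"""Non-negative CP (PARAFAC) decomposition by hierarchical ALS.

A three-mode non-negative tensor (patient x time x feature) is approximated
by a sum of R rank-one components, ``X ~ sum_r lambda_r a_r o b_r o c_r``,
with all factors non-negative.  Each component is read as a temporal
phenotype: a patient-membership vector, a temporal signature over the ten
six-month bins, and a clinical feature profile.  Factors are fit by
hierarchical alternating least squares (HALS): column-wise exact coordinate
updates with projection onto ``max(., eps)``, which makes the Frobenius
objective non-increasing at every update.

Held-out patients are scored against a frozen model by non-negative least
squares on the fixed time/feature basis, so the phenotypes themselves never
change after training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

log = logging.getLogger(__name__)

EPS_FLOOR = 1e-12  # non-negativity floor: avoids exactly-dead columns
DEAD_NORM = 1e-10


@dataclass
class CPModel:
    """Rank-R non-negative factor triple with component weights.

    After fitting, the time (B) and feature (C) columns have unit L2 norm;
    their scale is absorbed into ``weights`` so patient memberships are
    ``A @ diag(weights)``.
    """

    rank: int
    weights: np.ndarray  # (R,)
    A: np.ndarray  # patients x R
    B: np.ndarray  # time bins x R
    C: np.ndarray  # features x R
    n_iter: int = 0
    rel_error: float = np.nan
    seed: int | None = None
    time_labels: list = field(default_factory=list)
    feature_labels: list = field(default_factory=list)
    error_history: list = field(default_factory=list)  # rel. error per sweep

    def memberships(self) -> np.ndarray:
        return self.A * self.weights[None, :]


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    order = {0: (0, 1, 2), 1: (1, 0, 2), 2: (2, 0, 1)}[mode]
    Xp = np.transpose(X, order)
    return Xp.reshape(Xp.shape[0], -1)


def khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product, rows ordered with V's index fastest."""
    R = U.shape[1]
    return np.einsum("ir,jr->ijr", U, V).reshape(-1, R)


def _hals_update(U, W, G, rng):
    """In-place HALS sweep over the columns of one factor matrix."""
    R = U.shape[1]
    for r in range(R):
        denom = G[r, r]
        if denom <= EPS_FLOOR:
            U[:, r] = rng.uniform(0.0, 1.0, U.shape[0])
            log.debug("reseeded column %d (zero gram diagonal)", r)
            continue
        u = U[:, r] + (W[:, r] - U @ G[:, r]) / denom
        np.maximum(u, EPS_FLOOR, out=u)
        if np.linalg.norm(u) < DEAD_NORM:
            u = rng.uniform(0.0, 1.0, U.shape[0])
            log.debug("reseeded dead column %d", r)
        U[:, r] = u
    return U


def nncp_hals(
    tensor,
    rank: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> CPModel:
    """Fit a rank-``rank`` non-negative CP model by HALS.

    Initialisation is seeded uniform non-negative.  Iteration stops when the
    relative improvement of the reconstruction error falls below ``tol`` or
    after ``max_iter`` sweeps.  The objective is non-increasing across
    sweeps.
    """
    time_labels, feature_labels = [], []
    if hasattr(tensor, "values") and hasattr(tensor, "features"):
        time_labels = list(tensor.bins)
        feature_labels = list(tensor.features)
        X = np.asarray(tensor.values, dtype=float)
    else:
        X = np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a 3-mode tensor")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if (X < 0).any():
        raise ValueError("tensor must be non-negative")
    if rank > min(X.shape):
        warnings.warn(
            f"rank {rank} exceeds the smallest mode size {min(X.shape)}",
            stacklevel=2,
        )

    normX = np.linalg.norm(X)
    if normX == 0.0:
        Z = [np.zeros((s, rank)) for s in X.shape]
        return CPModel(rank, np.zeros(rank), *Z, n_iter=0, rel_error=0.0,
                       seed=seed, time_labels=time_labels,
                       feature_labels=feature_labels)

    rng = np.random.default_rng(seed)
    factors = [rng.uniform(0.0, 1.0, (s, rank)) for s in X.shape]
    unfolds = [_unfold(X, n) for n in range(3)]

    prev_err = np.inf
    rel_err = np.inf
    n_iter = 0
    history = []
    for sweep in range(max_iter):
        for n in range(3):
            others = [factors[m] for m in range(3) if m != n]
            K = khatri_rao(others[0], others[1])
            W = unfolds[n] @ K
            G = (others[0].T @ others[0]) * (others[1].T @ others[1])
            _hals_update(factors[n], W, G, rng)
        A, B, C = factors
        G_all = (A.T @ A) * (B.T @ B) * (C.T @ C)
        # after the final mode update, W corresponds to mode 2 (C)
        inner = float(np.sum(W * C))
        err2 = max(normX**2 - 2.0 * inner + float(G_all.sum()), 0.0)
        rel_err = np.sqrt(err2) / normX
        history.append(rel_err)
        n_iter = sweep + 1
        if prev_err - rel_err < tol * max(prev_err, 1.0):
            break
        prev_err = rel_err

    A, B, C = factors
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    weights = nb * nc
    with np.errstate(invalid="ignore", divide="ignore"):
        B = np.where(nb > 0, B / np.where(nb > 0, nb, 1.0), B)
        C = np.where(nc > 0, C / np.where(nc > 0, nc, 1.0), C)
    return CPModel(
        rank, weights, A, B, C, n_iter=n_iter, rel_error=float(rel_err),
        seed=seed, time_labels=time_labels, feature_labels=feature_labels,
        error_history=history,
    )


def reconstruct(model: CPModel) -> np.ndarray:
    """Dense reconstruction ``sum_r lambda_r a_r o b_r o c_r``."""
    return np.einsum(
        "r,ir,jr,kr->ijk", model.weights, model.A, model.B, model.C
    )


def project_patients(model: CPModel, new_tensor) -> np.ndarray:
    """Memberships of new patients under frozen time/feature phenotypes.

    Solves, per patient slice x (flattened time x feature), the non-negative
    least-squares problem ``min_{m>=0} ||x - Z m||`` where Z is the
    Khatri-Rao basis of the unit-normalised (B, C); the recovered membership
    therefore carries the component scale, and projecting the training
    tensor returns (up to solver tolerance) ``A @ diag(weights)``.
    """
    if hasattr(new_tensor, "values") and hasattr(new_tensor, "features"):
        if model.feature_labels and list(new_tensor.features) != list(model.feature_labels):
            raise ValueError("feature axis does not match the fitted model")
        X = np.asarray(new_tensor.values, dtype=float)
    else:
        X = np.asarray(new_tensor, dtype=float)
    if X.shape[1:] != (model.B.shape[0], model.C.shape[0]):
        raise ValueError("time/feature axes do not match the fitted model")

    Z = khatri_rao(model.B, model.C)
    M = np.zeros((X.shape[0], model.rank))
    flat = X.reshape(X.shape[0], -1)
    for i in range(X.shape[0]):
        if not flat[i].any():
            continue  # all-zero slice -> zero membership
        M[i], _ = nnls(Z, flat[i])
    return M


def factor_congruence(estimated, truth):
    """Mean matched-factor congruence between two factor lists.

    ``estimated`` and ``truth`` are lists of same-shaped (mode-size x R)
    matrices (any subset of modes).  The congruence of an (estimated, true)
    component pair is the product over modes of the cosine similarity of the
    matched columns; pairs are matched greedily (largest similarity first,
    without replacement).  Returns ``(mean congruence, matches)`` where
    matches is a list of (estimated column, true column, congruence).
    """
    est = [np.asarray(m, dtype=float) for m in estimated]
    tru = [np.asarray(m, dtype=float) for m in truth]
    Re, Rt = est[0].shape[1], tru[0].shape[1]

    def unitcols(M):
        n = np.linalg.norm(M, axis=0)
        return M / np.where(n > 0, n, 1.0)

    S = np.ones((Re, Rt))
    for E, T in zip(est, tru):
        S *= unitcols(E).T @ unitcols(T)

    matches = []
    S = S.copy()
    for _ in range(min(Re, Rt)):
        r, s = np.unravel_index(np.argmax(S), S.shape)
        matches.append((int(r), int(s), float(S[r, s])))
        S[r, :] = -np.inf
        S[:, s] = -np.inf
    mean = float(np.mean([m[2] for m in matches]))
    return mean, matches


def select_rank(
    tensor,
    labels,
    rank_grid=None,
    replicates: int = 3,
    val_fraction: float = 0.3,
    seed: int = 0,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Rank scan: fit replicate decompositions per rank and score a reference
    random-forest classifier on held-out patient memberships.

    Returns a tidy frame of per-(rank, replicate) F1/AUROC/AUPRC with a
    ``suggested`` flag at the maximum-curvature rank of the mean-AUROC curve.
    The final rank remains a configuration choice.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    from tempheno.evaluate import binary_metrics

    if rank_grid is None:
        rank_grid = sorted(set(range(1, 50, 2)) | {50})
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = tensor.values if hasattr(tensor, "values") else np.asarray(tensor)
    if X.shape[0] != y.shape[0]:
        raise ValueError("labels not aligned with tensor patients")

    rng = np.random.default_rng(seed)
    rows = []
    for rank in rank_grid:
        for rep in range(replicates):
            s = int(rng.integers(2**31))
            model = nncp_hals(X, rank, seed=s, max_iter=max_iter)
            M = model.memberships()
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)), test_size=val_fraction,
                random_state=s % (2**31), stratify=y,
            )
            clf = RandomForestClassifier(n_estimators=100, random_state=s % (2**31))
            clf.fit(M[idx_tr], y[idx_tr])
            scores = clf.predict_proba(M[idx_va])[:, 1]
            m = binary_metrics(scores, y[idx_va])
            rows.append(
                {"rank": rank, "replicate": rep, "rel_error": model.rel_error,
                 "f1": m["f1"], "auroc": m["auroc"], "auprc": m["auprc"]}
            )
    out = pd.DataFrame(rows)
    mean_curve = out.groupby("rank")["auroc"].mean()
    out.attrs["suggested_rank"] = _max_curvature_rank(mean_curve)
    return out


def _max_curvature_rank(curve: pd.Series) -> int:
    """Elbow suggestion: rank with the most negative discrete second
    difference of the metric-vs-rank curve (first rank if too short)."""
    ranks = curve.index.to_numpy()
    y = curve.to_numpy()
    if len(y) < 3:
        return int(ranks[np.argmax(y)])
    d2 = y[2:] - 2 * y[1:-1] + y[:-2]
    return int(ranks[1:-1][np.argmin(d2)])


def phenotype_report(model: CPModel, feature_labels=None, k: int = 5) -> list:
    """Per-component report: top-k feature weights (descending), the temporal
    profile, and the max-normalised patient membership column."""
    labels = list(feature_labels) if feature_labels is not None else list(
        model.feature_labels
    )
    if not labels:
        labels = [f"f{j}" for j in range(model.C.shape[0])]
    if k > len(labels):
        raise ValueError("k exceeds the number of features")
    report = []
    M = model.memberships()
    for r in range(model.rank):
        c = model.C[:, r]
        top = np.argsort(-c, kind="stable")[:k]
        col = M[:, r]
        norm = col / col.max() if col.max() > 0 else col
        report.append(
            {
                "component": r,
                "weight": float(model.weights[r]),
                "top_features": [(labels[j], float(c[j])) for j in top],
                "time_profile": model.B[:, r].copy(),
                "membership": norm,
            }
        )
    return report
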