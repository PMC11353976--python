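"""Tropical-geometry fuzzy neural network (TGFNN).

An interpretable classifier built from fuzzy logic: continuous inputs are
"fuzzified" into their membership of the concepts low / medium / high via
learnable Gaussian membership functions; a rule module learns, per rule,
which concept of each variable matters (concept attention) and how important
each variable is; rule activation is a parameterised T-norm (AND) that
interpolates continuously between product and minimum; an inference layer
aggregates importance-weighted rule strengths through a parameterised
T-conorm (OR) interpolating between sum and maximum — the tropical max-plus
end of the bridge — followed by softmax.

Everything is plain numpy with hand-derived analytic gradients (verified
against finite differences in the test suite) and a small Adam optimiser, so
training needs no deep-learning framework.

Parameterisation notes.  Concept attention is a masked softmax per
(rule, variable), so attention weights are non-negative and sum to one over
the concepts of each variable.  Variable and rule importances use a softplus
reparameterisation (non-negative, stable gradients).  The T-norm bridge is a
convex combination in the log domain, ``L = tau*sum(g) + (1-tau)*min(g)``
with ``g = w * log(s)``: ``tau = 1`` gives the exact weighted product and
``tau = 0`` the exact weighted minimum.  The T-conorm is the symmetric
construction between sum and max in the linear domain.  Binary (one-hot)
variables contribute the two concepts (absent, present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

S_EPS = 1e-12  # floor inside log() of the T-norm
N_CONCEPTS = 3
CONCEPT_NAMES = ("low", "medium", "high")
BINARY_CONCEPT_NAMES = ("absent", "present")


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class MembershipParams:
    """Gaussian concept membership functions per continuous variable."""

    centers: np.ndarray  # (V, 3)
    widths: np.ndarray  # (V, 3), > 0
    is_binary: np.ndarray  # (V,), bool

    def __post_init__(self):
        if (self.widths <= 0).any():
            raise ValueError("membership widths must be positive")


@dataclass
class RuleBank:
    """Effective (post-reparameterisation) rule parameters.

    ``tnorm_tau``: 1.0 -> product AND, 0.0 -> minimum AND.
    ``tconorm_tau``: 1.0 -> additive OR, 0.0 -> maximum OR.
    """

    concept_attention: np.ndarray  # (R, V, 3), >= 0, sums to 1 per (r, v)
    variable_importance: np.ndarray  # (R, V), >= 0
    rule_importance: np.ndarray  # (R, C), >= 0
    tnorm_tau: float = 0.5
    tconorm_tau: float = 0.5

    @property
    def n_rules(self) -> int:
        return self.concept_attention.shape[0]

    def __post_init__(self):
        if (self.concept_attention < 0).any() or (self.variable_importance < 0).any():
            raise ValueError("attention and importance weights must be >= 0")
        sums = self.concept_attention.sum(axis=2)
        active = self.concept_attention.max(axis=2) > 0
        if not np.allclose(sums[active], 1.0, atol=1e-6):
            raise ValueError("concept attention must sum to 1 per (rule, variable)")


# ---------------------------------------------------------------------------
# forward primitives (operate on effective parameters)

def fuzzify(X: np.ndarray, params: MembershipParams) -> np.ndarray:
    """Concept memberships in [0, 1]: Gaussians for continuous variables,
    (1-x, x, 0) pass-through for binary ones.  Returns (N, V, 3)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    z = (X[:, :, None] - params.centers[None]) / params.widths[None]
    m = np.exp(-0.5 * z**2)
    binm = np.stack(
        [1.0 - X, X, np.zeros_like(X)], axis=2
    )
    return np.where(params.is_binary[None, :, None], binm, m)


def rule_activation(memberships: np.ndarray, bank: RuleBank) -> np.ndarray:
    """Per-rule activation strength in [0, 1].

    Variable-level score = attention-weighted membership; rule strength is
    the parameterised T-norm of ``score ** importance`` over variables, so a
    variable with importance 0 contributes neutrally (as 1).
    """
    m = np.atleast_3d(np.asarray(memberships, dtype=float))
    s = np.einsum("nvc,rvc->nrv", m, bank.concept_attention)
    g = bank.variable_importance[None] * np.log(s + S_EPS)
    tau = bank.tnorm_tau
    L = tau * g.sum(axis=2) + (1.0 - tau) * g.min(axis=2)
    return np.exp(L)


def infer(strengths: np.ndarray, bank: RuleBank) -> np.ndarray:
    """Class probabilities from rule strengths.

    Per class, the T-conorm (sum <-> max bridge) of rule-importance-weighted
    strengths gives the logit; softmax normalises across classes.
    """
    F = np.atleast_2d(np.asarray(strengths, dtype=float))
    if (F < 0).any():
        raise ValueError("rule strengths must be >= 0")
    h = F[:, :, None] * bank.rule_importance[None]  # (N, R, C)
    tau = bank.tconorm_tau
    z = tau * h.sum(axis=1) + (1.0 - tau) * h.max(axis=1)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# trainable model

def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-np.clip(y, 1e-10, None)))


@dataclass
class TGFNNConfig:
    n_rules: int = 8
    lr: float = 0.05
    epochs: int = 300
    patience: int = 60
    val_fraction: float = 0.1
    l2: float = 1e-4
    l1_importance: float = 0.01  # sparsity pressure on variable importances
    seed: int = 0


@dataclass
class TGFNNModel:
    config: TGFNNConfig
    feature_names: list
    is_binary: np.ndarray
    x_min: np.ndarray
    x_max: np.ndarray
    params: dict  # raw trainable arrays
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))
    history: list = field(default_factory=list)

    # -- effective views -----------------------------------------------------
    def membership_params(self) -> MembershipParams:
        return MembershipParams(
            centers=self.params["mu"].copy(),
            widths=np.exp(self.params["logsig"]),
            is_binary=self.is_binary,
        )

    def rule_bank(self) -> RuleBank:
        att = _masked_softmax(self.params["Araw"], self._concept_mask())
        return RuleBank(
            concept_attention=att,
            variable_importance=_softplus(self.params["Wraw"]),
            rule_importance=_softplus(self.params["Rraw"]),
            tnorm_tau=float(_sigmoid(self.params["ta_raw"])),
            tconorm_tau=float(_sigmoid(self.params["to_raw"])),
        )

    def _concept_mask(self) -> np.ndarray:
        mask = np.ones((len(self.feature_names), N_CONCEPTS), dtype=bool)
        mask[self.is_binary, 2] = False
        return mask

    def _scale(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rng = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        Z = (X - self.x_min) / rng
        return np.clip(Z, -0.5, 1.5)  # mild clip outside the train range

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        Z = self._scale(X)
        bank = self.rule_bank()
        m = fuzzify(Z, self.membership_params())
        return infer(rule_activation(m, bank), bank)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _masked_softmax(raw: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the concept axis restricted to each variable's concepts."""
    z = np.where(mask[None], raw, -np.inf)
    z = z - z.max(axis=2, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=2, keepdims=True)


def _loss_and_grads(params, mask, is_binary, X, y, cw, l2, l1=0.0):
    """Class-weighted cross-entropy and analytic gradients.

    Forward pass mirrors fuzzify -> rule_activation -> infer with the raw
    parameterisation; gradients are derived by hand and checked against
    finite differences in the test suite.
    """
    N, V = X.shape
    mu, logsig = params["mu"], params["logsig"]
    sig = np.exp(logsig)

    # fuzzify
    zsc = (X[:, :, None] - mu[None]) / sig[None]
    m_gauss = np.exp(-0.5 * zsc**2)
    m_bin = np.stack([1.0 - X, X, np.zeros_like(X)], axis=2)
    m = np.where(is_binary[None, :, None], m_bin, m_gauss)

    att = _masked_softmax(params["Araw"], mask)  # (R, V, 3)
    w = _softplus(params["Wraw"])  # (R, V)
    rho = _softplus(params["Rraw"])  # (R, C)
    ta = float(_sigmoid(params["ta_raw"]))
    to = float(_sigmoid(params["to_raw"]))

    s = np.einsum("nvc,rvc->nrv", m, att)
    logs = np.log(s + S_EPS)
    g = w[None] * logs  # (N, R, V)
    gmin_idx = g.argmin(axis=2)  # (N, R)
    gsum = g.sum(axis=2)
    gmin = np.take_along_axis(g, gmin_idx[:, :, None], axis=2)[:, :, 0]
    L = ta * gsum + (1.0 - ta) * gmin
    F = np.exp(L)  # (N, R)

    h = F[:, :, None] * rho[None]  # (N, R, C)
    hmax_idx = h.argmax(axis=1)  # (N, C)
    hsum = h.sum(axis=1)
    hmax = np.take_along_axis(h, hmax_idx[:, None, :], axis=1)[:, 0, :]
    zlog = to * hsum + (1.0 - to) * hmax
    zc = zlog - zlog.max(axis=1, keepdims=True)
    ez = np.exp(zc)
    p = ez / ez.sum(axis=1, keepdims=True)

    wn = cw[y]
    Wtot = wn.sum()
    ll = -np.log(p[np.arange(N), y] + 1e-300)
    loss = float((wn * ll).sum() / Wtot)

    # backward
    dz = p.copy()
    dz[np.arange(N), y] -= 1.0
    dz *= (wn / Wtot)[:, None]  # (N, C)

    onehot_max = np.zeros_like(h)
    np.put_along_axis(onehot_max, hmax_idx[:, None, :], 1.0, axis=1)
    dh = dz[:, None, :] * (to + (1.0 - to) * onehot_max)
    dto_eff = float((dz * (hsum - hmax)).sum())
    drho = np.einsum("nrc,nr->rc", dh, F)
    dF = np.einsum("nrc,rc->nr", dh, rho)

    dL = dF * F
    onehot_min = np.zeros_like(g)
    np.put_along_axis(onehot_min, gmin_idx[:, :, None], 1.0, axis=2)
    dg = dL[:, :, None] * (ta + (1.0 - ta) * onehot_min)
    dta_eff = float((dL * (gsum - gmin)).sum())
    dw = np.einsum("nrv,nrv->rv", dg, logs)
    ds = dg * w[None] / (s + S_EPS)

    datt = np.einsum("nrv,nvc->rvc", ds, m)
    dm = np.einsum("nrv,rvc->nvc", ds, att)

    # masked softmax backprop per (r, v)
    inner = (att * datt).sum(axis=2, keepdims=True)
    dAraw = att * (datt - inner)

    # membership backprop (continuous variables only)
    dmu = np.einsum(
        "nvc,nvc->vc", dm * m_gauss, zsc / sig[None]
    )
    dlogsig = np.einsum("nvc,nvc->vc", dm * m_gauss, zsc**2)
    dmu[is_binary] = 0.0
    dlogsig[is_binary] = 0.0

    grads = {
        "mu": dmu,
        "logsig": dlogsig,
        "Araw": np.where(mask[None], dAraw, 0.0),
        "Wraw": dw * _sigmoid(params["Wraw"]),
        "Rraw": drho * _sigmoid(params["Rraw"]),
        "ta_raw": np.array(dta_eff * ta * (1.0 - ta)),
        "to_raw": np.array(dto_eff * to * (1.0 - to)),
    }
    if l2 > 0:
        for key in ("Wraw", "Rraw", "Araw"):
            loss += 0.5 * l2 * float((params[key] ** 2).sum())
            grads[key] = grads[key] + l2 * params[key]
    if l1 > 0:  # lasso on the effective importances: prunes idle variables
        loss += l1 * float(w.sum())
        grads["Wraw"] = grads["Wraw"] + l1 * _sigmoid(params["Wraw"])
    return loss, grads


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mh / (np.sqrt(vh) + self.eps)


def _detect_binary(X: np.ndarray) -> np.ndarray:
    out = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        u = np.unique(X[:, j])
        out[j] = np.all(np.isin(u, (0.0, 1.0)))
    return out


def _f1(y_true, y_pred) -> float:
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def fit_tgfnn(
    X,
    y,
    class_weights=None,
    config: TGFNNConfig | None = None,
    seed: int | None = None,
) -> TGFNNModel:
    """Train a TGFNN by full-batch Adam on class-weighted cross-entropy.

    Continuous features are min-max scaled to the training range; Gaussian
    concept centers start at the scaled 25th/50th/75th percentiles with
    widths of half the inter-quartile gap.  A held-out fraction of the
    training data drives early stopping on F1; the best checkpoint is kept.
    With ``epochs=0`` the returned model equals its initialisation.
    """
    config = config or TGFNNConfig()
    if seed is not None:
        config = TGFNNConfig(**{**config.__dict__, "seed": seed})
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(config.seed)
    is_binary = _detect_binary(X)
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    x_min[is_binary], x_max[is_binary] = 0.0, 1.0
    rngspan = np.where(x_max > x_min, x_max - x_min, 1.0)
    Z = (X - x_min) / rngspan

    V, R, C = X.shape[1], config.n_rules, classes.size
    q = np.nanpercentile(Z, [25, 50, 75], axis=0).T  # (V, 3)
    widths = np.maximum((q[:, 2] - q[:, 0]) / 2.0, 0.05)
    params = {
        "mu": q.copy(),
        "logsig": np.log(np.repeat(widths[:, None], 3, axis=1)),
        "Araw": 0.1 * rng.standard_normal((R, V, N_CONCEPTS)),
        "Wraw": rng.normal(-1.0, 0.5, (R, V)),
        "Rraw": rng.normal(-0.5, 0.5, (R, C)),
        "ta_raw": np.array(0.0),
        "to_raw": np.array(0.0),
    }
    mask = np.ones((V, N_CONCEPTS), dtype=bool)
    mask[is_binary, 2] = False

    if class_weights is None:
        counts = np.bincount(y, minlength=C)
        cw = y.size / (C * np.maximum(counts, 1))
    else:
        cw = np.array([class_weights[c] for c in classes], dtype=float)

    model = TGFNNModel(
        config=config, feature_names=names, is_binary=is_binary,
        x_min=x_min, x_max=x_max, params=params, classes_=classes,
    )
    if config.epochs == 0:
        return model

    # early-stopping split
    n_val = max(int(round(config.val_fraction * y.size)), 2)
    perm = rng.permutation(y.size)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[tr_idx]).size < 2 or np.unique(y[val_idx]).size < 2:
        val_idx = tr_idx = perm  # degenerate split: train == val
    Ztr, ytr = Z[tr_idx], y[tr_idx]
    Zva, yva = Z[val_idx], y[val_idx]

    opt = _Adam(params, config.lr)
    best = {k: v.copy() for k, v in params.items()}
    best_f1, since_best = -1.0, 0
    for epoch in range(config.epochs):
        loss, grads = _loss_and_grads(
            params, mask, is_binary, Ztr, ytr, cw, config.l2, config.l1_importance
        )
        opt.step(params, grads)
        probs = model.predict_proba(Zva * rngspan + x_min)
        f1 = _f1(yva, classes[probs.argmax(axis=1)])
        model.history.append({"epoch": epoch, "loss": loss, "val_f1": f1})
        if f1 > best_f1 + 1e-12:
            best_f1, since_best = f1, 0
            best = {k: v.copy() for k, v in params.items()}
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.params = best
    return model


def planted_rule_data(n: int, seed: int, n_noise_vars: int = 2):
    """Data generated BY a known 2-rule fuzzy model.

    Six uniform variables; the positive class fires when either planted rule
    activates: ``x0 low AND x1 high`` or ``x2 high AND x3 low`` (Gaussian
    concepts, max-OR, 0.35 activation threshold).  The remaining variables
    are pure noise.  Returns ``(X, y, planted_rules)`` where planted_rules
    lists each rule's defining variables.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, (n, 4 + n_noise_vars))

    def gauss(x, c, w=0.2):
        return np.exp(-0.5 * ((x - c) / w) ** 2)

    rule_a = gauss(X[:, 0], 0.15) * gauss(X[:, 1], 0.85)
    rule_b = gauss(X[:, 2], 0.85) * gauss(X[:, 3], 0.15)
    y = (np.maximum(rule_a, rule_b) > 0.35).astype(int)
    return X, y, [["x0", "x1"], ["x2", "x3"]]


def rule_recovery_study(
    base_seed: int = 0,
    replicates: int = 3,
    n_train: int = 1500,
    n_test: int = 800,
    n_rules: int = 12,
    top_k: int = 3,
    threshold: float = 0.1,
) -> dict:
    """Train TGFNN replicates on planted 2-rule data and score recovery.

    Mirrors how rules are read off cross-validation replicates: each
    replicate is trained with its own seed, rules extracted at ``threshold``
    are pooled, and a planted rule counts as recovered when its defining
    variables all appear among the top-``top_k`` weighted variables of some
    extracted rule.  Returns accuracies per replicate and recovery flags.
    """
    Xtr, ytr, planted = planted_rule_data(n_train, base_seed + 1)
    Xte, yte, _ = planted_rule_data(n_test, base_seed + 2)
    accs, pooled_tops = [], []
    for rep in range(replicates):
        cfg = TGFNNConfig(
            n_rules=n_rules, epochs=2000, patience=300, lr=0.05,
            seed=base_seed + rep,
        )
        model = fit_tgfnn(Xtr, ytr, config=cfg)
        accs.append(float((model.predict(Xte) == yte).mean()))
        for rule in extract_rules(model, threshold=threshold):
            pooled_tops.append(
                [c["variable"] for c in rule["clauses"][:top_k]]
            )
    recovered = [
        any(set(p) <= set(top) for top in pooled_tops) for p in planted
    ]
    return {
        "accuracy": accs,
        "recovered": recovered,
        "planted": planted,
        "pooled_rule_tops": pooled_tops,
    }


def extract_rules(model: TGFNNModel, threshold: float = 0.1, positive_class: int = 1):
    """Human-readable rules, pruned at ``threshold`` relative importance.

    Rules are ranked by their relative contribution to the positive class
    (rule importance normalised by the largest); within a rule, variables
    below ``threshold`` relative importance are dropped and each survivor is
    rendered with its highest-attention concept, e.g.
    ``"glucose is high AND age is medium"``.
    """
    bank = model.rule_bank()
    cls_col = int(np.where(model.classes_ == positive_class)[0][0])
    rho = bank.rule_importance[:, cls_col]
    # relative contribution = share of the total rule importance
    rel = rho / rho.sum() if rho.sum() > 0 else np.full_like(rho, 1.0 / len(rho))
    order = np.argsort(-rel, kind="stable")

    rules = []
    for r in order:
        if rel[r] < threshold:
            continue
        w = bank.variable_importance[r]
        wrel = w / w.max() if w.max() > 0 else w
        clauses = []
        for v in np.argsort(-wrel, kind="stable"):
            if wrel[v] < threshold:
                continue
            names = (
                BINARY_CONCEPT_NAMES if model.is_binary[v] else CONCEPT_NAMES
            )
            concept = names[int(bank.concept_attention[r, v, : len(names)].argmax())]
            clauses.append(
                {
                    "variable": model.feature_names[v],
                    "concept": concept,
                    "importance": float(wrel[v]),
                }
            )
        text = " AND ".join(f"{c['variable']} is {c['concept']}" for c in clauses)
        rules.append(
            {
                "rule": int(r),
                "relative_importance": float(rel[r]),
                "clauses": clauses,
                "text": text,
            }
        )
    return rules
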