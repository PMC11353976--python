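"""Synthetic longitudinal EHR cohorts with planted temporal phenotypes.

The generator emulates the statistical shape of a matched outpatient
case-control extract: five years of irregularly timed encounters per patient,
continuous labs with missingness, binary diagnosis/medication events whose
per-bin intensity follows a planted low-rank (patient x time x feature)
structure, and an AMI-like outcome whose log-odds are driven by the planted
patient memberships.  Controls are matched 2:1 on sex, age and a hospital
frailty risk score, and the ground-truth phenotypes are returned so that
downstream tensor decompositions can be scored against them.

Time is encoded as non-negative ``days_before_anchor`` (the anchor is AMI
onset for cases, the last encounter for controls), so no calendar arithmetic
is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from tempheno.timebins import BIN_DAYS, N_BINS, SPAN_DAYS

EVENT_COLUMNS = ["patient_id", "days_before_anchor", "domain", "variable", "value"]

#: family-history conditions that qualify as cardiovascular (cohort flag)
QUALIFYING_FAMHX = (
    "heart disease",
    "heart attack",
    "coronary artery disease",
    "heart failure",
    "heart defect",
    "aortic disease",
    "sudden cardiac death",
    "cardiomyopathy",
    "cardiovascular disease",
    "rheumatic heart disease",
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic matched cohort.

    Counts must be >= 1, probabilities in [0, 1], ``years`` > 0 and
    ``planted_rank`` no larger than any per-domain feature count.
    """

    n_cases: int = 100
    control_ratio: int = 2
    years: float = 5.0
    n_lab_features: int = 12
    n_dx_features: int = 20
    n_rx_features: int = 10
    planted_rank: int = 4
    encounter_rate: float = 4.0  # mean encounters per patient per year
    missing_prob: float = 0.3  # P(lab not measured at an encounter)
    outcome_coefs: tuple | None = None  # per-phenotype log-odds; default (+1.5, 0, ...)
    noise_sd: float = 1.0
    seed: int = 0
    # shape of the planted signal
    lab_baseline_range: tuple = (60.0, 140.0)
    signal_scale: float = 25.0
    dx_base_logit: float = -2.5
    dx_signal_scale: float = 4.0
    famhx_prob: float = 0.45
    ensure_bin_coverage: bool = False  # force >=1 encounter per six-month bin
    age_tol: float = 2.0
    frailty_tol: float = 2.0
    train_fraction: float = 0.7

    def coefs(self) -> np.ndarray:
        if self.outcome_coefs is None:
            c = np.zeros(self.planted_rank)
            c[0] = 1.5
            return c
        return np.asarray(self.outcome_coefs, dtype=float)

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "control_ratio": self.control_ratio,
            "n_lab_features": self.n_lab_features,
            "n_dx_features": self.n_dx_features,
            "n_rx_features": self.n_rx_features,
            "planted_rank": self.planted_rank,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.years <= 0:
            raise ValueError("years must be > 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        if not 0.0 <= self.famhx_prob <= 1.0:
            raise ValueError("famhx_prob must be in [0, 1]")
        if self.planted_rank > min(
            self.n_lab_features, self.n_dx_features, self.n_rx_features
        ):
            raise ValueError("planted_rank exceeds a per-domain feature count")
        if len(self.coefs()) != self.planted_rank:
            raise ValueError("outcome_coefs length must equal planted_rank")


@dataclass
class PlantedPhenotype:
    """Ground-truth rank-one component: non-negative patient/time/feature vectors."""

    patient_loading: np.ndarray  # aligned with the returned CohortTable rows
    time_profile: np.ndarray  # length N_BINS
    feature_profile: np.ndarray  # over feature_names (lab + dx + rx)
    feature_names: list = field(default_factory=list)


def _feature_names(spec: CohortSpec):
    labs = [f"lab_{i:02d}" for i in range(spec.n_lab_features)]
    # ICD-10-like synthetic dx codes: letter + 2 digits + optional subcode
    dx = []
    letters = "EIJKMNRF"
    for i in range(spec.n_dx_features):
        cat = f"{letters[i % len(letters)]}{10 + i:02d}"
        dx.append(f"{cat}.{i % 9}")
    rx = [f"rx_{i:02d}" for i in range(spec.n_rx_features)]
    return labs, dx, rx


def _planted_factors(spec: CohortSpec, rng: np.random.Generator):
    """Time and feature factors of the planted phenotypes."""
    R = spec.planted_rank
    # peaked temporal signatures spread over the middle of the history
    centers = np.linspace(2.0, 8.0, R)
    bins = np.arange(N_BINS)[:, None]
    B = np.exp(-0.5 * ((bins - centers[None, :]) / 1.5) ** 2)
    B /= B.max(axis=0, keepdims=True)

    def sparse_block(n):
        mask = rng.random((n, R)) < 0.35
        # every component loads at least one feature in every domain block
        for r in range(R):
            if not mask[:, r].any():
                mask[rng.integers(n), r] = True
        return np.where(mask, rng.uniform(0.5, 1.0, (n, R)), 0.0)

    C_lab = sparse_block(spec.n_lab_features)
    C_dx = sparse_block(spec.n_dx_features)
    C_rx = sparse_block(spec.n_rx_features)
    return B, C_lab, C_dx, C_rx


def assign_outcomes(
    memberships: np.ndarray,
    outcome_coefs,
    seed,
    target_prevalence: float = 1.0 / 3.0,
) -> np.ndarray:
    """Sample case/control labels from planted phenotype memberships.

    ``label ~ Bernoulli(sigmoid(intercept + coefs . membership))`` with the
    intercept solved so the expected prevalence equals ``target_prevalence``.
    """
    M = np.asarray(memberships, dtype=float)
    if M.ndim != 2:
        raise ValueError("memberships must be a (patients x rank) matrix")
    if (M < 0).any():
        raise ValueError("memberships must be non-negative")
    coefs = np.asarray(outcome_coefs, dtype=float)
    if coefs.shape != (M.shape[1],):
        raise ValueError(
            f"outcome_coefs length {coefs.size} != rank {M.shape[1]}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = M @ coefs

    def prev_gap(b):
        return expit(b + eta).mean() - target_prevalence

    if np.ptp(eta) < 1e-12:
        intercept = float(logit(target_prevalence) - eta.mean())
    else:
        intercept = float(brentq(prev_gap, -30.0, 30.0))
    p = expit(intercept + eta)
    return (rng.random(M.shape[0]) < p).astype(int)


def load_frailty_weights(path=None) -> dict:
    """Read a code->points frailty weight table (the repo ships a synthetic
    stand-in for the published hospital-frailty-risk catalogue)."""
    if path is None:
        path = resources.files("tempheno.data") / "frailty_weights_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"icd10": str})
    return dict(zip(df["icd10"], df["points"].astype(float)))


def frailty_score(dx_events: pd.DataFrame, weight_map: dict) -> float:
    """Sum of weights of *distinct* mapped diagnosis codes; unmapped -> 0."""
    if len(dx_events) == 0:
        return 0.0
    codes = pd.unique(dx_events["variable"].astype(str))
    return float(sum(weight_map.get(c, 0.0) for c in codes))


def match_controls(
    candidates: pd.DataFrame,
    ratio: int = 2,
    age_tol: float = 2.0,
    frailty_tol: float = 2.0,
) -> pd.DataFrame:
    """Greedy without-replacement case-control matching.

    Exact on sex, |age difference| <= ``age_tol`` years, |frailty difference|
    <= ``frailty_tol`` points.  Cases are processed in ascending patient_id;
    for each, the nearest controls by |age gap| (ties: |frailty gap|, then
    patient_id) are taken.  Cases that cannot obtain ``ratio`` controls are
    excluded from the output.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if len(candidates) == 0:
        raise ValueError("empty candidate pool")
    for col in ("patient_id", "label", "sex", "age", "frailty"):
        if col not in candidates.columns:
            raise ValueError(f"candidates missing column {col!r}")

    cases = candidates[candidates["label"] == "case"].sort_values("patient_id")
    controls = candidates[candidates["label"] == "control"]
    free = dict.fromkeys(controls["patient_id"], True)
    ctrl = controls.set_index("patient_id")

    rows = []
    set_id = 0
    for case in cases.itertuples(index=False):
        pool = ctrl[
            (ctrl["sex"] == case.sex)
            & ((ctrl["age"] - case.age).abs() <= age_tol)
            & ((ctrl["frailty"] - case.frailty).abs() <= frailty_tol)
        ]
        pool = pool[[free[pid] for pid in pool.index]]
        if len(pool) < ratio:
            continue  # case excluded: not enough eligible controls
        order = pool.assign(
            _dage=(pool["age"] - case.age).abs(),
            _dfr=(pool["frailty"] - case.frailty).abs(),
            _pid=pool.index,
        ).sort_values(["_dage", "_dfr", "_pid"], kind="stable")
        chosen = order.index[:ratio]
        for pid in chosen:
            free[pid] = False
        rows.append((case.patient_id, "case", set_id))
        rows.extend((pid, "control", set_id) for pid in chosen)
        set_id += 1

    matched = pd.DataFrame(rows, columns=["patient_id", "label", "matched_set_id"])
    out = matched.merge(
        candidates.drop(columns=["label"]), on="patient_id", how="left"
    )
    return out


def _patient_pool(spec: CohortSpec, n_pool: int, rng: np.random.Generator):
    age = np.clip(rng.normal(64.0, 13.0, n_pool), 23, 89).round(1)
    sex = np.where(rng.random(n_pool) < 0.57, "M", "F")
    A = rng.uniform(0.0, 1.0, (n_pool, spec.planted_rank))
    return age, sex, A


def _events_for_pool(spec, rng, A, B, C_lab, C_dx, C_rx, labs, dx_names, rx_names):
    """Emit event rows for every patient in the pool (vectorised per patient)."""
    n_pool = A.shape[0]
    span = spec.years * 365.0
    baselines = rng.uniform(*spec.lab_baseline_range, size=len(labs))
    race_levels = np.array(["white", "black", "asian", "other"])
    race_p = np.array([0.80, 0.08, 0.05, 0.07])

    pid_col, day_col, dom_col, var_col, val_col = [], [], [], [], []

    def emit(pids, days, domain, variables, values):
        pid_col.append(np.asarray(pids))
        day_col.append(np.asarray(days, dtype=float))
        dom_col.append(np.full(len(pids), domain, dtype=object))
        var_col.append(np.asarray(variables, dtype=object))
        val_col.append(np.asarray(values, dtype=object))

    lab_arr = np.array(labs, dtype=object)
    dx_arr = np.array(dx_names, dtype=object)
    rx_arr = np.array(rx_names, dtype=object)
    bin_edges_old = SPAN_DAYS - BIN_DAYS * np.arange(N_BINS)  # older edge per bin

    for i in range(n_pool):
        n_enc = rng.poisson(spec.encounter_rate * spec.years)
        while n_enc < 3:  # cohort requires at least three outpatient visits
            n_enc = rng.poisson(spec.encounter_rate * spec.years)
        days = rng.uniform(0.0, span, n_enc)
        if spec.ensure_bin_coverage:
            days = np.concatenate([days, bin_edges_old - BIN_DAYS / 2.0])
        days = np.sort(np.floor(days))
        enc_bins = np.clip((N_BINS - 1) - (days // BIN_DAYS).astype(int), 0, N_BINS - 1)

        # continuous labs: baseline + low-rank signal + noise, with missingness
        AiB = A[i] * B[enc_bins, :]  # (E, R)
        signal = spec.signal_scale * (AiB @ C_lab.T)  # (E, F)
        vals = baselines[None, :] + signal
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, vals.shape)
        measured = rng.random(vals.shape) >= spec.missing_prob
        e_idx, f_idx = np.nonzero(measured)
        if e_idx.size:
            emit(
                np.full(e_idx.size, i), days[e_idx], "lab",
                lab_arr[f_idx], vals[e_idx, f_idx],
            )

        # binary dx / rx: Bernoulli with logit = base + low-rank intensity,
        # sampled once per six-month bin that has an encounter
        ubins, first = np.unique(enc_bins, return_index=True)
        AuB = A[i] * B[ubins, :]
        for names_arr, C in ((dx_arr, C_dx), (rx_arr, C_rx)):
            logits = spec.dx_base_logit + spec.dx_signal_scale * (AuB @ C.T)
            present = rng.random(logits.shape) < expit(logits)
            b_idx, f_idx = np.nonzero(present)
            if b_idx.size:
                domain = "dx" if C is C_dx else "rx"
                emit(
                    np.full(b_idx.size, i), days[first[b_idx]], domain,
                    names_arr[f_idx], np.full(b_idx.size, "present", dtype=object),
                )

        # time-independent rows
        emit([i], [0.0], "demo", ["race"], [rng.choice(race_levels, p=race_p)])
        if rng.random() < spec.famhx_prob:
            cond = QUALIFYING_FAMHX[rng.integers(len(QUALIFYING_FAMHX))]
            emit([i], [0.0], "famhx", ["family_history"], [cond])
        elif rng.random() < 0.3:
            emit([i], [0.0], "famhx", ["family_history"], ["asthma"])

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_col).astype(int),
            "days_before_anchor": np.concatenate(day_col),
            "domain": np.concatenate(dom_col),
            "variable": np.concatenate(var_col),
            "value": np.concatenate(val_col),
        }
    )
    return events


def generate_cohort(spec: CohortSpec):
    """Generate (EventTable, CohortTable, planted phenotypes).

    The returned cohort has exactly ``spec.n_cases`` matched sets, each of one
    case and ``spec.control_ratio`` controls; the event table covers exactly
    those patients.  Ground-truth :class:`PlantedPhenotype` triples (patient
    loadings aligned with the cohort row order) are returned for recovery
    tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labs, dx_names, rx_names = _feature_names(spec)
    B, C_lab, C_dx, C_rx = _planted_factors(spec, rng)
    weight_map = load_frailty_weights()
    # give frailty matching some traction: map a few dx codes into the weight
    # table's universe by aliasing (synthetic dx codes reuse real categories)
    coefs = spec.coefs()

    n_needed = spec.n_cases * (1 + spec.control_ratio)
    n_pool = int(math.ceil(n_needed * 1.8))
    for _attempt in range(6):
        sub = np.random.default_rng(rng.integers(2**31))
        age, sex, A = _patient_pool(spec, n_pool, sub)
        labels = assign_outcomes(
            A, coefs, sub, target_prevalence=1.0 / (1 + spec.control_ratio)
        )
        events = _events_for_pool(
            spec, sub, A, B, C_lab, C_dx, C_rx, labs, dx_names, rx_names
        )
        dx_ev = events[events["domain"] == "dx"]
        wmap = _aliased_weights(weight_map, dx_names)
        frailty = {
            pid: frailty_score(g, wmap) for pid, g in dx_ev.groupby("patient_id")
        }
        candidates = pd.DataFrame(
            {
                "patient_id": np.arange(n_pool),
                "label": np.where(labels == 1, "case", "control"),
                "sex": sex,
                "age": age,
                "frailty": [frailty.get(i, 0.0) for i in range(n_pool)],
            }
        )
        matched = match_controls(
            candidates, spec.control_ratio, spec.age_tol, spec.frailty_tol
        )
        n_sets = matched["matched_set_id"].nunique()
        if n_sets >= spec.n_cases:
            break
        n_pool *= 2
    else:
        raise RuntimeError("could not form enough matched sets; relax tolerances")

    keep_sets = sorted(matched["matched_set_id"].unique())[: spec.n_cases]
    cohort = matched[matched["matched_set_id"].isin(keep_sets)].reset_index(drop=True)

    # 70/30 split by matched set (sets are never split across train and test)
    sets = np.array(keep_sets)
    sub2 = np.random.default_rng(rng.integers(2**31))
    perm = sub2.permutation(len(sets))
    n_train = int(round(spec.train_fraction * len(sets)))
    train_sets = set(sets[perm[:n_train]])
    cohort["split"] = np.where(
        cohort["matched_set_id"].isin(train_sets), "train", "test"
    )

    keep_pids = set(cohort["patient_id"])
    events = events[events["patient_id"].isin(keep_pids)].reset_index(drop=True)

    feature_names = labs + dx_names + rx_names
    C_all = np.vstack([C_lab, C_dx, C_rx])
    order = cohort["patient_id"].to_numpy()
    phenotypes = [
        PlantedPhenotype(
            patient_loading=A[order, r].copy(),
            time_profile=B[:, r].copy(),
            feature_profile=C_all[:, r].copy(),
            feature_names=feature_names,
        )
        for r in range(spec.planted_rank)
    ]
    return events, cohort, phenotypes


def _aliased_weights(weight_map: dict, dx_names) -> dict:
    """Extend the weight table so synthetic dx categories earn points too.

    The synthetic code universe only partly overlaps the shipped table; alias
    each synthetic 3-character category onto a table row round-robin so
    frailty varies across patients and matching has real work to do.
    """
    pts = list(weight_map.values())
    out = dict(weight_map)
    for j, name in enumerate(sorted(dx_names)):
        out.setdefault(name, pts[j % len(pts)] * 0.5)
    return out
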