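"""Feature representations: latest values, five-year summaries, EHR tensors.

Three views of a patient's history feed the classifiers: (1) the most recent
value of each variable plus demographics, (2) mean/SD/min/max summary
statistics over the full five-year window, and (3) two non-negative
(patient x time-bin x feature) tensors — discretised labs/vitals, and binary
diagnosis/medication occupancy — whose CP decomposition yields temporal
phenotypes.  Provenance tags (``latest``/``demo``/``stat``/``phenotype``)
travel with every column via ``DataFrame.attrs["provenance"]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tempheno.preprocess import family_history_flag
from tempheno.timebins import BIN_DAYS, N_BINS, SPAN_DAYS, bin_of_days


@dataclass
class EHRTensor:
    """Non-negative 3-mode array with axis label registries."""

    values: np.ndarray  # (patients, N_BINS, features)
    patients: list
    features: list
    domain: str  # "labvital" | "dxrx"
    bins: list = field(default_factory=lambda: list(range(N_BINS)))

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.patients), len(self.bins), len(self.features)):
            raise ValueError("tensor shape inconsistent with axis labels")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("tensor entries must be finite and non-negative")
        self.values = v


def tag_provenance(df: pd.DataFrame, tag: str) -> pd.DataFrame:
    df.attrs["provenance"] = {c: tag for c in df.columns}
    return df


def _anchored(events: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    keep = events["patient_id"].isin(set(cohort["patient_id"]))
    return events[keep & (events["days_before_anchor"] <= SPAN_DAYS)]


def latest_values(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    variables,
    recency_window: int = 183,
) -> pd.DataFrame:
    """Most recent measurement of each variable before the anchor.

    Values observed more than ``recency_window`` days before the anchor are
    treated as missing; a window of ``None`` disables the cutoff.
    """
    ev = _anchored(events, cohort)
    ev = ev[ev["domain"].isin(["lab", "vital"]) & ev["variable"].isin(set(variables))]
    if recency_window is not None:
        ev = ev[ev["days_before_anchor"] <= recency_window]
    ev = ev.sort_values("days_before_anchor", kind="stable")
    latest = ev.groupby(["patient_id", "variable"])["value"].first().unstack()
    out = latest.reindex(index=cohort["patient_id"], columns=sorted(variables))
    out = out.astype(float)
    out.index.name = "patient_id"
    return tag_provenance(out, "latest")


def demographics(events: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Age, one-hot sex and race, and the cardiovascular family-history flag."""
    out = pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    out["age"] = cohort.set_index("patient_id")["age"].reindex(out.index)
    sex = cohort.set_index("patient_id")["sex"].reindex(out.index)
    out["sex_M"] = (sex == "M").astype(float)

    ev = events[events["patient_id"].isin(set(cohort["patient_id"]))]
    race = (
        ev[(ev["domain"] == "demo") & (ev["variable"] == "race")]
        .drop_duplicates("patient_id")
        .set_index("patient_id")["value"]
        .reindex(out.index)
    )
    for level in sorted(race.dropna().unique()):
        out[f"race_{level}"] = (race == level).astype(float)

    famhx = ev[ev["domain"] == "famhx"].groupby("patient_id").apply(
        family_history_flag, include_groups=False
    )
    out["family_history_cvd"] = famhx.reindex(out.index).fillna(0).astype(float)
    return tag_provenance(out, "demo")


def summary_statistics(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    continuous_vars,
    binary_vars=(),
) -> pd.DataFrame:
    """Five-year mean/SD/min/max per continuous variable; ever-present flag
    (max) per binary variable.  The SD of a single observation is 0."""
    ev = _anchored(events, cohort)
    idx = pd.Index(cohort["patient_id"], name="patient_id")
    pieces = []

    cont = ev[ev["domain"].isin(["lab", "vital"]) & ev["variable"].isin(set(continuous_vars))]
    if len(continuous_vars):
        vals = cont.assign(value=cont["value"].astype(float))
        g = vals.groupby(["patient_id", "variable"])["value"]
        stats = g.agg(["mean", "std", "min", "max"])
        stats["std"] = stats["std"].fillna(0.0)  # single observation -> SD 0
        wide = stats.unstack()
        wide.columns = [f"{var}_{stat}" for stat, var in wide.columns]
        order = [
            f"{v}_{s}" for v in sorted(continuous_vars) for s in ("mean", "std", "min", "max")
        ]
        pieces.append(wide.reindex(index=idx, columns=order))

    if len(binary_vars):
        binev = ev[ev["domain"].isin(["dx", "rx"]) & ev["variable"].isin(set(binary_vars))]
        ever = (
            binev.groupby(["patient_id", "variable"]).size().unstack().notna().astype(float)
        )
        ever = ever.reindex(index=idx, columns=sorted(binary_vars)).fillna(0.0)
        ever.columns = [f"{v}_ever" for v in ever.columns]
        pieces.append(ever)

    out = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=idx)
    return tag_provenance(out, "stat")


def fit_quintiles(train_events: pd.DataFrame, variables) -> dict:
    """Inner quintile edges (20/40/60/80th percentiles) per variable, fit on
    training-split values only.  Duplicate edges are collapsed, so a variable
    with too few distinct values gets fewer than five levels."""
    edges = {}
    ev = train_events[train_events["domain"].isin(["lab", "vital"])]
    for var in variables:
        vals = pd.to_numeric(
            ev.loc[ev["variable"] == var, "value"], errors="coerce"
        ).dropna().to_numpy()
        if vals.size == 0:
            edges[var] = np.array([])
            continue
        q = np.quantile(vals, [0.2, 0.4, 0.6, 0.8])
        edges[var] = np.unique(q)
    return edges


def quintile_level(values, edges) -> np.ndarray:
    """Discretise to levels ``1..len(edges)+1`` (a value equal to an edge
    falls in the lower level)."""
    return np.searchsorted(edges, np.asarray(values, dtype=float), side="left") + 1


def build_labvital_tensor(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    variables,
    quintiles: dict | None = None,
) -> EHRTensor:
    """Last value of each lab/vital per six-month bin, quintile-discretised.

    Entries are levels 1..5 (train-fit quintiles) or the raw last value when
    ``quintiles`` is None; bins with no measurement are 0.
    """
    variables = sorted(variables)
    patients = list(cohort["patient_id"])
    pidx = {p: i for i, p in enumerate(patients)}
    vidx = {v: j for j, v in enumerate(variables)}
    T = np.zeros((len(patients), N_BINS, len(variables)))

    ev = _anchored(events, cohort)
    ev = ev[ev["domain"].isin(["lab", "vital"]) & ev["variable"].isin(vidx)]
    if len(ev):
        ev = ev.assign(
            _bin=bin_of_days(ev["days_before_anchor"].to_numpy()),
            value=ev["value"].astype(float),
        )
        # last recorded value per (patient, bin, variable)
        last = (
            ev.sort_values("days_before_anchor", kind="stable")
            .groupby(["patient_id", "_bin", "variable"])["value"]
            .first()
        )
        for (pid, b, var), val in last.items():
            if quintiles is not None:
                if var not in quintiles:
                    raise KeyError(f"no quintile edges fit for variable {var!r}")
                val = quintile_level(val, quintiles[var])
            T[pidx[pid], b, vidx[var]] = val
    return EHRTensor(T, patients, variables, "labvital")


def build_dxrx_tensor(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    dx_vars,
    rx_vars,
) -> EHRTensor:
    """Binary diagnosis/medication occupancy per six-month bin.

    Diagnoses: 1 in bins where the code is documented at an encounter; bins
    without any encounter inherit the previous bin's value (carry-forward),
    and anything still unobserved becomes 0.  Medications: 1 in every bin the
    prescription interval overlaps (rows may carry a ``days_before_anchor_end``
    column; point events otherwise), no carry-forward.
    """
    dx_vars, rx_vars = sorted(dx_vars), sorted(rx_vars)
    patients = list(cohort["patient_id"])
    pidx = {p: i for i, p in enumerate(patients)}
    ev = _anchored(events, cohort)

    # bins with at least one clinical event mark encounter occupancy
    enc = np.zeros((len(patients), N_BINS), dtype=bool)
    clin = ev[ev["domain"].isin(["lab", "vital", "dx", "rx"])]
    if len(clin):
        b = bin_of_days(clin["days_before_anchor"].to_numpy())
        for pid, bb in zip(clin["patient_id"], b):
            enc[pidx[pid], bb] = True

    # diagnoses: observed / 0-at-encounter / null, then carry-forward + zero
    dmap = {v: j for j, v in enumerate(dx_vars)}
    D = np.full((len(patients), N_BINS, len(dx_vars)), np.nan)
    D[enc] = 0.0
    dx = ev[(ev["domain"] == "dx") & ev["variable"].isin(dmap)]
    if len(dx):
        b = bin_of_days(dx["days_before_anchor"].to_numpy())
        for pid, bb, var in zip(dx["patient_id"], b, dx["variable"]):
            D[pidx[pid], bb, dmap[var]] = 1.0
    for b in range(1, N_BINS):  # oldest -> newest
        sl = D[:, b, :]
        D[:, b, :] = np.where(np.isnan(sl), D[:, b - 1, :], sl)
    D = np.nan_to_num(D, nan=0.0)

    # medications: interval-overlap flags, zero-fill
    rmap = {v: j for j, v in enumerate(rx_vars)}
    R = np.zeros((len(patients), N_BINS, len(rx_vars)))
    rx = ev[(ev["domain"] == "rx") & ev["variable"].isin(rmap)]
    if len(rx):
        start = rx["days_before_anchor"].to_numpy(dtype=float)
        if "days_before_anchor_end" in rx.columns:
            end = rx["days_before_anchor_end"].to_numpy(dtype=float)
            end = np.where(np.isnan(end), start, end)
        else:
            end = start
        lo, hi = np.minimum(start, end), np.maximum(start, end)
        for pid, var, a, z in zip(rx["patient_id"], rx["variable"], lo, hi):
            b_hi = bin_of_days(min(a, SPAN_DAYS))  # most recent overlapped bin
            b_lo = bin_of_days(min(z, SPAN_DAYS))
            R[pidx[pid], b_lo : b_hi + 1, rmap[var]] = 1.0

    T = np.concatenate([D, R], axis=2)
    return EHRTensor(T, patients, dx_vars + rx_vars, "dxrx")


def assemble_feature_sets(
    latest: pd.DataFrame,
    demo: pd.DataFrame,
    stats: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> dict:
    """The six evaluated feature sets (latest+demo, stats, phenotypes, and
    their combinations), provenance preserved."""
    mats = {"latest": latest, "demo": demo, "stat": stats, "phenotype": phenotypes}
    for name, m in mats.items():
        if not m.index.equals(latest.index):
            raise ValueError(f"patient axis of {name!r} does not align")

    def cat(*dfs):
        out = pd.concat(dfs, axis=1)
        if out.columns.duplicated().any():
            dupes = out.columns[out.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        prov = {}
        for d in dfs:
            prov.update(d.attrs.get("provenance", {}))
        out.attrs["provenance"] = prov
        return out

    return {
        "latest_demo": cat(latest, demo),
        "stats": cat(stats),
        "phenotypes": cat(phenotypes),
        "latest_demo_stats": cat(latest, demo, stats),
        "latest_demo_phenotypes": cat(latest, demo, phenotypes),
        "all": cat(latest, demo, stats, phenotypes),
    }
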