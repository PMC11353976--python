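"""Cleaning, encoding and filtering rules for longitudinal EHR event tables.

The pipeline order is fixed: value cleaning -> ICD9-to-ICD10 mapping ->
Z-chapter removal -> hierarchical roll-up -> train-fitted missingness and
prevalence filters.  Every data-dependent filter is fit on the training split
only and then frozen before it touches the test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)


@dataclass
class CleaningConfig:
    """Plausible-value ranges, unit rules and filter cutoffs.

    ``missingness_cutoff``: continuous variables are kept only if *more than*
    this fraction of training patients have at least one measurement.
    ``prevalence_cutoff``: binary variables are dropped if present in *less
    than* this fraction of both case and control training patients.
    """

    ranges: dict = field(default_factory=dict)  # variable -> (min, max)
    temperature_variables: tuple = ("temperature",)
    missingness_cutoff: float = 0.60
    prevalence_cutoff: float = 0.01
    recency_window: int = 183  # days

    def __post_init__(self):
        for name, cutoff in (
            ("missingness_cutoff", self.missingness_cutoff),
            ("prevalence_cutoff", self.prevalence_cutoff),
        ):
            if not 0.0 < cutoff < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for var, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {var!r} must satisfy min < max")

    @classmethod
    def from_yaml(cls, path=None) -> "CleaningConfig":
        if path is None:
            path = resources.files("tempheno.data") / "cleaning_defaults.yaml"
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            ranges={k: tuple(v) for k, v in raw.get("ranges", {}).items()},
            temperature_variables=tuple(raw.get("temperature_variables", ())),
            missingness_cutoff=raw.get("missingness_cutoff", 0.60),
            prevalence_cutoff=raw.get("prevalence_cutoff", 0.01),
            recency_window=raw.get("recency_window", 183),
        )


def celsius_to_fahrenheit(c):
    return c * 9.0 / 5.0 + 32.0


def clean_values(events: pd.DataFrame, config: CleaningConfig):
    """Drop non-parsable and out-of-range numeric values; normalise units.

    Applies to the continuous domains (lab, vital).  Temperature readings
    below 50 are taken as Celsius and converted to Fahrenheit before the
    range check.  Returns ``(events, stats)`` where ``stats`` counts dropped
    rows by reason.
    """
    events = events.copy()
    numeric = events["domain"].isin(["lab", "vital"])
    vals = pd.to_numeric(events.loc[numeric, "value"], errors="coerce")
    unparsable = numeric.copy()
    unparsable.loc[numeric] = vals.isna().to_numpy()

    events.loc[numeric, "value"] = vals.to_numpy()

    # unit normalisation: all temperatures reported in Fahrenheit
    is_temp = numeric & events["variable"].isin(config.temperature_variables)
    tvals = pd.to_numeric(events.loc[is_temp, "value"], errors="coerce")
    converted = tvals.where(tvals >= 50.0, celsius_to_fahrenheit(tvals))
    events.loc[is_temp, "value"] = converted.to_numpy()

    out_of_range = pd.Series(False, index=events.index)
    for var, (lo, hi) in config.ranges.items():
        m = numeric & (events["variable"] == var) & ~unparsable
        v = pd.to_numeric(events.loc[m, "value"])
        bad = (v < lo) | (v > hi)
        out_of_range.loc[m] = bad.to_numpy()

    stats = {
        "dropped_unparsable": int(unparsable.sum()),
        "dropped_out_of_range": int(out_of_range.sum()),
    }
    if stats["dropped_unparsable"] or stats["dropped_out_of_range"]:
        log.info("clean_values dropped rows: %s", stats)
    kept = events[~(unparsable | out_of_range)].reset_index(drop=True)
    return kept, stats


def load_icd_mapping(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("mapping file must have two columns (icd9, icd10)")
    c9, c10 = df.columns[:2]
    return dict(zip(df[c9].str.strip(), df[c10].str.strip()))


def _looks_icd9(code: str) -> bool:
    """ICD9 codes are numeric (possibly dotted, possibly E/V prefixed with
    digits); ICD10 codes start with a letter followed by two digits."""
    return code[:1].isdigit()


def map_icd9_to_icd10(events: pd.DataFrame, mapping) -> tuple:
    """Replace ICD9-shaped dx codes via the mapping; drop unmapped ones.

    ``mapping`` is a ``{icd9: icd10}`` dict or a path to a two-column TSV.
    Returns ``(events, n_unmapped_dropped)``.
    """
    if not isinstance(mapping, dict):
        mapping = load_icd_mapping(mapping)
    events = events.copy()
    dx = events["domain"] == "dx"
    codes = events.loc[dx, "variable"].astype(str)
    is9 = codes.map(_looks_icd9)
    mapped = codes.where(~is9, codes.map(mapping))
    dropped = dx.copy()
    dropped.loc[dx] = (is9 & mapped.isna()).to_numpy()
    events.loc[dx, "variable"] = mapped.to_numpy()
    n_dropped = int(dropped.sum())
    if n_dropped:
        log.info("map_icd9_to_icd10 dropped %d unmapped ICD9 rows", n_dropped)
    return events[~dropped].reset_index(drop=True), n_dropped


def drop_z_chapter(events: pd.DataFrame) -> pd.DataFrame:
    """Remove administrative "Z" chapter ICD10 diagnosis codes."""
    is_z = (events["domain"] == "dx") & events["variable"].astype(str).str.startswith("Z")
    return events[~is_z].reset_index(drop=True)


def rollup_hierarchy(dx_events: pd.DataFrame) -> pd.DataFrame:
    """Add the 3-character ICD10 category whenever a child code is present.

    E.g. an E11.0 event also emits E11 at the same patient/time.  Idempotent:
    codes that are already 3 characters gain no parent, and duplicate parent
    rows (same patient, time, code) are collapsed.
    """
    dx = dx_events[dx_events["domain"] == "dx"]
    other = dx_events[dx_events["domain"] != "dx"]
    codes = dx["variable"].astype(str)
    has_sub = codes.str.len() > 3
    parents = dx[has_sub].copy()
    parents["variable"] = codes[has_sub].str[:3]
    out = pd.concat([dx, parents], ignore_index=True)
    out = out.drop_duplicates(
        subset=["patient_id", "days_before_anchor", "variable"]
    )
    return (
        pd.concat([out, other], ignore_index=True)
        .sort_values(["patient_id", "days_before_anchor"], kind="stable")
        .reset_index(drop=True)
    )


def missingness_filter(
    train_events: pd.DataFrame,
    train_patients,
    config: CleaningConfig,
) -> list:
    """Continuous variables kept iff measured at least once for *more than*
    ``missingness_cutoff`` of training patients (strict inequality)."""
    train_patients = list(train_patients)
    if len(train_patients) == 0:
        raise ValueError("empty train split")
    cont = train_events[
        train_events["domain"].isin(["lab", "vital"])
        & train_events["patient_id"].isin(train_patients)
    ]
    frac = (
        cont.groupby("variable")["patient_id"].nunique() / len(train_patients)
    )
    kept = sorted(frac[frac > config.missingness_cutoff].index)
    return kept


def prevalence_filter(
    train_events: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CleaningConfig,
    domains=("dx", "rx"),
) -> list:
    """Binary variables dropped iff present in less than ``prevalence_cutoff``
    of case patients AND of control patients in the training split."""
    train = cohort[cohort["split"] == "train"]
    case_ids = set(train.loc[train["label"] == "case", "patient_id"])
    ctrl_ids = set(train.loc[train["label"] == "control", "patient_id"])
    if not case_ids or not ctrl_ids:
        raise ValueError("a class is absent from the train split")
    ev = train_events[train_events["domain"].isin(domains)]
    kept = []
    for var, g in ev.groupby("variable"):
        pids = set(g["patient_id"])
        p_case = len(pids & case_ids) / len(case_ids)
        p_ctrl = len(pids & ctrl_ids) / len(ctrl_ids)
        if not (p_case < config.prevalence_cutoff and p_ctrl < config.prevalence_cutoff):
            kept.append(var)
    return sorted(kept)


def family_history_flag(famhx_events: pd.DataFrame, qualifying=None) -> int:
    """1 iff any qualifying cardiovascular condition appears in the family
    history; the qualifying list defaults to the cardiovascular set."""
    from tempheno.synth import QUALIFYING_FAMHX

    qualifying = set(qualifying if qualifying is not None else QUALIFYING_FAMHX)
    if len(famhx_events) == 0:
        return 0
    vals = famhx_events["value"].astype(str).str.lower()
    return int(vals.isin(qualifying).any())


def carry_forward_zero(sequence) -> np.ndarray:
    """Carry-forward imputation followed by zero imputation.

    ``None``/NaN entries after an observed value take the last observed
    value; leading unobserved entries become 0.
    """
    out = []
    last = None
    for v in sequence:
        missing = v is None or (isinstance(v, float) and np.isnan(v))
        if missing:
            out.append(0.0 if last is None else last)
        else:
            last = float(v)
            out.append(last)
    return np.asarray(out)


def preprocess_events(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CleaningConfig | None = None,
    icd_mapping: dict | None = None,
):
    """Run the fixed cleaning pipeline and fit the train-only filters.

    Returns ``(events, kept_continuous, kept_binary, stats)``.
    """
    if config is None:
        config = CleaningConfig.from_yaml()
    events, stats = clean_values(events, config)
    if icd_mapping is not None:
        events, n_unmapped = map_icd9_to_icd10(events, icd_mapping)
        stats["dropped_unmapped_icd9"] = n_unmapped
    events = drop_z_chapter(events)
    events = rollup_hierarchy(events)
    train_ids = cohort.loc[cohort["split"] == "train", "patient_id"]
    kept_cont = missingness_filter(events, train_ids, config)
    kept_bin = prevalence_filter(events, cohort, config)
    keep = (
        events["domain"].isin(["demo", "famhx"])
        | (events["domain"].isin(["lab", "vital"]) & events["variable"].isin(kept_cont))
        | (events["domain"].isin(["dx", "rx"]) & events["variable"].isin(kept_bin))
    )
    return events[keep].reset_index(drop=True), kept_cont, kept_bin, stats
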