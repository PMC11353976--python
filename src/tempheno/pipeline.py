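"""End-to-end orchestration: synthetic cohort -> features -> phenotypes ->
classification, with train-only fitting of every data-dependent step.

This is the programmatic spine used by the command-line interface and the
acceptance checks: it generates (or accepts) a cohort, applies the cleaning
rules, builds the three feature representations, factorises the two tensors
on the training patients, projects held-out patients onto the frozen
phenotypes, and scores classifiers per feature set on the fixed test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tempheno import cp
from tempheno.evaluate import binary_metrics, make_classifier
from tempheno.features import (
    assemble_feature_sets,
    build_dxrx_tensor,
    build_labvital_tensor,
    demographics,
    fit_quintiles,
    latest_values,
    summary_statistics,
    tag_provenance,
)
from tempheno.preprocess import preprocess_events
from tempheno.selection import knn_impute, mrmr_select
from tempheno.synth import CohortSpec, generate_cohort


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    feature_sets: dict  # name -> imputed FeatureMatrix (all patients)
    labels: pd.Series  # patient_id -> 0/1
    metrics: pd.DataFrame  # per (feature_set) test metrics
    cp_models: dict = field(default_factory=dict)
    planted: list = field(default_factory=list)


def phenotype_features(
    events, cohort, kept_cont, kept_bin, rank_labvital, rank_dxrx, seed,
    max_iter: int = 150,
):
    """Factorise train-patient tensors; project all patients onto the frozen
    phenotypes.  Returns (membership DataFrame, {"labvital": model, ...})."""
    train_mask = (cohort["split"] == "train").to_numpy()
    dx_vars = sorted(v for v in kept_bin if not v.startswith("rx_"))
    rx_vars = sorted(v for v in kept_bin if v.startswith("rx_"))

    train_events = events[events["patient_id"].isin(
        set(cohort.loc[train_mask, "patient_id"])
    )]
    quintiles = fit_quintiles(train_events, kept_cont)
    t_lab = build_labvital_tensor(events, cohort, kept_cont, quintiles)
    t_dxrx = build_dxrx_tensor(events, cohort, dx_vars, rx_vars)

    cols, blocks, models = [], [], {}
    for tag, tensor, rank in (
        ("labvital", t_lab, rank_labvital),
        ("dxrx", t_dxrx, rank_dxrx),
    ):
        model = cp.nncp_hals(
            tensor.values[train_mask], rank, seed=seed, max_iter=max_iter
        )
        model.feature_labels = list(tensor.features)
        memb = cp.project_patients(model, tensor.values)
        blocks.append(memb)
        cols.extend(f"{tag}_ph{r}" for r in range(rank))
        models[tag] = model

    M = pd.DataFrame(
        np.hstack(blocks), columns=cols,
        index=pd.Index(cohort["patient_id"], name="patient_id"),
    )
    return tag_provenance(M, "phenotype"), models


def run_pipeline(
    spec: CohortSpec,
    rank_labvital: int | None = None,
    rank_dxrx: int | None = None,
    models=("rf",),
    feature_set_names=("latest_demo", "phenotypes", "latest_demo_phenotypes", "all"),
    select_k: int | None = None,
    knn_k: int = 5,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full synthetic study once and score models per feature set.

    CP ranks default to the planted rank.  ``select_k`` optionally applies
    mRMR before fitting.  Models are fit on the training split with
    imbalance handling and evaluated on the fixed test split.
    """
    if seed is not None:
        spec = CohortSpec(**{**spec.__dict__, "seed": seed})
    rank_labvital = rank_labvital or spec.planted_rank
    rank_dxrx = rank_dxrx or spec.planted_rank

    events, cohort, planted = generate_cohort(spec)
    events, kept_cont, kept_bin, _ = preprocess_events(events, cohort)

    latest = latest_values(events, cohort, kept_cont)
    demo = demographics(events, cohort)
    stats = summary_statistics(events, cohort, kept_cont, kept_bin)
    phen, cp_models = phenotype_features(
        events, cohort, kept_cont, kept_bin, rank_labvital, rank_dxrx,
        seed=spec.seed,
    )
    sets = assemble_feature_sets(latest, demo, stats, phen)
    sets = {k: v for k, v in sets.items() if k in feature_set_names}

    y = pd.Series(
        (cohort["label"] == "case").astype(int).to_numpy(),
        index=pd.Index(cohort["patient_id"], name="patient_id"),
    )
    train_mask = (cohort["split"] == "train").to_numpy()

    rows = []
    imputed = {}
    for name, X in sets.items():
        Xtr = X.iloc[train_mask]
        if X.isna().any().any():
            # guard against fully-missing train columns before kNN imputation
            ok = ~Xtr.isna().all(axis=0)
            X = X.loc[:, ok]
            Xtr = Xtr.loc[:, ok]
            X = knn_impute(Xtr, X, k_neighbors=knn_k)
            Xtr = X.iloc[train_mask]
        if select_k is not None and select_k < X.shape[1]:
            sel = mrmr_select(Xtr, y.iloc[train_mask], select_k, seed=spec.seed)
            X = X[sel.selected]
            Xtr = Xtr[sel.selected]
        imputed[name] = X
        Xte = X.iloc[~train_mask]
        for mname in models:
            clf = make_classifier(mname).fit(Xtr, y.iloc[train_mask], seed=spec.seed)
            m = binary_metrics(clf.predict_scores(Xte), y.iloc[~train_mask])
            rows.append({"feature_set": name, "model": mname, **m})

    return PipelineResult(
        cohort=cohort,
        feature_sets=imputed,
        labels=y,
        metrics=pd.DataFrame(rows),
        cp_models=cp_models,
        planted=planted,
    )


def phenotype_gain_sign_test(
    spec: CohortSpec,
    n_seeds: int = 10,
    model: str = "rf",
    phenotype_set: str = "latest_demo_phenotypes",
    baseline_set: str = "latest_demo",
    base_seed: int = 0,
):
    """Paired-seed comparison of phenotype-bearing vs latest-value features.

    Runs the pipeline once per seed, pairs test AUROC of the two feature
    sets, and applies a one-sided sign test (binomial, ties dropped).
    Returns a dict with the per-seed AUROCs and the sign-test p-value.
    """
    from scipy.stats import binomtest

    aurocs = {baseline_set: [], phenotype_set: []}
    for i in range(n_seeds):
        res = run_pipeline(
            spec,
            models=(model,),
            feature_set_names=(baseline_set, phenotype_set),
            seed=base_seed + 1000 * i + spec.seed,
        )
        m = res.metrics.set_index("feature_set")["auroc"]
        for k in aurocs:
            aurocs[k].append(float(m[k]))
    a = np.array(aurocs[phenotype_set])
    b = np.array(aurocs[baseline_set])
    wins = int((a > b).sum())
    n_eff = int((a != b).sum())
    p = binomtest(wins, n_eff, alternative="greater").pvalue if n_eff else 1.0
    return {
        "auroc_phenotypes": a,
        "auroc_baseline": b,
        "mean_gain": float(np.mean(a - b)),
        "wins": wins,
        "n": n_seeds,
        "sign_test_p": float(p),
    }
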