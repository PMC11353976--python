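"""Metrics against brute-force oracles, calibration, Friedman/Nemenyi,
Kendall concordance, imbalance handling, search and CV loops."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempheno.evaluate import (
    binary_metrics,
    class_weights,
    downsample_majority,
    friedman_nemenyi,
    kendall_concordance,
    kfold_evaluate,
    make_classifier,
    permutation_importance,
    platt_calibrate,
    random_search,
    reliability_bins,
)


def auroc_bruteforce(scores, labels):
    """All-pairs concordance with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def auprc_bruteforce(scores, labels):
    """Precision-recall step integral: sum of (dRecall * precision)."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    n_pos = y.sum()
    area, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # process tied scores together
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def kendall_tau_b_bruteforce(a, b):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(a)
    nc = nd = ta = tb = 0
    for i, j in itertools.combinations(range(n), 2):
        da, db = a[i] - a[j], b[i] - b[j]
        if da == 0 and db == 0:
            ta += 1
            tb += 1
        elif da == 0:
            ta += 1
        elif db == 0:
            tb += 1
        elif da * db > 0:
            nc += 1
        else:
            nd += 1
    n0 = n * (n - 1) / 2
    return (nc - nd) / np.sqrt((n0 - ta) * (n0 - tb))


def friedman_bruteforce(M):
    """Tie-corrected Friedman chi-square from within-block rank sums."""
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    ranks = np.array([stats.rankdata(row) for row in M])
    Rj = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3 * n * (k + 1)
    ties = 0.0
    for row in M:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1 - ties / (n * (k**3 - k))
    return chisq / correction


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        w = class_weights([0, 0, 1, 1])
        assert w[0] == w[1] == 1.0

    def test_formula(self):
        y = np.array([0] * 100 + [1] * 50)
        w = class_weights(y)
        assert w[0] == pytest.approx(0.75)
        assert w[1] == pytest.approx(1.5)

    def test_weighted_counts_equalised(self):
        y = np.array([0] * 130 + [1] * 37)
        w = class_weights(y)
        assert w[0] * 130 == pytest.approx(w[1] * 37)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestDownsample:
    def test_counts(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 300)})
        y = np.array([0] * 200 + [1] * 100)
        Xs, ys = downsample_majority(X, y, seed=4)
        assert (ys == 0).sum() == 100 and (ys == 1).sum() == 100

    def test_already_balanced_unchanged(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 20)})
        y = np.array([0, 1] * 10)
        Xs, ys = downsample_majority(X, y, seed=0)
        assert len(Xs) == 20

    def test_seed_determinism(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 300)})
        y = np.array([0] * 200 + [1] * 100)
        X1, y1 = downsample_majority(X, y, seed=9)
        X2, y2 = downsample_majority(X, y, seed=9)
        pd.testing.assert_frame_equal(X1, X2)


class TestBinaryMetrics:
    def test_worked_auroc_example(self):
        m = binary_metrics([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert m["auroc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["auroc"] == m["auprc"] == m["f1"] == 1.0

    def test_matches_bruteforce_oracles(self, rng):
        for trial in range(5):
            n = int(rng.integers(20, 100))
            scores = rng.choice(np.linspace(0, 1, 17), n)  # ties on purpose
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            m = binary_metrics(scores, labels)
            assert abs(m["auroc"] - auroc_bruteforce(scores, labels)) < 1e-9
            assert abs(m["auprc"] - auprc_bruteforce(scores, labels)) < 1e-9

    def test_random_scores_near_half(self, rng):
        n = 4000
        m = binary_metrics(rng.random(n), rng.integers(0, 2, n))
        assert abs(m["auroc"] - 0.5) < 0.05

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            binary_metrics([0.1, 0.9], [1, 1])


class TestPlatt:
    def test_recovers_calibration_on_logistic_sim(self, rng):
        n = 2000
        s = rng.uniform(0, 1, n)
        y = (rng.random(n) < s).astype(int)  # scores are true probabilities
        cal = platt_calibrate(s, y)
        p = cal.transform(s)
        slope = np.polyfit(s, p, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_matches_grid_search_oracle(self):
        s = np.array([0.1, 0.3, 0.45, 0.55, 0.7, 0.9])
        y = np.array([0, 0, 1, 0, 1, 1])
        cal = platt_calibrate(s, y)

        def logloss(A, B):
            from scipy.special import expit

            p = np.clip(expit(-(A * s + B)), 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        grid = np.linspace(-20, 20, 401)
        best = min(logloss(a, b) for a in grid for b in grid)
        assert logloss(cal.A, cal.B) <= best + 1e-3

    def test_label_flip_reverses_ordering(self):
        s = np.array([0.1, 0.4, 0.6, 0.9, 0.2, 0.8])
        y = np.array([0, 0, 1, 1, 0, 1])
        p_fwd = platt_calibrate(s, y).transform(s)
        p_rev = platt_calibrate(s, 1 - y).transform(s)
        assert np.all(np.argsort(p_fwd) == np.argsort(-p_rev))

    def test_degenerate_scores_warn(self):
        with pytest.warns(UserWarning):
            cal = platt_calibrate(np.full(10, 0.5), np.array([0, 1] * 5))
        assert np.allclose(cal.transform(np.full(3, 0.5)), 0.5)


class TestReliability:
    def test_single_occupied_bin(self):
        out = reliability_bins([0.52, 0.55, 0.58], [1, 0, 1])
        assert len(out) == 1 and out["count"].iloc[0] == 3

    def test_calibrated_draws_small_gap(self, rng):
        n = 5000
        p = rng.uniform(0, 1, n)
        y = (rng.random(n) < p).astype(int)
        out = reliability_bins(p, y, n_bins=10)
        assert len(out) == 10
        assert (out["mean_prob"] - out["frac_positive"]).abs().max() < 0.05

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reliability_bins([1.2], [1])


class TestFriedmanNemenyi:
    def test_identical_columns_degenerate(self):
        M = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        res = friedman_nemenyi(M)
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.nemenyi is None and res.tied_blocks == 3

    def test_matches_rank_arithmetic_oracle(self, rng):
        M = rng.normal(0, 1, (4, 3))
        res = friedman_nemenyi(M, alpha=0.01)
        assert res.statistic == pytest.approx(friedman_bruteforce(M), abs=1e-9)

    def test_column_permutation_invariance(self, rng):
        M = rng.normal(0, 1, (6, 4))
        p1 = friedman_nemenyi(M).pvalue
        p2 = friedman_nemenyi(M[:, [2, 0, 3, 1]]).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_posthoc_on_clear_separation(self, rng):
        base = rng.normal(0, 0.01, (12, 1))
        M = np.hstack([base, base + 1.0, base + 2.0])
        res = friedman_nemenyi(M, alpha=0.01)
        assert res.significant and res.nemenyi is not None
        assert res.nemenyi.iloc[0, 2] < 0.05

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman_nemenyi(np.ones((1, 3)))


class TestKendall:
    def test_identical_rankings(self):
        M = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4]])
        out = kendall_concordance(M)
        assert out.iloc[0, 1] == pytest.approx(1.0)

    def test_reversed_rankings(self):
        M = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]])
        out = kendall_concordance(M)
        assert out.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_pair_count_oracle(self, rng):
        a = rng.integers(0, 8, 10)  # ties likely
        b = rng.integers(0, 8, 10)
        out = kendall_concordance(pd.DataFrame([a, b]))
        assert out.iloc[0, 1] == pytest.approx(
            kendall_tau_b_bruteforce(a, b), abs=1e-9
        )

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            kendall_concordance(pd.DataFrame([[1], [2]]))


def _separable(rng, n=300, p=4):
    X = pd.DataFrame(
        rng.normal(0, 1, (n, p)), columns=[f"f{j}" for j in range(p)]
    )
    y = (X["f0"] > 0).astype(int).to_numpy()
    return X, y


class TestPermutationImportance:
    def test_informative_feature_dominates(self, rng):
        X, y = _separable(rng)
        clf = make_classifier("rf").fit(X, y, seed=0)
        imp = permutation_importance(clf, X, y, n_repeats=5, seed=0)
        assert imp.idxmax() == "f0"
        assert imp.drop("f0").abs().max() < imp["f0"]

    def test_seed_stability(self, rng):
        X, y = _separable(rng)
        clf = make_classifier("rf").fit(X, y, seed=0)
        i1 = permutation_importance(clf, X, y, n_repeats=20, seed=1)
        i2 = permutation_importance(clf, X, y, n_repeats=20, seed=2)
        assert (i1 - i2).abs().max() < 0.05


class TestSearchAndCV:
    def test_single_draw_returned(self, rng):
        X, y = _separable(rng, n=120)
        out = random_search("dt", {"max_depth": [2]}, n_draws=1, X=X, y=y, seed=0)
        assert out["best"] == {"max_depth": 2}

    def test_dominant_setting_found_by_exhaustive_oracle(self, rng):
        # XOR labels: a depth-1 tree cannot express the interaction, so the
        # grid points genuinely differ in CV score
        X = pd.DataFrame(
            rng.normal(0, 1, (240, 3)), columns=["f0", "f1", "f2"]
        )
        y = ((X["f0"] > 0) ^ (X["f1"] > 0)).astype(int).to_numpy()
        grid = {"max_depth": [1, 8], "min_samples_leaf": [1, 60]}
        out = random_search("dt", grid, n_draws=12, X=X, y=y, seed=3)
        # oracle: evaluate all four grid points exhaustively
        scores = {}
        for md in grid["max_depth"]:
            for msl in grid["min_samples_leaf"]:
                r = random_search(
                    "dt", {"max_depth": [md], "min_samples_leaf": [msl]},
                    n_draws=1, X=X, y=y, seed=3,
                )
                scores[(md, msl)] = r["best_f1"]
        best_combo = max(scores, key=scores.get)
        assert (out["best"]["max_depth"], out["best"]["min_samples_leaf"]) == best_combo

    def test_empty_grid_rejected(self, rng):
        X, y = _separable(rng, n=60)
        with pytest.raises(ValueError):
            random_search("dt", {}, n_draws=1, X=X, y=y)

    def test_five_folds_and_separable_auroc(self, rng):
        X, y = _separable(rng, n=250)
        cv = kfold_evaluate("lr", {}, X, y, X, y, folds=5, seed=0)
        assert cv[cv["eval"] == "validation"]["fold"].nunique() == 5
        assert (cv[cv["eval"] == "test"]["auroc"] > 0.95).all()

    def test_metrics_within_unit_interval(self, rng):
        X, y = _separable(rng, n=150)
        cv = kfold_evaluate("rf", {"n_estimators": 50}, X, y, folds=5, seed=1)
        vals = cv[["auroc", "auprc", "f1", "precision", "recall"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
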