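"""Fuzzy-rule network: encoding, T-norm/T-conorm algebra, training, rules."""

import numpy as np
import pytest

from tempheno.tgfnn import (
    MembershipParams,
    RuleBank,
    TGFNNConfig,
    _loss_and_grads,
    _softplus_inv,
    extract_rules,
    fit_tgfnn,
    fuzzify,
    infer,
    planted_rule_data,
    rule_activation,
)


def make_bank(attention, importance, rule_importance, tnorm=1.0, tconorm=1.0):
    return RuleBank(
        concept_attention=np.asarray(attention, dtype=float),
        variable_importance=np.asarray(importance, dtype=float),
        rule_importance=np.asarray(rule_importance, dtype=float),
        tnorm_tau=tnorm,
        tconorm_tau=tconorm,
    )


class TestFuzzify:
    def test_peak_membership_at_center(self):
        p = MembershipParams(
            centers=np.array([[0.1, 0.5, 0.9]]),
            widths=np.full((1, 3), 0.2),
            is_binary=np.array([False]),
        )
        m = fuzzify(np.array([[0.1]]), p)
        assert m[0, 0, 0] == pytest.approx(1.0)

    def test_gaussian_closed_form(self):
        p = MembershipParams(
            centers=np.zeros((1, 3)),
            widths=np.ones((1, 3)),
            is_binary=np.array([False]),
        )
        m = fuzzify(np.array([[1.0]]), p)
        assert m[0, 0, 0] == pytest.approx(np.exp(-0.5))

    def test_binary_passthrough(self):
        p = MembershipParams(
            centers=np.zeros((1, 3)),
            widths=np.ones((1, 3)),
            is_binary=np.array([True]),
        )
        m = fuzzify(np.array([[1.0]]), p)
        assert m[0, 0].tolist() == [0.0, 1.0, 0.0]

    def test_nonfinite_rejected(self):
        p = MembershipParams(
            centers=np.zeros((1, 3)), widths=np.ones((1, 3)),
            is_binary=np.array([False]),
        )
        with pytest.raises(ValueError):
            fuzzify(np.array([[np.nan]]), p)


def two_score_memberships(s1, s2):
    """Memberships and attention so rule 0 sees variable scores (s1, s2)."""
    m = np.array([[[s1, 0, 0], [s2, 0, 0]]])
    att = np.zeros((1, 2, 3))
    att[:, :, 0] = 1.0
    return m, att


class TestRuleActivation:
    def test_and_identity(self):
        m, att = two_score_memberships(1.0, 1.0)
        for tau in (0.0, 0.37, 1.0):
            bank = make_bank(att, np.ones((1, 2)), np.ones((1, 2)), tnorm=tau)
            assert rule_activation(m, bank)[0, 0] == pytest.approx(1.0, abs=1e-7)

    def test_pure_min_endpoint(self):
        m, att = two_score_memberships(0.2, 0.9)
        bank = make_bank(att, np.ones((1, 2)), np.ones((1, 2)), tnorm=0.0)
        assert rule_activation(m, bank)[0, 0] == pytest.approx(0.2, abs=1e-7)

    def test_pure_product_endpoint(self):
        m, att = two_score_memberships(0.2, 0.9)
        bank = make_bank(att, np.ones((1, 2)), np.ones((1, 2)), tnorm=1.0)
        assert rule_activation(m, bank)[0, 0] == pytest.approx(0.18, abs=1e-6)

    def test_endpoints_exact_to_1e9(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.05, 1.0, 4)
        m = np.zeros((1, 4, 3))
        m[0, :, 0] = scores
        att = np.zeros((1, 4, 3))
        att[:, :, 0] = 1.0
        w = np.ones((1, 4))
        prod = rule_activation(m, make_bank(att, w, np.ones((1, 2)), tnorm=1.0))
        assert abs(prod[0, 0] - scores.prod()) < 1e-9
        mn = rule_activation(m, make_bank(att, w, np.ones((1, 2)), tnorm=0.0))
        assert abs(mn[0, 0] - scores.min()) < 1e-9

    def test_zero_importance_is_neutral(self):
        m, att = two_score_memberships(0.2, 0.9)
        w = np.array([[0.0, 1.0]])  # first variable switched off
        bank = make_bank(att, w, np.ones((1, 2)), tnorm=1.0)
        assert rule_activation(m, bank)[0, 0] == pytest.approx(0.9, abs=1e-6)


class TestInfer:
    def test_zero_strengths_uniform(self):
        bank = make_bank(np.ones((2, 1, 3)) / 3, np.ones((2, 1)), np.ones((2, 2)))
        p = infer(np.zeros((1, 2)), bank)
        assert np.allclose(p, 0.5)

    def test_max_mode_logit(self):
        rho = np.array([[0.0, 1.0], [0.0, 1.0]])
        bank = make_bank(np.ones((2, 1, 3)) / 3, np.ones((2, 1)), rho, tconorm=0.0)
        F = np.array([[0.5, 0.9]])
        h = F[0] * rho[:, 1]
        assert max(h) == pytest.approx(0.9)
        p = infer(F, bank)
        expect = np.exp(0.9) / (np.exp(0.0) + np.exp(0.9))
        assert p[0, 1] == pytest.approx(expect, abs=1e-9)

    def test_sum_mode_logit(self):
        rho = np.array([[0.0, 1.0], [0.0, 1.0]])
        bank = make_bank(np.ones((2, 1, 3)) / 3, np.ones((2, 1)), rho, tconorm=1.0)
        F = np.array([[0.5, 0.9]])
        p = infer(F, bank)
        expect = np.exp(1.4) / (np.exp(0.0) + np.exp(1.4))
        assert p[0, 1] == pytest.approx(expect, abs=1e-9)

    def test_probabilities_normalised(self, rng):
        bank = make_bank(
            np.ones((3, 1, 3)) / 3, rng.uniform(0, 2, (3, 1)),
            rng.uniform(0, 2, (3, 2)), tnorm=0.4, tconorm=0.7,
        )
        p = infer(rng.uniform(0, 1, (20, 3)), bank)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        N, V, R, C = 6, 4, 3, 2
        X = rng.uniform(0, 1, (N, V))
        X[:, 3] = (X[:, 3] > 0.5).astype(float)
        y = rng.integers(0, 2, N)
        is_binary = np.array([False, False, False, True])
        mask = np.ones((V, 3), bool)
        mask[is_binary, 2] = False
        params = {
            "mu": rng.uniform(0, 1, (V, 3)),
            "logsig": rng.normal(-1, 0.2, (V, 3)),
            "Araw": rng.normal(0, 0.5, (R, V, 3)),
            "Wraw": rng.normal(0, 0.5, (R, V)),
            "Rraw": rng.normal(0, 0.5, (R, C)),
            "ta_raw": np.array(0.3),
            "to_raw": np.array(-0.2),
        }
        cw = np.array([1.0, 1.7])
        _, grads = _loss_and_grads(params, mask, is_binary, X, y, cw, 1e-3, 1e-2)
        eps = 1e-6
        for key, val in params.items():
            flat = np.atleast_1d(val).ravel()
            for idx in range(flat.size):
                for sgn, store in ((+1, "hi"), (-1, "lo")):
                    p2 = {k: v.copy() for k, v in params.items()}
                    f2 = np.atleast_1d(p2[key]).ravel()
                    f2[idx] += sgn * eps
                    p2[key] = f2.reshape(val.shape) if val.shape else np.array(f2[0])
                    l, _ = _loss_and_grads(p2, mask, is_binary, X, y, cw, 1e-3, 1e-2)
                    if store == "hi":
                        hi = l
                    else:
                        lo = l
                num = (hi - lo) / (2 * eps)
                ana = np.atleast_1d(grads[key]).ravel()[idx]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), key


class TestTraining:
    def test_zero_epochs_returns_initialisation(self, rng):
        X = rng.uniform(0, 1, (40, 3))
        y = rng.integers(0, 2, 40)
        m1 = fit_tgfnn(X, y, config=TGFNNConfig(epochs=0, seed=5))
        m2 = fit_tgfnn(X, y, config=TGFNNConfig(epochs=0, seed=5))
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])
        assert len(m1.history) == 0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_tgfnn(rng.uniform(0, 1, (20, 2)), np.zeros(20, dtype=int))

    def test_learns_planted_signal(self):
        X, y, _ = planted_rule_data(600, seed=1)
        m = fit_tgfnn(
            X, y, config=TGFNNConfig(n_rules=6, epochs=400, patience=150, seed=0)
        )
        Xte, yte, _ = planted_rule_data(400, seed=2)
        assert (m.predict(Xte) == yte).mean() > 0.85

    def test_label_permutation_control(self):
        """With shuffled labels, validation AUROC hovers around chance."""
        from sklearn.metrics import roc_auc_score

        X, y, _ = planted_rule_data(300, seed=3)
        aurocs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            m = fit_tgfnn(
                X, yp, config=TGFNNConfig(n_rules=4, epochs=60, patience=60, seed=seed)
            )
            col = int(np.where(m.classes_ == 1)[0][0])
            aurocs.append(roc_auc_score(yp, m.predict_proba(X)[:, col]))
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_monotone_in_pure_product_sum_mode(self, rng):
        """Raising a membership feeding a positive-class rule never lowers
        the positive-class probability at the product/sum endpoints."""
        att = np.zeros((1, 2, 3))
        att[0, 0, 2] = 1.0  # rule reads 'high' of variable 0
        att[0, 1, 0] = 1.0
        bank = make_bank(
            att, np.ones((1, 2)), np.array([[0.0, 2.0]]), tnorm=1.0, tconorm=1.0
        )
        m = rng.uniform(0.1, 0.9, (1, 2, 3))
        for bump in (0.02, 0.1, 0.3):
            m2 = m.copy()
            m2[0, 0, 2] = min(m[0, 0, 2] + bump, 1.0)
            p1 = infer(rule_activation(m, bank), bank)[0, 1]
            p2 = infer(rule_activation(m2, bank), bank)[0, 1]
            assert p2 >= p1 - 1e-12


class TestExtractRules:
    def _hand_model(self):
        cfg = TGFNNConfig(n_rules=2, epochs=0, seed=0)
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (30, 2))
        y = rng.integers(0, 2, 30)
        m = fit_tgfnn(X, y, config=cfg)
        # overwrite with a hand-built bank: rule 0 = "x0 high AND x1 low"
        Araw = np.full((2, 2, 3), -10.0)
        Araw[0, 0, 2] = 10.0
        Araw[0, 1, 0] = 10.0
        Araw[1, 0, 0] = 10.0
        Araw[1, 1, 1] = 10.0
        m.params["Araw"] = Araw
        m.params["Wraw"] = _softplus_inv(np.array([[1.0, 0.8], [1.0, 0.04]]))
        m.params["Rraw"] = _softplus_inv(np.array([[0.1, 3.0], [0.1, 1.0]]))
        return m

    def test_rendered_text(self):
        rules = extract_rules(self._hand_model(), threshold=0.1)
        assert rules[0]["text"] == "x0 is high AND x1 is low"
        assert rules[1]["text"] == "x0 is low"  # x1 pruned below threshold

    def test_rule_ordering_and_relative_contribution(self):
        rules = extract_rules(self._hand_model(), threshold=0.1)
        assert rules[0]["relative_importance"] == pytest.approx(0.75)
        assert rules[1]["relative_importance"] == pytest.approx(0.25)

    def test_equal_importances_split_evenly(self):
        m = self._hand_model()
        m.params["Rraw"] = _softplus_inv(np.full((2, 2), 0.5))
        rules = extract_rules(m, threshold=0.1)
        assert all(r["relative_importance"] == pytest.approx(0.5) for r in rules)
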