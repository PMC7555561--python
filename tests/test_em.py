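"""Penalized EM: E-step, M-steps, multi-start driver."""

import numpy as np
import pytest
from scipy.optimize import minimize

import rlca
from rlca.em import e_step, fit, m_step_class_probs, m_step_item
from rlca.lcm import (
    ModelParams,
    ResponseMatrix,
    class_probs,
    log_likelihood,
    simulate,
)
from rlca.penalties import PenaltySpec


class TestEStep:
    def test_single_class_posterior_is_one(self, rng):
        params = ModelParams.from_probs([np.array([[0.4], [0.6]])], np.array([1.0]))
        data = ResponseMatrix.from_array(rng.integers(0, 2, size=(10, 1)),
                                         n_categories=[2])
        np.testing.assert_allclose(e_step(data, params), 1.0)

    def test_identical_items_give_prior(self, rng):
        t = np.array([[0.3, 0.3], [0.7, 0.7]])
        params = ModelParams.from_probs([t, t], np.array([0.8, 0.2]))
        data = ResponseMatrix.from_array(rng.integers(0, 2, size=(10, 2)),
                                         n_categories=[2, 2])
        np.testing.assert_allclose(
            e_step(data, params), np.tile([0.8, 0.2], (10, 1)), atol=1e-9
        )

    def test_matches_brute_force_bayes(self):
        # 2 items, 2 classes: posterior from first principles
        t1 = np.array([[0.2, 0.7], [0.8, 0.3]])
        t2 = np.array([[0.5, 0.1], [0.5, 0.9]])
        pc = np.array([0.4, 0.6])
        params = ModelParams.from_probs([t1, t2], pc)
        data = ResponseMatrix(np.array([[0, 1], [1, 0], [1, 1], [0, 0]]), [2, 2])
        post = e_step(data, params)
        for n in range(4):
            x = data.data[n]
            joint = np.array([pc[c] * t1[x[0], c] * t2[x[1], c] for c in range(2)])
            np.testing.assert_allclose(post[n], joint / joint.sum(), atol=1e-12)

    def test_rows_sum_to_one(self, dicho_data, dicho_design):
        data, _ = dicho_data
        post = e_step(data, dicho_design.to_params())
        np.testing.assert_allclose(post.sum(axis=1), 1.0)


class TestMStepClassProbs:
    def test_counting(self):
        post = np.array([[1, 0], [1, 0], [1, 0], [0, 1]], dtype=float)
        np.testing.assert_allclose(class_probs(m_step_class_probs(post)),
                                   [0.75, 0.25])

    def test_uniform(self):
        post = np.full((6, 3), 1 / 3)
        np.testing.assert_allclose(class_probs(m_step_class_probs(post)), 1 / 3)

    def test_matches_numeric_maximizer(self, rng):
        post = rng.dirichlet(np.ones(3), size=20)
        p_hat = class_probs(m_step_class_probs(post))

        def neg_q(d_free):
            p = class_probs(np.concatenate([[0.0], d_free]))
            return -(post * np.log(p)[None, :]).sum()

        res = minimize(neg_q, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(p_hat, class_probs(np.concatenate([[0.0], res.x])),
                                   atol=1e-5)

    def test_empty_class_floored_with_warning(self):
        post = np.column_stack([np.ones(5), np.zeros(5)])
        with pytest.warns(RuntimeWarning):
            delta = m_step_class_probs(post)
        assert np.all(class_probs(delta) > 0)


class TestMStepItem:
    def test_unpenalized_matches_weighted_frequencies(self, rng):
        item = rng.integers(0, 3, size=40)
        post = rng.dirichlet(np.ones(2), size=40)
        spec = PenaltySpec("mcp", "fused_classes", lambda1=0.0)
        g = m_step_item(item, post, spec, np.zeros((2, 2)))
        p_hat = rlca.logits_to_probs(g)
        for c in range(2):
            for k in range(3):
                expected = post[item == k, c].sum() / post[:, c].sum()
                assert p_hat[k, c] == pytest.approx(expected, abs=1e-9)

    def test_huge_lambda_pools_classes(self, rng):
        item = rng.integers(0, 2, size=200)
        post = rng.dirichlet(np.ones(3), size=200)
        spec = PenaltySpec("mcp", "fused_classes", lambda1=50.0, smooth_eps=1e-6)
        g = m_step_item(item, post, spec, np.zeros((1, 3)))
        p_hat = rlca.logits_to_probs(g)
        pooled = (item == 1).mean()
        np.testing.assert_allclose(p_hat[1], pooled, atol=0.01)
        assert np.ptp(g) < 1e-3  # classes fused

    def test_ascent_contract(self, rng):
        from rlca.em import _item_counts, _item_objective

        item = rng.integers(0, 3, size=60)
        post = rng.dirichlet(np.ones(3), size=60)
        spec = PenaltySpec("scad", "fused_both", lambda1=0.2, lambda2=0.2)
        n_kc = _item_counts(item, post, None, 3)
        for _ in range(20):
            init = rng.normal(scale=2, size=(2, 3))
            g = m_step_item(item, post, spec, init)
            f_init, _ = _item_objective(init.ravel(), n_kc, 60.0, spec, 2, 3,
                                        spec.smooth_eps)
            f_final, _ = _item_objective(g.ravel(), n_kc, 60.0, spec, 2, 3,
                                         spec.smooth_eps)
            assert f_final <= f_init + 1e-9


def _plain_em_oracle(data, C, init_params, n_iter=400):
    """Independent textbook EM on the probability scale (no penalty)."""
    pc = init_params.class_probs().copy()
    tables = [t.copy() for t in init_params.all_item_probs()]
    N, I = data.data.shape
    for _ in range(n_iter):
        lik = np.tile(pc, (N, 1))
        for i in range(I):
            lik *= tables[i][data.data[:, i], :]
        post = lik / lik.sum(axis=1, keepdims=True)
        pc = post.mean(axis=0)
        for i in range(I):
            ncat = tables[i].shape[0]
            t = np.zeros((ncat, C))
            for k in range(ncat):
                t[k] = post[data.data[:, i] == k].sum(axis=0)
            tables[i] = t / t.sum(axis=0, keepdims=True)
    return pc, tables


class TestFit:
    def test_single_class_closed_form(self, rng):
        data = ResponseMatrix.from_array(rng.integers(0, 3, size=(80, 2)),
                                         n_categories=[3, 3])
        res = fit(data, 1, spec=None, n_starts=1, seed=0)
        for i in range(2):
            marginal = np.bincount(data.data[:, i], minlength=3) / 80
            np.testing.assert_allclose(res.params.item_probs(i)[:, 0], marginal,
                                       atol=1e-8)
        assert res.loglik == pytest.approx(log_likelihood(data, res.params))
        assert res.n_params == 2 * 2 + 0

    def test_unpenalized_matches_independent_em(self, dicho_design):
        data, _ = simulate(dicho_design, 300, seed=9)
        res = fit(data, 2, spec=None, n_starts=5, seed=4)
        pc, tables = _plain_em_oracle(data, 2, res.params)
        np.testing.assert_allclose(res.params.class_probs(), pc, atol=1e-4)
        for i in range(12):
            np.testing.assert_allclose(res.params.item_probs(i), tables[i],
                                       atol=1e-3)

    def test_class_probability_recovery(self, dicho_base_fit, dicho_design):
        matched = rlca.match_labels(dicho_base_fit.params, dicho_design)
        np.testing.assert_allclose(
            matched.class_probs(), [0.30, 0.20, 0.10, 0.40], atol=0.05
        )

    def test_item_probability_recovery(self, dicho_base_fit, dicho_design):
        # the 10%-probability class is estimated from ~100 soft-assigned
        # persons, so its item probabilities carry visibly more error than
        # the large classes; bound the bulk tightly and the worst case loosely
        matched = rlca.match_labels(dicho_base_fit.params, dicho_design)
        devs = np.concatenate(
            [
                np.abs(matched.item_probs(i)[1] - dicho_design.item_probs[i][1])
                for i in range(12)
            ]
        )
        assert devs.mean() < 0.04
        assert devs.max() < 0.20

    def test_posterior_rows_sum_to_one(self, dicho_base_fit):
        np.testing.assert_allclose(dicho_base_fit.posterior.sum(axis=1), 1.0)
        assert dicho_base_fit.posterior.shape == (1000, 4)

    def test_objective_monotone_within_smoothing_phase(self, dicho_data):
        data, _ = dicho_data
        spec = PenaltySpec("mcp", "fused_classes", lambda1=0.2)
        res = fit(data, 4, spec=spec, n_starts=2, seed=3)
        hist = res.objective_history
        for (eps_a, obj_a), (eps_b, obj_b) in zip(hist, hist[1:]):
            if eps_a == eps_b:
                assert obj_b >= obj_a - 1e-6

    def test_penalized_objective_bounded_by_loglik(self, dicho_data):
        data, _ = dicho_data
        spec = PenaltySpec("mcp", "fused_classes", lambda1=0.2)
        res = fit(data, 4, spec=spec, n_starts=1, seed=3)
        assert res.penalized_objective <= res.loglik
        assert res.n_params + res.n_regularized == 12 * 4 + 4 - 1

    def test_deterministic_given_seed(self, dicho_design):
        data, _ = simulate(dicho_design, 200, seed=8)
        a = fit(data, 3, spec=None, n_starts=3, seed=5)
        b = fit(data, 3, spec=None, n_starts=3, seed=5)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params.delta, b.params.delta)

    def test_too_many_classes_warns(self):
        data = ResponseMatrix(np.array([[0, 1], [0, 1], [1, 0]]), [2, 2])
        with pytest.warns(RuntimeWarning):
            fit(data, 4, spec=None, n_starts=1, seed=0, max_iter=30)

    def test_serialization_round_trip(self, tmp_path, dicho_base_fit):
        path = tmp_path / "fit.json"
        dicho_base_fit.to_json(path)
        import json

        loaded = json.load(open(path))
        assert loaded["n_params"] == dicho_base_fit.n_params
        assert loaded["loglik"] == pytest.approx(dicho_base_fit.loglik)
        g0 = np.array(loaded["gamma"][0])
        np.testing.assert_allclose(g0, dicho_base_fit.params.gamma[0])
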