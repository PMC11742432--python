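"""Attention-MIL network: forward ops, MIL loss, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pumil import model as M
from pumil.train import TrainConfig, _bag_losses_and_grads
from pumil.simulate import MilGenConfig, gen_mil_bags


def _params(dim_in=6, dim_embed=5, dim_att=3, seed=0):
    return M.init_params(dim_in, dim_embed, dim_att, seed=seed)


class TestEmbed:
    def test_identity_configuration_passes_input_through(self):
        # M = D, identity weights, zero bias: ReLU(ReLU(x)) = x for x >= 0
        p = _params(dim_in=4, dim_embed=4)
        p.W1 = np.eye(4); p.b1 = np.zeros(4)
        p.W2 = np.eye(4); p.b2 = np.zeros(4)
        x = np.array([0.5, 1.0, 0.0, 2.0])
        np.testing.assert_allclose(M.embed(x, p)[0], x)

    def test_zero_input_zero_bias_gives_zero(self):
        p = _params()
        p.b1[:] = 0.0; p.b2[:] = 0.0
        np.testing.assert_allclose(M.embed(np.zeros(6), p)[0], 0.0)

    def test_matches_layerwise_recomputation(self):
        rng = np.random.default_rng(3)
        p = _params(seed=3)
        X = rng.normal(size=(4, 6))
        # independent per-layer oracle
        h1 = np.maximum(X @ p.W1 + p.b1, 0)
        expect = np.maximum(h1 @ p.W2 + p.b2, 0)
        np.testing.assert_allclose(M.embed(X, p), expect, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="expected 6"):
            M.embed(np.zeros(5), _params())


class TestAttention:
    def test_zero_V_gives_zero_scores(self):
        p = _params()
        p.V = np.zeros_like(p.V)
        H = np.random.default_rng(0).normal(size=(3, 5))
        np.testing.assert_allclose(M.attention_scores(H, p), 0.0)

    def test_identical_rows_get_identical_scores(self):
        p = _params(seed=1)
        h = np.random.default_rng(1).normal(size=5)
        H = np.stack([h, h])
        s = M.attention_scores(H, p)
        assert s[0] == pytest.approx(s[1], abs=1e-12)

    def test_matches_per_instance_loop_oracle(self):
        p = _params(seed=2)
        H = np.random.default_rng(2).normal(size=(3, 5))
        expect = [float(p.w_att @ np.tanh(p.V @ h)) for h in H]
        np.testing.assert_allclose(M.attention_scores(H, p), expect, atol=1e-12)

    @pytest.mark.parametrize("atts,expected", [
        ([0.7], [1.0]),
        ([1.3] * 4, [0.25] * 4),
        ([0.0, np.log(3)], [0.25, 0.75]),
    ])
    def test_softmax_weights(self, atts, expected):
        np.testing.assert_allclose(M.attention_weights(np.array(atts)),
                                   expected, atol=1e-12)

    def test_softmax_shift_invariance(self):
        atts = np.array([0.1, -2.0, 3.0])
        np.testing.assert_allclose(M.attention_weights(atts),
                                   M.attention_weights(atts + 100.0), atol=1e-12)


class TestPool:
    def test_one_hot_selects_row(self):
        H = np.arange(12, dtype=float).reshape(4, 3)
        np.testing.assert_allclose(M.pool(H, np.array([0, 0, 1, 0])), H[2])

    def test_identical_rows_invariant_to_weights(self):
        h = np.array([1.0, -2.0, 0.5])
        H = np.tile(h, (3, 1))
        np.testing.assert_allclose(M.pool(H, np.array([0.2, 0.5, 0.3])), h)

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(4)
        H = rng.normal(size=(4, 3))
        a = rng.dirichlet(np.ones(4))
        expect = sum(a[j] * H[j] for j in range(4))
        np.testing.assert_allclose(M.pool(H, a), expect, atol=1e-12)


class TestBagScore:
    def test_zero_weight_gives_half(self):
        p = _params()
        p.classifier_w = np.zeros_like(p.classifier_w)
        assert M.bag_score(np.ones(5), p) == pytest.approx(0.5)

    def test_logit_log9_gives_09(self):
        p = _params(dim_embed=1, dim_att=2, dim_in=2)
        p.classifier_w = np.array([1.0])
        assert M.bag_score(np.array([np.log(9)]), p) == pytest.approx(0.9, abs=1e-9)

    def test_monotone_in_logit(self):
        p = _params()
        z = np.ones(5)
        lo = M.bag_score(z * 0.1, p)
        hi = M.bag_score(z * 0.1 + p.classifier_w, p)  # moves along +w
        assert hi > lo


class TestLossMil:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.5], [1], 0.693147),
        ([0.8, 0.2], [1, 0], 0.446287),
    ])
    def test_frozen_values(self, scores, labels, expected):
        assert M.loss_mil(scores, labels) == pytest.approx(expected, abs=1e-6)

    def test_boundary_is_near_zero(self):
        assert M.loss_mil([1.0 - 1e-7], [1]) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError, match="0/1"):
            M.loss_mil([0.5], [2])


class TestForwardInvariants:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10))
    def test_permutation_invariance_and_weight_normalization(self, k, seed):
        rng = np.random.default_rng(seed)
        p = _params(seed=seed)
        X = rng.normal(size=(k, 6))
        fw = M.bag_forward(X, p)
        assert fw.a.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(fw.a >= 0)
        assert 0.0 < fw.P < 1.0
        perm = rng.permutation(k)
        fw2 = M.bag_forward(X[perm], p)
        np.testing.assert_allclose(fw2.z, fw.z, atol=1e-6)
        assert fw2.P == pytest.approx(fw.P, abs=1e-6)

    def test_mean_pool_ablation_runs_with_uniform_weights(self):
        p = _params()
        X = np.random.default_rng(1).normal(size=(5, 6))
        fw = M.bag_forward(X, p, mean_pool=True)
        np.testing.assert_allclose(fw.a, 0.2)
        np.testing.assert_allclose(fw.z, fw.H.mean(axis=0), atol=1e-12)


class TestGradients:
    def test_finite_difference_agreement_on_two_bag_toy(self):
        """Analytic gradients of L = L_m + L_p match central differences."""
        bags = gen_mil_bags(MilGenConfig(n_bags=4, bag_size_range=(3, 5),
                                         instance_dim=5, seed=1))
        params = M.init_params(5, dim_embed=4, dim_att=3, seed=3)
        cfg = TrainConfig(lam=1e-3)

        def total(p):
            g = M.zero_grads(p)
            lm1, lp1 = _bag_losses_and_grads(bags[0], 1, p, g, cfg)
            lm2, lp2 = _bag_losses_and_grads(bags[1], 0, p, g, cfg)
            reg = cfg.lam * (p.alpha ** 2 + p.beta ** 2)
            return lm1 + lm2 + lp1 + lp2 + reg, g

        _, grads = total(params)
        grads["alpha"] += 2 * cfg.lam * params.alpha
        grads["beta"] += 2 * cfg.lam * params.beta
        eps = 1e-6
        for key in params.PARAM_KEYS:
            val = np.atleast_1d(np.asarray(getattr(params, key), dtype=float))
            shape = np.shape(getattr(params, key))
            for idx in range(val.size):
                plus, minus = val.copy().ravel(), val.copy().ravel()
                plus[idx] += eps
                minus[idx] -= eps
                p2, p3 = params.copy(), params.copy()
                if shape == ():
                    setattr(p2, key, float(plus[0]))
                    setattr(p3, key, float(minus[0]))
                else:
                    setattr(p2, key, plus.reshape(shape))
                    setattr(p3, key, minus.reshape(shape))
                fd = (total(p2)[0] - total(p3)[0]) / (2 * eps)
                an = grads[key].ravel()[idx]
                if abs(fd) > 1e-8 or abs(an) > 1e-8:
                    assert abs(fd - an) / max(abs(fd), abs(an)) < 1e-4, (
                        f"{key}[{idx}]: analytic {an} vs numeric {fd}")


class TestCheckpointFormat:
    def test_round_trip(self):
        p = _params(seed=8)
        p.alpha, p.beta = 1.5, -0.25
        d = M.params_to_dict(p)
        assert d["format"] == "pumil-v1"
        q = M.params_from_dict(d)
        for key in p.PARAM_KEYS:
            np.testing.assert_allclose(np.asarray(getattr(p, key)),
                                       np.asarray(getattr(q, key)))

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            M.params_from_dict({"format": "other", "params": {}})
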