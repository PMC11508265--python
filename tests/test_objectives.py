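"""Loss-term oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2adc.networks import FeatureStack
from t2adc.nn import Tensor
from t2adc.objectives import (
    ContrastiveBatch, LossConfig, info_nce, lsgan_terms, patch_nce,
    self_regularization, total_loss,
)


def brute_force_info_nce(v, v_plus, v_minus, tau):
    """Independent oracle: plain softmax cross-entropy over [pos, negs]."""
    logits = np.array([v @ v_plus] + [v @ n for n in v_minus]) / tau
    p = np.exp(logits) / np.exp(logits).sum()
    return -np.log(p[0])


def make_stack(embeddings_per_layer, locations_per_layer):
    layers = tuple(embeddings_per_layer)
    return FeatureStack(
        layers=layers,
        embeddings={l: Tensor(embeddings_per_layer[l]) for l in layers},
        locations={l: np.asarray(locations_per_layer[l]) for l in layers},
    )


class TestInfoNce:
    def test_equal_logits_closed_form(self):
        # all logits equal -> loss = log(M+1)
        v = np.zeros(4)
        batch = ContrastiveBatch(v=v, v_plus=np.ones(4),
                                 v_minus=np.ones((3, 4)), tau=0.07)
        assert abs(info_nce(batch) - np.log(4.0)) < 1e-9

    def test_orthogonal_negative_scalar_oracle(self):
        batch = ContrastiveBatch(v=np.array([1.0, 0.0]),
                                 v_plus=np.array([1.0, 0.0]),
                                 v_minus=np.array([[0.0, 1.0]]), tau=0.07)
        expected = np.log(1.0 + np.exp(-1.0 / 0.07))
        assert abs(info_nce(batch) - expected) < 1e-12
        assert info_nce(batch) < 1e-5

    def test_large_positive_logit_drives_loss_to_zero(self):
        v = np.array([30.0, 0.0])
        batch = ContrastiveBatch(v=v, v_plus=np.array([30.0, 0.0]),
                                 v_minus=np.array([[0.0, 1.0]]), tau=0.07)
        val = info_nce(batch)
        assert 0.0 <= val < 1e-12  # stabilized, no overflow

    def test_brute_force_oracle_100_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dim = int(rng.integers(2, 8))
            m = int(rng.integers(1, 6))
            tau = float(rng.uniform(0.05, 1.0))
            v = rng.normal(size=dim)
            vp = rng.normal(size=dim)
            vm = rng.normal(size=(m, dim))
            got = info_nce(ContrastiveBatch(v, vp, vm, tau))
            want = brute_force_info_nce(v, vp, vm, tau)
            assert abs(got - want) < 1e-6

    def test_positive(self):
        rng = np.random.default_rng(1)
        batch = ContrastiveBatch(rng.normal(size=3), rng.normal(size=3),
                                 rng.normal(size=(4, 3)))
        assert info_nce(batch) > 0

    def test_invalid_tau(self):
        with pytest.raises(ValueError, match="tau"):
            ContrastiveBatch(np.ones(2), np.ones(2), np.ones((1, 2)), tau=0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ContrastiveBatch(np.array([np.nan, 0.0]), np.ones(2),
                             np.ones((1, 2)))


class TestPatchNce:
    def test_reduces_to_info_nce_mean_for_two_locations(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(1, 2, 4))
        z /= np.linalg.norm(z, axis=-1, keepdims=True)
        zq = rng.normal(size=(1, 2, 4))
        zq /= np.linalg.norm(zq, axis=-1, keepdims=True)
        stack_q = make_stack({1: zq}, {1: [0, 1]})
        stack_k = make_stack({1: z}, {1: [0, 1]})
        got = patch_nce(stack_q, stack_k, tau=0.07).item()
        want = np.mean([
            info_nce(ContrastiveBatch(zq[0, 0], z[0, 0], z[0, 1:2], 0.07)),
            info_nce(ContrastiveBatch(zq[0, 1], z[0, 1], z[0, 0:1], 0.07)),
        ])
        assert abs(got - want) < 1e-9

    def test_exactly_equals_info_nce_on_symmetric_pair(self):
        # symmetric construction: both per-location terms coincide, so the
        # mean equals the single info_nce value
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        zq = np.stack([a, b])[None]
        zk = np.stack([a, b])[None]
        got = patch_nce(make_stack({1: zq}, {1: [0, 1]}),
                        make_stack({1: zk}, {1: [0, 1]}), tau=0.07).item()
        want = info_nce(ContrastiveBatch(a, a, b[None], tau=0.07))
        assert abs(got - want) < 1e-9

    def test_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        tau = 0.07
        z = rng.normal(size=(1, 5, 6))
        z /= np.linalg.norm(z, axis=-1, keepdims=True)
        stack = make_stack({0: z}, {0: np.arange(5)})
        got = patch_nce(stack, stack, tau=tau).item()
        # perfect correspondence: loss = mean_s log(1 + sum_{n!=s} e^{(z_s.z_n - 1)/tau})
        acc = []
        for s in range(5):
            denom = sum(np.exp((z[0, s] @ z[0, n] - 1.0) / tau)
                        for n in range(5) if n != s)
            acc.append(np.log(1.0 + denom))
        assert abs(got - np.mean(acc)) < 1e-9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        zq = rng.normal(size=(2, 6, 5))
        zk = rng.normal(size=(2, 6, 5))
        locs = np.arange(6)
        base = patch_nce(make_stack({0: zq}, {0: locs}),
                         make_stack({0: zk}, {0: locs}), 0.07).item()
        perm = rng.permutation(6)
        shuffled = patch_nce(make_stack({0: zq[:, perm]}, {0: locs[perm]}),
                             make_stack({0: zk[:, perm]}, {0: locs[perm]}),
                             0.07).item()
        assert abs(base - shuffled) < 1e-6

    def test_layer_mismatch_errors(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(1, 3, 4))
        a = make_stack({0: z}, {0: np.arange(3)})
        b = make_stack({1: z}, {1: np.arange(3)})
        with pytest.raises(ValueError, match="layer"):
            patch_nce(a, b, 0.07)

    def test_location_mismatch_errors(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(1, 3, 4))
        a = make_stack({0: z}, {0: np.array([0, 1, 2])})
        b = make_stack({0: z}, {0: np.array([0, 1, 5])})
        with pytest.raises(ValueError, match="location"):
            patch_nce(a, b, 0.07)

    def test_gradient_flows(self):
        rng = np.random.default_rng(7)
        zq = Tensor(rng.normal(size=(1, 4, 5)), requires_grad=True)
        zk = Tensor(rng.normal(size=(1, 4, 5)))
        stack_q = FeatureStack((0,), {0: zq}, {0: np.arange(4)})
        stack_k = FeatureStack((0,), {0: zk}, {0: np.arange(4)})
        loss = patch_nce(stack_q, stack_k, 0.07)
        loss.backward()
        assert zq.grad is not None and np.abs(zq.grad).max() > 0


class TestSelfRegularization:
    def test_identity_zero(self):
        x = np.random.default_rng(8).normal(size=(2, 3, 4, 4))
        assert self_regularization(x, x).item() == 0.0

    def test_constant_offset_closed_form(self):
        x = np.random.default_rng(9).normal(size=(2, 3, 4, 4))
        c = 0.37
        assert abs(self_regularization(x, x + c).item() - c**2) < 1e-12

    def test_nonnegative_random(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            v = self_regularization(rng.normal(size=(4, 4)),
                                    rng.normal(size=(4, 4))).item()
            assert v >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            self_regularization(np.zeros((2, 2)), np.zeros((3, 3)))


class TestLsgan:
    def test_perfect_discriminator(self):
        d_loss, _ = lsgan_terms(np.ones((2, 1, 3, 3)), np.zeros((2, 1, 3, 3)))
        assert d_loss.item() == 0.0

    def test_perfectly_fooled_generator(self):
        _, g_loss = lsgan_terms(np.zeros((1, 1, 2, 2)), np.ones((1, 1, 2, 2)))
        assert g_loss.item() == 0.0

    def test_half_scores_arithmetic(self):
        half = np.full((1, 1, 4, 4), 0.5)
        d_loss, g_loss = lsgan_terms(half, half)
        assert abs(d_loss.item() - 0.25) < 1e-12
        assert abs(g_loss.item() - 0.125) < 1e-12


class TestTotalLoss:
    def test_zero_lambdas(self):
        cfg = LossConfig(lambda_x=0, lambda_y=0, lambda_sr=0)
        assert total_loss(3.5, 1.0, 2.0, 4.0, cfg).item() == 3.5

    def test_unit_weights_sum(self):
        cfg = LossConfig()
        assert total_loss(1.0, 3.0, 2.0, 4.0, cfg).item() == 10.0

    @given(lam=st.floats(0.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_linear_in_lambda_x(self, lam):
        base = total_loss(1.0, 1.0, 2.0, 1.0,
                          LossConfig(lambda_x=0.0)).item()
        shifted = total_loss(1.0, 1.0, 2.0, 1.0,
                             LossConfig(lambda_x=lam)).item()
        assert abs(shifted - (base + lam * 2.0)) < 1e-9

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="lambda_sr"):
            LossConfig(lambda_sr=-1.0)
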