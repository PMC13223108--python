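"""Saliency, band aggregation, the KL alignment loss, and the joint objective."""

import numpy as np
import pytest

import cardialign.autodiff as ad
from cardialign.autodiff import Tensor
from cardialign.backbones import BackboneSpec, build_backbone
from cardialign.features import SpectrogramBatch
from cardialign.priors import (clinical_priors, make_band_partition,
                               select_prior, uniform_prior)
from cardialign.sca import (AttributionResult, SCAConfig, band_attribution,
                            gradient_x_input, kl_alignment_loss,
                            kl_per_sample, sca_objective, total_loss,
                            true_class_score)

PART = make_band_partition(128, 4)


def _batch(X, y):
    return SpectrogramBatch(X=X, y=y, valid_frames=[X.shape[2]] * X.shape[0])


class _LinearModel(ad.Module):
    """z_{i,c} = <w_c, x_i>: the analytic reference for gradient x input."""

    def __init__(self, w):  # w: (2, T*F)
        super().__init__()
        self.w = ad.Parameter(w)

    def forward(self, x):
        B = x.shape[0]
        flat = ad.reshape(x, (B, x.shape[2] * x.shape[3]))
        return ad.matmul(flat, ad.transpose(self.w, (1, 0)))


class TestTrueClassScore:
    def test_direct_sum(self):
        z = Tensor([[1.0, 2.0], [3.0, 4.0]])
        assert true_class_score(z, [0, 1]).item() == 5.0

    def test_zero_logits(self):
        assert true_class_score(Tensor(np.zeros((3, 2))), [1, 0, 1]).item() == 0.0

    def test_matches_loop(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(17, 2))
        y = rng.integers(0, 2, 17)
        expected = sum(z[i, y[i]] for i in range(17))
        assert true_class_score(Tensor(z), y).item() == pytest.approx(
            expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            true_class_score(Tensor(np.zeros((3, 2))), [0, 1])


class TestGradientXInput:
    def test_linear_model_analytic(self):
        rng = np.random.default_rng(1)
        T, F = 4, 128
        w = rng.normal(size=(2, T * F))
        X = rng.normal(size=(3, 1, T, F))
        y = np.array([0, 1, 0])
        model = _LinearModel(w)
        att = gradient_x_input(model, _batch(X, y))
        for i in range(3):
            expected = np.abs(w[y[i]].reshape(T, F) * X[i, 0])
            np.testing.assert_allclose(att.saliency[i, 0], expected,
                                       atol=1e-12)

    def test_padded_frames_get_zero_attribution(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2, 1, 6, 128))
        X[0, 0, 4:] = 0.0  # padding
        model = _LinearModel(rng.normal(size=(2, 6 * 128)))
        att = gradient_x_input(model, _batch(X, [0, 1]))
        assert np.all(att.saliency[0, 0, 4:] == 0)

    def test_saliency_nonnegative(self):
        rng = np.random.default_rng(3)
        model = build_backbone(BackboneSpec(name="smallcnn", init_seed=0))
        X = np.abs(rng.normal(size=(2, 1, 16, 128)))
        att = gradient_x_input(model, _batch(X, [0, 1]))
        assert np.all(att.saliency >= 0)

    def test_bad_output_shape_rejected(self):
        class ThreeWay(ad.Module):
            def forward(self, x):
                return Tensor(np.zeros((x.shape[0], 3)))

        with pytest.raises(ValueError, match="expected"):
            gradient_x_input(ThreeWay(), _batch(np.ones((1, 1, 4, 128)), [0]))

    def test_batch_sum_trick_equals_per_sample(self):
        """Grad of the summed score w.r.t. X_i equals the per-sample grad."""
        rng = np.random.default_rng(4)
        model = build_backbone(BackboneSpec(name="smallcnn", init_seed=1))
        X = np.abs(rng.normal(size=(3, 1, 12, 128)))
        y = np.array([0, 1, 1])
        att_joint = gradient_x_input(model, _batch(X, y))
        for i in range(3):
            att_i = gradient_x_input(model, _batch(X[i:i + 1], y[i:i + 1]))
            np.testing.assert_allclose(att_joint.saliency[i], att_i.saliency[0],
                                       atol=1e-12)


class TestBandAttribution:
    def test_constant_saliency_gives_uniform_mass(self):
        A = np.full((2, 1, 5, 128), 3.0)
        att = band_attribution(AttributionResult(saliency=A), PART)
        np.testing.assert_allclose(att.band_mass, 0.25, atol=1e-7)

    def test_confined_support(self):
        A = np.zeros((1, 1, 4, 128))
        A[0, 0, :, :32] = 1.0
        att = band_attribution(AttributionResult(saliency=A), PART)
        np.testing.assert_allclose(att.band_mass[0], [1, 0, 0, 0], atol=1e-7)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        A = np.abs(rng.normal(size=(4, 1, 7, 128)))
        eps = 1e-8
        att = band_attribution(AttributionResult(saliency=A), PART, eps)
        for i in range(4):
            band_sums = np.zeros(4)
            for k, (lo, hi) in enumerate(PART.bands):
                for f in range(lo, hi):
                    for t in range(7):
                        band_sums[k] += A[i, 0, t, f]
            expected = band_sums / (band_sums.sum() + eps)
            np.testing.assert_allclose(att.band_mass[i], expected, atol=1e-10)

    def test_rows_on_simplex(self):
        rng = np.random.default_rng(6)
        A = np.abs(rng.normal(size=(8, 1, 3, 128))) + 0.1
        att = band_attribution(AttributionResult(saliency=A), PART)
        np.testing.assert_allclose(att.band_mass.sum(axis=1), 1.0, atol=1e-6)

    def test_all_zero_saliency_warns(self):
        A = np.zeros((1, 1, 2, 128))
        with pytest.warns(UserWarning, match="all-zero saliency"):
            att = band_attribution(AttributionResult(saliency=A), PART)
        assert np.all(att.band_mass == 0)


class TestKLAlignment:
    def test_zero_at_matching_strictly_positive_prior(self):
        p = np.array([[0.4, 0.3, 0.2, 0.1]])
        assert kl_alignment_loss(p, p).item() == pytest.approx(0.0, abs=1e-6)

    def test_clinical_vs_uniform_hand_value(self):
        """KL([0.7,0.2,0.1,0] || uniform) = 0.5845 nats (hand evaluation)."""
        p = np.array([[0.7, 0.2, 0.1, 0.0]])
        q = np.array([[0.25] * 4])
        hand = (0.7 * np.log(0.7 / 0.25) + 0.2 * np.log(0.2 / 0.25)
                + 0.1 * np.log(0.1 / 0.25))
        assert hand == pytest.approx(0.5845, abs=2e-4)
        assert kl_alignment_loss(p, q, 1e-8).item() == pytest.approx(
            hand, abs=1e-6)

    def test_mass_in_zero_prior_band_is_heavily_penalized(self):
        eps = 1e-8
        p = np.array([[0.0, 0.0, 0.5, 0.5]])
        pi = clinical_priors().pi0[None, :]
        val = kl_alignment_loss(p, pi, eps).item()
        assert val >= 0.5 * np.log(0.5 / eps) - 1e-6

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        raw = np.abs(rng.normal(size=(20, 4))) + 1e-3
        p = raw / raw.sum(axis=1, keepdims=True)
        pi = select_prior(rng.integers(0, 2, 20), clinical_priors())
        eps = 1e-8
        expected = 0.0
        for i in range(20):
            for k in range(4):
                expected += p[i, k] * np.log(p[i, k] / (pi[i, k] + eps))
        expected /= 20
        assert kl_alignment_loss(p, pi, eps).item() == pytest.approx(
            expected, abs=1e-10)
        per = kl_per_sample(p, pi, eps)
        assert per.mean() == pytest.approx(expected, abs=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            kl_alignment_loss(np.array([[-0.1, 0.5, 0.3, 0.3]]),
                              np.array([[0.25] * 4]))

    def test_nonnegative_up_to_epsilon(self):
        rng = np.random.default_rng(8)
        eps = 1e-8
        raw = np.abs(rng.normal(size=(50, 4))) + 1e-2
        p = raw / raw.sum(axis=1, keepdims=True)
        per = kl_per_sample(p, p, eps)
        assert np.all(per >= -4 * eps)


class TestTotalLoss:
    def test_lambda_zero_reduces_to_ce(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(6, 2))
        y = rng.integers(0, 2, 6)
        p = np.full((6, 4), 0.25)
        pi = select_prior(y, clinical_priors())
        bd = total_loss(z, y, p, pi, SCAConfig(lambda_sca=0.0))
        assert bd.total == pytest.approx(bd.ce, rel=1e-12)

    def test_linear_combination(self):
        z = np.array([[0.0, 0.0]])
        p = np.array([[0.7, 0.2, 0.1, 0.0]])
        pi = np.array([[0.25] * 4])
        bd = total_loss(z, [0], p, pi, SCAConfig(lambda_sca=0.3))
        assert bd.total == pytest.approx(bd.ce + 0.3 * bd.sca, rel=1e-9)

    @pytest.mark.parametrize("lam", [0.05, 0.1, 0.2, 0.3, 0.5])
    def test_grid_lambdas_accepted(self, lam):
        bd = total_loss(np.zeros((1, 2)), [0], np.full((1, 4), 0.25),
                        np.full((1, 4), 0.25), SCAConfig(lambda_sca=lam))
        assert bd.lambda_sca == lam
        assert bd.total == pytest.approx(bd.ce + lam * bd.sca, abs=1e-6)


class TestDoubleBackprop:
    def test_sca_gradient_matches_finite_difference(self):
        """Perturbing any parameter changes L_SCA as autodiff predicts."""
        rng = np.random.default_rng(10)
        model = build_backbone(BackboneSpec(name="smallcnn", init_seed=2))
        X = np.abs(rng.normal(size=(4, 1, 12, 128)))
        batch = _batch(X, np.array([0, 1, 0, 1]))
        table, cfg = clinical_priors(), SCAConfig(lambda_sca=1.0,
                                                  differentiable=True)

        def sca_value():
            bd, _ = sca_objective(model, batch, table, PART, cfg)
            return bd.sca

        bd, att = sca_objective(model, batch, table, PART, cfg)
        # isolate d(L_SCA)/dtheta by differentiating total with lambda=1 and
        # subtracting the CE gradient
        params = model.parameters()
        g_tot = ad.grad(bd.total_t, params)
        z = model(Tensor(batch.X))
        g_ce = ad.grad(ad.cross_entropy(z, batch.y), params)
        h = 1e-5
        checked = 0
        for pi_idx in (0, 2, 4):
            p = params[pi_idx]
            g_sca = g_tot[pi_idx].data - g_ce[pi_idx].data
            idx = np.unravel_index(np.argmax(np.abs(g_sca)), p.data.shape)
            if abs(g_sca[idx]) < 1e-8:
                continue
            old = p.data[idx]
            p.data[idx] = old + h
            up = sca_value()
            p.data[idx] = old - h
            dn = sca_value()
            p.data[idx] = old
            fd = (up - dn) / (2 * h)
            assert fd == pytest.approx(g_sca[idx], rel=1e-3)
            checked += 1
        assert checked >= 2

    def test_non_differentiable_mode_detaches(self):
        rng = np.random.default_rng(11)
        model = build_backbone(BackboneSpec(name="smallcnn", init_seed=3))
        X = np.abs(rng.normal(size=(2, 1, 8, 128)))
        batch = _batch(X, np.array([0, 1]))
        att = gradient_x_input(model, batch, SCAConfig(differentiable=False))
        assert att.saliency_t is None
        att = band_attribution(att, PART)
        assert att.band_mass_t is None

    def test_differentiable_mode_keeps_graph(self):
        rng = np.random.default_rng(12)
        model = build_backbone(BackboneSpec(name="smallcnn", init_seed=3))
        X = np.abs(rng.normal(size=(2, 1, 8, 128)))
        batch = _batch(X, np.array([0, 1]))
        att = gradient_x_input(model, batch, SCAConfig(differentiable=True))
        assert att.saliency_t is not None
        assert att.saliency_t.requires_grad
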