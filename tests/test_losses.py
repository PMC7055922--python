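"""Loss terms against brute-force loop oracles and printed-weight arithmetic."""

import numpy as np
import pytest

from hicsr import (
    LossWeights, adversarial_loss_g, discriminator_loss,
    generator_total_loss, make_extractor, mse_loss, perceptual_loss, tv_loss,
)
from hicsr.losses import BuiltinExtractor, IdentityExtractor
from hicsr.nn import Tensor


def mse_oracle(a, b):
    total, n = 0.0, 0
    for x, y in zip(a.ravel(), b.ravel()):
        total += (x - y) ** 2
        n += 1
    return total / n


def tv_oracle(batch):
    vals = []
    for img in batch[:, 0]:
        h, w = img.shape
        v = sum((img[i + 1, j] - img[i, j]) ** 2
                for i in range(h - 1) for j in range(w))
        hz = sum((img[i, j + 1] - img[i, j]) ** 2
                 for i in range(h) for j in range(w - 1))
        vals.append(v / ((h - 1) * w) + hz / (h * (w - 1)))
    return float(np.mean(vals))


def bce_oracle(real, fake, eps=1e-7):
    total = 0.0
    for y, yh in zip(real, fake):
        y = min(max(y, eps), 1 - eps)
        yh = min(max(yh, eps), 1 - eps)
        total += -(np.log(y) + np.log(1 - yh))
    return total / len(real)


class TestMSE:
    def test_identical_inputs_zero(self, rng):
        a = rng.random((2, 1, 4, 4))
        assert mse_loss(a, a).item() == 0.0

    def test_unit_offset(self):
        assert mse_loss(np.zeros((1, 1, 4, 4)), np.ones((1, 1, 4, 4))).item() == 1.0

    def test_matches_loop_oracle(self, rng):
        a, b = rng.random((3, 1, 4, 4)), rng.random((3, 1, 4, 4))
        assert mse_loss(a, b).item() == pytest.approx(mse_oracle(a, b),
                                                      abs=1e-12)


class TestPerceptual:
    def test_identical_inputs_zero_for_any_extractor(self, rng):
        a = rng.random((2, 1, 8, 8))
        for ex in (IdentityExtractor(), BuiltinExtractor()):
            assert perceptual_loss(ex, a, a).item() == 0.0

    def test_identity_extractor_collapses_to_mse(self, rng):
        a, b = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        assert perceptual_loss(IdentityExtractor(), a, b).item() == \
            pytest.approx(mse_loss(a, b).item(), abs=1e-15)

    def test_linear_extractor_matches_matrix_oracle(self, rng):
        """Extractor y = A @ x on flattened 4x4 tiles: loss must equal
        mean of ||A (a-b)||^2 elementwise."""
        a_mat = rng.normal(size=(16, 16))

        class LinearExtractor:
            def __call__(self, x):
                flat = x.reshape(x.shape[0], 16)
                return flat.matmul(Tensor(a_mat.T))

        a, b = rng.random((3, 1, 4, 4)), rng.random((3, 1, 4, 4))
        got = perceptual_loss(LinearExtractor(), a, b).item()
        expected = np.mean([
            ((a_mat @ (a[i].ravel() - b[i].ravel())) ** 2).mean()
            for i in range(3)
        ])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_builtin_extractor_is_frozen_and_deterministic(self, rng):
        ex1, ex2 = BuiltinExtractor(), BuiltinExtractor()
        x = Tensor(rng.random((1, 1, 16, 16)))
        assert np.array_equal(ex1(x).data, ex2(x).data)
        assert all(not p.requires_grad for p in ex1.parameters())


class TestTV:
    def test_constant_tile_zero(self):
        assert tv_loss(np.full((1, 1, 5, 5), 0.7)).item() == 0.0

    def test_hand_evaluated_two_by_two(self):
        x = np.array([[[[0.0, 1.0], [0.0, 1.0]]]])
        assert tv_loss(x).item() == pytest.approx(1.0, abs=1e-15)

    def test_quadratic_homogeneity(self, rng):
        x = rng.random((2, 1, 6, 6))
        assert tv_loss(2 * x).item() == pytest.approx(4 * tv_loss(x).item(),
                                                      abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        x = rng.random((3, 1, 4, 4))
        assert tv_loss(x).item() == pytest.approx(tv_oracle(x), abs=1e-12)

    def test_tiny_tile_rejected(self):
        with pytest.raises(ValueError, match="side >= 2"):
            tv_loss(np.ones((1, 1, 1, 1)))


class TestAdversarial:
    def test_perfectly_real_scores_zero(self):
        assert adversarial_loss_g(np.ones(4)).item() == 0.0

    def test_perfectly_fake_scores_one(self):
        assert adversarial_loss_g(np.zeros(4)).item() == 1.0

    def test_arithmetic(self):
        assert adversarial_loss_g(np.array([0.2, 0.6])).item() == \
            pytest.approx(0.6, abs=1e-15)

    def test_literal_mode_is_raw_mean(self):
        scores = np.array([0.2, 0.6])
        assert adversarial_loss_g(scores, literal=True).item() == \
            pytest.approx(0.4, abs=1e-15)


class TestDiscriminatorLoss:
    def test_perfect_discriminator_near_zero(self):
        eps = 1e-7
        val = discriminator_loss(np.full(3, 1 - eps), np.full(3, eps)).item()
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_chance_level_is_two_log_two(self):
        val = discriminator_loss(np.full(4, 0.5), np.full(4, 0.5)).item()
        assert val == pytest.approx(2 * np.log(2), abs=1e-12)
        assert val == pytest.approx(1.3862943611198906, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        real, fake = rng.random(8), rng.random(8)
        assert discriminator_loss(real, fake).item() == \
            pytest.approx(bce_oracle(real, fake), abs=1e-12)

    def test_literal_mode_shares_minimizer_direction(self):
        """The printed objective decreases as y_hat -> 1 and y -> 0; the BCE
        form decreases as y -> 1 and y_hat -> 0. Both are extremal at a
        perfectly separating discriminator."""
        good = discriminator_loss(np.full(2, 0.99), np.full(2, 0.01))
        bad = discriminator_loss(np.full(2, 0.5), np.full(2, 0.5))
        assert good.item() < bad.item()
        lit_sep = discriminator_loss(np.full(2, 0.99), np.full(2, 0.01),
                                     literal=True)
        lit_mix = discriminator_loss(np.full(2, 0.5), np.full(2, 0.5),
                                     literal=True)
        assert lit_sep.item() < lit_mix.item()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            discriminator_loss(np.ones(2), np.ones(3))


class TestTotalLoss:
    def test_printed_weights_forced_arithmetic(self):
        w = LossWeights()
        assert (w.alpha, w.beta, w.gamma) == (0.006, 2e-8, 0.001)
        total = w.combine(0.01, 1.0, 10.0, 0.5)
        assert total == pytest.approx(0.0165002, abs=1e-12)

    def test_zero_at_perfect_prediction(self, rng):
        # constant tiles: every term, including TV, vanishes exactly
        a = np.full((2, 1, 4, 4), 0.3)
        total, rep = generator_total_loss(a, a, np.ones(2),
                                          IdentityExtractor())
        assert total.item() == 0.0
        # random tiles: only the TV term (a function of pred alone) remains,
        # scaled by beta = 2e-8
        b = rng.random((2, 1, 4, 4))
        total_b, rep_b = generator_total_loss(b, b, np.ones(2),
                                              IdentityExtractor())
        assert rep_b.l_mse == rep_b.l_vgg == rep_b.l_ad == 0.0
        assert abs(total_b.item()) < 1e-7

    def test_zero_weights_reduce_to_mse(self, rng):
        a, b = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        total, _ = generator_total_loss(
            a, b, np.zeros(2), IdentityExtractor(),
            LossWeights(alpha=0, beta=0, gamma=0))
        assert total.item() == pytest.approx(mse_loss(a, b).item(), abs=1e-15)

    def test_report_internal_consistency(self, rng):
        w = LossWeights()
        a, b = rng.random((2, 1, 8, 8)), rng.random((2, 1, 8, 8))
        total, rep = generator_total_loss(a, b, rng.random(2),
                                          BuiltinExtractor(), w)
        assert rep.total == pytest.approx(
            rep.l_mse + w.alpha * rep.l_vgg + w.beta * rep.l_tv
            + w.gamma * rep.l_ad, abs=1e-9)
        assert total.item() == pytest.approx(rep.total, abs=1e-15)

    def test_all_components_nonnegative(self, rng):
        a, b = rng.random((2, 1, 8, 8)), rng.random((2, 1, 8, 8))
        _, rep = generator_total_loss(a, b, rng.random(2),
                                      BuiltinExtractor())
        assert min(rep.l_mse, rep.l_vgg, rep.l_tv, rep.l_ad) >= 0


def test_gradient_step_on_mse_reduces_it(rng):
    """One Adam step from a perturbed target moves the prediction closer."""
    from hicsr.nn import Adam
    target = rng.random((1, 1, 4, 4))
    pred = Tensor(target + 0.1 * rng.normal(size=target.shape),
                  requires_grad=True)
    before = mse_loss(pred, target).item()
    opt = Adam([pred], lr=0.01)
    loss = mse_loss(pred, target)
    loss.backward()
    opt.step()
    assert mse_loss(pred, target).item() < before


def test_make_extractor_names():
    assert make_extractor("none") is None
    assert isinstance(make_extractor("builtin"), BuiltinExtractor)
    with pytest.raises(ValueError, match="unknown extractor"):
        make_extractor("vgg99")
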