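"""Self-cross similarity loss: formulas, limits, gradients, monotonicity."""

import numpy as np
import pytest

from maepick import (LossConfig, SimilaritySums, adjusted_similarities, cosine,
                     cross_similarity, scs_from_features, scs_loss,
                     self_similarity, similarity_sums, total_loss)
from maepick._autodiff import Tensor, parameter


def naive_cosine(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def naive_sums(fl, fu):
    s_ll = sum(naive_cosine(a, b) for a in fl for b in fl)
    s_lu = sum(naive_cosine(a, b) for a in fl for b in fu)
    s_uu = sum(naive_cosine(a, b) for a in fu for b in fu)
    return s_ll, s_lu, s_uu


class TestCosine:
    def test_identical_vectors(self, rng):
        v = rng.normal(size=8)
        assert cosine(v, v) == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_vectors(self):
        assert cosine([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0, abs=1e-7)

    def test_45_degrees(self):
        assert cosine([1.0, 0.0], [1.0, 1.0]) == pytest.approx(0.70710678, abs=1e-6)

    def test_scale_invariance_and_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        assert cosine(3.0 * a, b) == pytest.approx(cosine(a, b), abs=1e-5)
        assert cosine(b, a) == pytest.approx(cosine(a, b), abs=1e-6)

    def test_zero_norm_is_an_error(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine([0.0, 0.0], [1.0, 0.0])


class TestMeanSimilarities:
    def test_single_feature_self_similarity_is_one(self, rng):
        assert self_similarity(rng.normal(size=(1, 5))) == pytest.approx(1.0, abs=1e-6)

    def test_two_orthogonal_features(self):
        f = np.array([[1.0, 0.0], [0.0, 1.0]])
        # 2 self-pairs at 1 plus 2 cross-pairs at 0, over 4 ordered pairs
        assert self_similarity(f) == pytest.approx(0.5, abs=1e-6)

    def test_identical_sets_cross_similarity_is_one(self, rng):
        v = rng.normal(size=6)
        fl = np.tile(v, (3, 1))
        assert cross_similarity(fl, np.tile(v, (4, 1))) == pytest.approx(1.0, 1e-5)

    def test_mixed_cross_similarity_brute_force(self):
        fl = np.array([[1.0, 0.0]])
        fu = np.array([[1.0, 0.0], [0.0, 1.0]])  # cosines {1, 0}
        assert cross_similarity(fl, fu) == pytest.approx(0.5, abs=1e-6)

    def test_empty_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            self_similarity(np.zeros((0, 4)))
        with pytest.raises(ValueError):
            cross_similarity(rng.normal(size=(2, 4)), np.zeros((0, 4)))

    def test_vectorized_sums_match_double_loop_oracle(self, rng):
        """Vectorized pairwise sums vs a naive O(m*n) loop, many random sets."""
        for _ in range(50):
            m, n = rng.integers(1, 11, size=2)
            d = int(rng.integers(2, 9))
            fl = rng.normal(size=(m, d))
            fu = rng.normal(size=(n, d))
            sums = similarity_sums(fl, fu)
            s_ll, s_lu, s_uu = naive_sums(fl, fu)
            assert sums.s_ll == pytest.approx(s_ll, abs=1e-4)
            assert sums.s_lu == pytest.approx(s_lu, abs=1e-4)
            assert sums.s_uu == pytest.approx(s_uu, abs=1e-4)
            assert self_similarity(fl) == pytest.approx(s_ll / m**2, abs=1e-5)
            assert cross_similarity(fl, fu) == pytest.approx(s_lu / (m * n), abs=1e-5)
            # each pairwise cosine is <= 1, bounding the sums
            assert sums.s_ll <= m**2 + 1e-6
            assert sums.s_uu <= n**2 + 1e-6
            assert abs(sums.s_lu) <= m * n + 1e-6


class TestAdjustedSimilarities:
    def worked_sums(self):
        # m=2, n=3, every pairwise cosine = 1
        return SimilaritySums(4.0, 6.0, 9.0, 2, 3)

    def test_printed_formula_worked_example(self):
        s_self, s_cross = adjusted_similarities(self.worked_sums(), 0.5)
        assert s_self == pytest.approx(0.49, abs=1e-9)
        assert s_cross == pytest.approx(0.35, abs=1e-9)

    def test_pi_one_limit_zeroes_cross(self):
        _, s_cross = adjusted_similarities(self.worked_sums(), 1.0)
        assert s_cross == 0.0

    def test_pi_zero_limit_printed_forms(self, rng):
        fl, fu = rng.normal(size=(3, 5)), rng.normal(size=(4, 5))
        sums = similarity_sums(fl, fu)
        s_self, s_cross = adjusted_similarities(sums, 0.0)
        m, n = 3, 4
        assert s_self == pytest.approx(sums.s_ll / (m + n) ** 2, abs=1e-6)
        assert s_cross == pytest.approx(sums.s_lu / ((m + n) * n), abs=1e-6)

    def test_from_matching_feature_construction(self):
        v = np.array([2.0, 1.0, -1.0])
        sums = similarity_sums(np.tile(v, (2, 1)), np.tile(v, (3, 1)))
        s_self, s_cross = adjusted_similarities(sums, 0.5)
        assert s_self == pytest.approx(0.49, abs=1e-5)
        assert s_cross == pytest.approx(0.35, abs=1e-5)


class TestScsLoss:
    CFG = LossConfig(alpha=0.5, tau=0.05)

    def test_worked_values(self):
        assert scs_loss(1.0, 1.0, self.CFG) == pytest.approx(1.0)
        assert scs_loss(-1.0, 1.0, self.CFG) == pytest.approx(0.05)

    def test_floor_and_monotonicity_grid(self):
        grid = np.linspace(-1, 1, 20)
        vals = np.array([[scs_loss(sc, ss, self.CFG) for ss in grid] for sc in grid])
        assert (vals >= self.CFG.tau - 1e-12).all()
        # non-decreasing in s_cross (rows), non-increasing in s_self (cols)
        assert (np.diff(vals, axis=0) >= -1e-12).all()
        assert (np.diff(vals, axis=1) <= 1e-12).all()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            LossConfig(alpha=1.5)
        with pytest.raises(ValueError, match="pi_hat"):
            LossConfig(pi_hat=-0.1)
        with pytest.raises(ValueError, match="beta"):
            LossConfig(beta=-1.0)


class TestTotalLoss:
    def test_beta_zero_is_pure_mse(self):
        assert total_loss(0.42, 99.0, 0.0) == pytest.approx(0.42)

    def test_weighted_sum(self):
        assert total_loss(0.2, 0.3, 1.0) == pytest.approx(0.5)

    def test_gradient_composition_finite_difference(self, rng):
        """d(total)/dw == d(mse-part)/dw + beta * d(scs-part)/dw on a toy model."""
        w = parameter(rng.normal(size=(4,)) + 2.0)
        target = rng.normal(size=4).astype(np.float32)
        fl_np = rng.normal(size=(2, 4)).astype(np.float32)
        beta = 0.7
        cfg = LossConfig(alpha=0.5, tau=-10.0, adjusted=False)  # inactive floor

        def l_mse():
            d = w - Tensor(target)
            return (d * d).mean()

        def l_scs():
            fu = w.reshape(1, 4)
            loss, _, _ = scs_from_features(Tensor(fl_np), fu, cfg)
            return loss

        total = l_mse() + beta * l_scs()
        total.backward()
        g_total = w.grad.copy()

        eps = 1e-3
        num = np.zeros(4)
        for i in range(4):
            orig = w.data[i]
            w.data[i] = orig + eps
            f1 = l_mse().item() + beta * l_scs().item()
            w.data[i] = orig - eps
            f2 = l_mse().item() + beta * l_scs().item()
            w.data[i] = orig
            num[i] = (f1 - f2) / (2 * eps)
        np.testing.assert_allclose(g_total, num, atol=5e-3)

    def test_directional_training_separates_embeddings(self, rng):
        """Minimizing the SCS loss on a 2-parameter embedding drives
        self-similarity up and cross-similarity down."""
        from maepick._nn import AdamW

        cfg = LossConfig(alpha=0.5, tau=0.05, adjusted=False)
        fl = parameter(np.array([[1.0, 0.2], [0.8, 0.4]]))
        fu_np = np.array([[0.7, 0.5], [0.6, 0.6], [-0.2, 1.0]], np.float32)
        loss0, s_self0, s_cross0 = scs_from_features(fl, Tensor(fu_np), cfg)
        opt = AdamW([fl], lr=0.05)
        for _ in range(60):
            loss, _, _ = scs_from_features(fl, Tensor(fu_np), cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
        _, s_self1, s_cross1 = scs_from_features(fl, Tensor(fu_np), cfg)
        assert s_self1.item() >= s_self0.item() - 1e-6
        assert s_cross1.item() < s_cross0.item()
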