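import numpy as np
import pytest

from emgknee.dbn import (
    DbnModel,
    DbnTrainConfig,
    RbmParams,
    cd_update,
    energy,
    exact_loglik_gradient,
    fine_tune_autoencoder,
    hidden_probs,
    joint_distribution,
    pretrain_dbn,
    reconstruct,
    transform,
    visible_probs,
)


def rbm(W, b, c):
    return RbmParams(W=np.array(W, float), b=np.array(b, float), c=np.array(c, float))


def random_rbm(m, n, rng, scale=1.0):
    return RbmParams(
        W=scale * rng.standard_normal((m, n)),
        b=scale * rng.standard_normal(m),
        c=scale * rng.standard_normal(n),
    )


class TestConditionals:
    def test_zero_parameters_give_half(self):
        r = rbm(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert hidden_probs(r, np.array([1.0, 0.0, 1.0])) == pytest.approx([0.5, 0.5])
        assert visible_probs(r, np.array([1.0, 0.0])) == pytest.approx([0.5] * 3)

    def test_cancelling_weight_and_bias(self):
        r = rbm([[2.0]], [0.0], [-2.0])
        assert hidden_probs(r, np.array([1.0]))[0] == pytest.approx(0.5)
        r2 = rbm([[2.0]], [-2.0], [0.0])
        assert visible_probs(r2, np.array([1.0]))[0] == pytest.approx(0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        r = random_rbm(4, 6, rng, scale=5.0)
        h = hidden_probs(r, rng.random(4))
        v = visible_probs(r, rng.random(6))
        assert np.all((h > 0) & (h < 1)) and np.all((v > 0) & (v < 1))

    def test_shape_mismatch_rejected(self):
        r = rbm(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            hidden_probs(r, np.zeros(4))
        with pytest.raises(ValueError):
            visible_probs(r, np.zeros(3))


class TestEnergy:
    def test_zero_state_has_zero_energy(self):
        rng = np.random.default_rng(1)
        r = random_rbm(3, 2, rng)
        assert energy(r, np.zeros(3), np.zeros(2)) == 0.0

    def test_hand_computed_energy(self):
        r = rbm([[1.0]], [0.5], [-0.5])
        assert energy(r, np.array([1.0]), np.array([1.0])) == pytest.approx(-1.0)

    def test_energy_linear_in_visible_bias(self):
        rng = np.random.default_rng(2)
        r = random_rbm(3, 2, rng)
        v, h = rng.random(3), rng.random(2)
        delta = np.array([0.3, -0.2, 0.7])
        shifted = RbmParams(W=r.W, b=r.b + delta, c=r.c)
        assert energy(shifted, v, h) - energy(r, v, h) == pytest.approx(-delta @ v)

    @pytest.mark.parametrize("m,n", [(2, 2), (3, 2), (4, 3)])
    def test_joint_distribution_normalizes(self, m, n):
        rng = np.random.default_rng(3)
        p = joint_distribution(random_rbm(m, n, rng))
        assert abs(1.0 - p.sum()) < 1e-12
        assert p.min() > 0.0


class TestContrastiveDivergence:
    def test_zero_learning_rate_is_identity(self):
        rng = np.random.default_rng(4)
        r = random_rbm(3, 2, rng)
        batch = rng.random((8, 3))
        out = cd_update(r, batch, 0.0, rng=np.random.default_rng(0))
        assert np.array_equal(out.W, r.W)
        assert np.array_equal(out.b, r.b)

    def test_fixed_seed_reproduces_update(self):
        rng = np.random.default_rng(5)
        r = random_rbm(3, 2, rng)
        batch = rng.random((8, 3))
        u1 = cd_update(r, batch, 0.1, rng=np.random.default_rng(42))
        u2 = cd_update(r, batch, 0.1, rng=np.random.default_rng(42))
        assert np.array_equal(u1.W, u2.W)

    def test_invalid_batches_rejected(self):
        r = rbm(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            cd_update(r, np.empty((0, 2)), 0.1)
        with pytest.raises(ValueError):
            cd_update(r, np.array([[0.5, 1.5]]), 0.1)

    @pytest.mark.parametrize("m,n", [(2, 2), (3, 2)])
    def test_averaged_cd_aligns_with_exact_gradient(self, m, n):
        """The mean CD-1 update over many chains must point in roughly the
        same direction as the exact log-likelihood gradient (cosine > 0.5)
        at random initializations."""
        rng = np.random.default_rng(6)
        data = (rng.random((4, m)) > 0.5).astype(float)
        for trial in range(10):
            r = random_rbm(m, n, rng, scale=0.5)
            gW, gb, gc = exact_loglik_gradient(r, data)
            big = np.tile(data, (10_000, 1))
            upd = cd_update(r, big, 1.0, rng=np.random.default_rng(trial))
            dW, db, dc = upd.W - r.W, upd.b - r.b, upd.c - r.c
            g = np.concatenate([gW.ravel(), gb, gc])
            d = np.concatenate([dW.ravel(), db, dc])
            cos = g @ d / (np.linalg.norm(g) * np.linalg.norm(d))
            assert cos > 0.5


class TestExactGradientOracle:
    def test_uniform_model_uniform_data_has_zero_gradient(self):
        r = rbm(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        data = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        gW, gb, gc = exact_loglik_gradient(r, data)
        assert np.abs(gW).max() < 1e-12
        assert np.abs(gb).max() < 1e-12
        assert np.abs(gc).max() < 1e-12

    def test_gradient_equivariant_under_hidden_permutation(self):
        """Permuting the hidden units permutes the gradient the same way."""
        rng = np.random.default_rng(7)
        r = random_rbm(3, 3, rng, scale=0.4)
        data = (rng.random((6, 3)) > 0.5).astype(float)
        gW, gb, gc = exact_loglik_gradient(r, data)
        perm = [2, 0, 1]
        rp = RbmParams(W=r.W[:, perm], b=r.b, c=r.c[perm])
        gWp, gbp, gcp = exact_loglik_gradient(rp, data)
        assert gWp == pytest.approx(gW[:, perm], abs=1e-12)
        assert gcp == pytest.approx(gc[perm], abs=1e-12)
        assert gbp == pytest.approx(gb, abs=1e-12)

    def test_gradient_vanishes_after_long_training(self):
        """Gradient-ascent on the exact gradient converges to a stationary
        point of the likelihood (oracle self-consistency).  The empirical
        distribution has full support so the optimum is at finite weights."""
        rng = np.random.default_rng(8)
        data = np.array(
            [[0.0, 0.0]] * 3 + [[1.0, 1.0]] * 3 + [[0.0, 1.0], [1.0, 0.0]]
        )
        r = random_rbm(2, 2, rng, scale=0.1)
        for _ in range(5000):
            gW, gb, gc = exact_loglik_gradient(r, data)
            r = RbmParams(W=r.W + 0.2 * gW, b=r.b + 0.2 * gb, c=r.c + 0.2 * gc)
        norm = np.sqrt(np.sum(gW**2) + np.sum(gb**2) + np.sum(gc**2))
        assert norm < 1e-3

    def test_oversized_rbm_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            exact_loglik_gradient(random_rbm(10, 10, rng), np.zeros((1, 10)))


class TestDbnTraining:
    def test_single_rbm_stack_structure(self, small_dataset):
        cfg = DbnTrainConfig(epochs=2, seed=0)
        model = pretrain_dbn([4, 5], small_dataset.features[:100], cfg)
        assert len(model.rbms) == 1
        assert model.rbms[0].W.shape == (4, 5)

    def test_zero_epochs_keeps_random_initialization(self, small_dataset):
        X = small_dataset.features[:50]
        m0 = pretrain_dbn([4, 3, 3], X, DbnTrainConfig(epochs=0, seed=1))
        m1 = pretrain_dbn([4, 3, 3], X, DbnTrainConfig(epochs=0, seed=1))
        assert np.array_equal(m0.rbms[0].W, m1.rbms[0].W)
        trained = pretrain_dbn([4, 3, 3], X, DbnTrainConfig(epochs=2, seed=1))
        assert not np.array_equal(m0.rbms[0].W, trained.rbms[0].W)

    def test_pretraining_is_seed_deterministic(self, small_dataset):
        X = small_dataset.features[:120]
        a = pretrain_dbn([4, 6, 4], X, DbnTrainConfig(epochs=5, seed=3))
        b = pretrain_dbn([4, 6, 4], X, DbnTrainConfig(epochs=5, seed=3))
        for ra, rb in zip(a.rbms, b.rbms):
            assert np.array_equal(ra.W, rb.W)

    def test_training_reduces_first_rbm_reconstruction_error(self, small_dataset):
        """Median over 5 seeds: 200-epoch CD reconstructs the features
        better than 1-epoch CD."""
        X = small_dataset.features
        deltas = []
        for seed in range(5):
            errs = []
            for epochs in (1, 200):
                m = pretrain_dbn([4, 8], X, DbnTrainConfig(epochs=epochs, seed=seed))
                recon = visible_probs(m.rbms[0], hidden_probs(m.rbms[0], X))
                errs.append(float(np.mean((recon - X) ** 2)))
            deltas.append(errs[0] - errs[1])
        assert np.median(deltas) > 0.0

    def test_fine_tune_zero_epochs_keeps_pretrained_weights(self, small_dataset):
        X = small_dataset.features[:100]
        pre = pretrain_dbn([4, 5, 3], X, DbnTrainConfig(epochs=2, seed=0))
        ft = fine_tune_autoencoder(pre, X, DbnTrainConfig(epochs=2, fine_tune_epochs=0, seed=0))
        assert np.array_equal(ft.encoder[0][0], pre.rbms[0].W)
        assert np.array_equal(ft.decoder[-1][0], pre.rbms[0].W.T)

    def test_fine_tune_does_not_worsen_reconstruction(self, small_dataset):
        X = small_dataset.features
        improvements = []
        for seed in range(5):
            cfg = DbnTrainConfig(epochs=5, fine_tune_epochs=100, seed=seed)
            pre = pretrain_dbn([4, 8, 5], X, cfg)
            before = float(np.mean((reconstruct(pre, X) - X) ** 2))
            after = float(np.mean((reconstruct(fine_tune_autoencoder(pre, X, cfg), X) - X) ** 2))
            improvements.append(before - after)
        assert np.median(improvements) >= 0.0

    def test_fine_tune_requires_trained_model(self, small_dataset):
        X = small_dataset.features[:60]
        m = pretrain_dbn([4, 3], X, DbnTrainConfig(epochs=1, seed=0))
        m.trained = False
        with pytest.raises(ValueError):
            fine_tune_autoencoder(m, X, DbnTrainConfig())

    def test_reconstruction_shape_matches_input(self, small_dataset):
        X = small_dataset.features[:80]
        cfg = DbnTrainConfig(epochs=2, fine_tune_epochs=20, seed=0)
        ft = fine_tune_autoencoder(pretrain_dbn([4, 6, 3], X, cfg), X, cfg)
        assert reconstruct(ft, X).shape == X.shape


class TestTransform:
    def test_output_width_is_top_layer_width(self, small_dataset):
        X = small_dataset.features[:100]
        cfg = DbnTrainConfig(epochs=2, seed=0)
        model = pretrain_dbn([4, 37, 26, 16, 5], X, cfg)
        out = transform(model, X)
        assert out.shape == (100, 5)

    def test_outputs_in_open_unit_interval_and_deterministic(self, small_dataset):
        X = small_dataset.features[:50]
        cfg = DbnTrainConfig(epochs=2, fine_tune_epochs=10, seed=0)
        model = fine_tune_autoencoder(pretrain_dbn([4, 6, 4], X, cfg), X, cfg)
        out = transform(model, X)
        assert np.all((out > 0) & (out < 1))
        assert np.array_equal(out, transform(model, X))

    def test_wrong_feature_dimension_rejected(self, small_dataset):
        cfg = DbnTrainConfig(epochs=1, seed=0)
        model = pretrain_dbn([4, 3], small_dataset.features[:50], cfg)
        with pytest.raises(ValueError):
            transform(model, np.zeros((5, 3)))
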