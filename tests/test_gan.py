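import numpy as np
import pytest
from scipy.stats import ks_2samp

from ganprog.gan import (
    GanConfig,
    LatentSampler,
    build_networks,
    critic_loss,
    gene_association,
    generate,
    load_checkpoints,
    restore_generator,
    save_checkpoints,
    train,
)
from ganprog.nn import DenseNet


class TestBuildNetworks:
    def test_default_generator_parameter_count(self):
        """100-250-250-1208 layout: 100*250+250 + 250*250+250 + 250*1208+1208 weights+biases."""
        cfg = GanConfig(gene_count=1208)
        gen, critic = build_networks(cfg)
        assert gen.n_parameters() == 100 * 250 + 250 + 250 * 250 + 250 + 250 * 1208 + 1208
        assert critic.sizes == (1208, 150, 150, 1)

    def test_zero_latent_input_finite_output(self):
        cfg = GanConfig(gene_count=30, latent_dim=10, gen_hidden=(16, 16))
        gen, _ = build_networks(cfg, np.random.default_rng(0))
        y = gen.forward(np.zeros((3, 10)))
        assert y.shape == (3, 30) and np.isfinite(y).all()

    def test_zero_init_range_makes_output_constant_in_z(self):
        cfg = GanConfig(gene_count=12, latent_dim=5, gen_hidden=(8,), init_half_range=0.0)
        gen, _ = build_networks(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        y1 = gen.forward(rng.normal(size=(4, 5)))
        y2 = gen.forward(rng.normal(size=(4, 5)))
        assert np.allclose(y1, y2)

    def test_generator_init_within_half_range(self):
        cfg = GanConfig(gene_count=20, latent_dim=6, gen_hidden=(9, 9), init_half_range=0.3)
        gen, _ = build_networks(cfg, np.random.default_rng(5))
        for w in gen.weights:
            assert np.abs(w).max() <= 0.3


class TestCriticLoss:
    def test_identical_batches_zero_wasserstein(self):
        rng = np.random.default_rng(0)
        critic = DenseNet((10, 6, 1), output_activation="linear", rng=rng)
        x = rng.normal(size=(8, 10))
        loss, penalty, _, _ = critic_loss(critic, x, x, gp_lambda=0.0, rng=rng)
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert penalty == 0.0

    def test_lambda_zero_reduces_to_plain_wasserstein(self):
        rng = np.random.default_rng(1)
        critic = DenseNet((7, 5, 1), output_activation="linear", rng=rng)
        real, fake = rng.normal(size=(6, 7)), rng.normal(size=(6, 7))
        loss, _, _, _ = critic_loss(critic, real, fake, gp_lambda=0.0, rng=rng)
        expected = critic.forward(fake).mean() - critic.forward(real).mean()
        assert loss == pytest.approx(expected)

    def test_unit_norm_linear_critic_has_zero_penalty(self):
        critic = DenseNet((5, 1), output_activation="linear", init=("uniform", 0.0))
        w = np.array([3.0, 0.0, 4.0, 0.0, 0.0])[:, None]
        critic.weights[0] = w / np.linalg.norm(w)
        rng = np.random.default_rng(2)
        penalty, gw, _ = critic.gradient_penalty(rng.normal(size=(10, 5)))
        assert penalty == pytest.approx(0.0, abs=1e-24)

    def test_nan_input_rejected(self):
        rng = np.random.default_rng(3)
        critic = DenseNet((4, 3, 1), output_activation="linear", rng=rng)
        bad = np.full((2, 4), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            critic_loss(critic, bad, bad, gp_lambda=1.0, rng=rng)


class TestGradientPenaltyNumerics:
    """Analytic penalty gradients against central finite differences (1e-4)."""

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        critic = DenseNet((10, 8, 6, 1), output_activation="linear", rng=rng)
        x = rng.normal(0.5, 0.3, size=(5, 10))
        g = critic.input_gradient(x)
        h = 1e-5
        for i, j in [(0, 0), (2, 5), (4, 9)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += h
            xm[i, j] -= h
            fd = (critic.forward(xp)[i, 0] - critic.forward(xm)[i, 0]) / (2 * h)
            assert g[i, j] == pytest.approx(fd, abs=1e-4)

    def test_parameter_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        critic = DenseNet((10, 7, 5, 1), output_activation="linear", rng=rng)
        x = rng.normal(0.5, 0.3, size=(8, 10))
        _, gw, _ = critic.gradient_penalty(x)
        h = 1e-6
        for l in range(critic.n_layers):
            W = critic.weights[l]
            for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1),
                        (W.shape[0] // 2, W.shape[1] // 2)]:
                orig = W[idx]
                W[idx] = orig + h
                p1, _, _ = critic.gradient_penalty(x)
                W[idx] = orig - h
                p2, _, _ = critic.gradient_penalty(x)
                W[idx] = orig
                assert gw[l][idx] == pytest.approx((p1 - p2) / (2 * h), abs=1e-4)


class TestTraining:
    def test_smoke_run_finite_and_checkpointed(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0.5, 0.2, size=(40, 20))
        cfg = GanConfig(gene_count=20, latent_dim=6, gen_hidden=(12, 12),
                        critic_hidden=(10, 10), batch_size=16, epochs=30,
                        checkpoint_every=10, seed=0)
        _, _, trace = train(data, cfg)
        assert np.isfinite(trace.d_loss).all()
        assert trace.checkpoint_epochs == [10, 20, 30]
        assert trace.aborted_at is None

    def test_same_seed_reproduces_parameters(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0.5, 0.2, size=(30, 10))
        cfg = GanConfig(gene_count=10, latent_dim=4, gen_hidden=(8,), critic_hidden=(6,),
                        batch_size=10, epochs=10, checkpoint_every=5, seed=3)
        g1, _, _ = train(data, cfg)
        g2, _, _ = train(data, cfg)
        for a, b in zip(g1.get_parameters(), g2.get_parameters()):
            assert np.array_equal(a, b)

    def test_checkpoint_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(2)
        data = rng.normal(0.5, 0.2, size=(30, 12))
        cfg = GanConfig(gene_count=12, latent_dim=5, gen_hidden=(8,), critic_hidden=(6,),
                        batch_size=10, epochs=8, checkpoint_every=4, seed=9)
        gen, _, trace = train(data, cfg)
        save_checkpoints(trace, cfg, tmp_path)
        cfg2, checkpoints = load_checkpoints(tmp_path)
        assert cfg2 == cfg
        z = rng.normal(0.5, 0.2, size=(7, 5))
        for epoch, params in trace.checkpoints.items():
            restored = restore_generator(cfg2, checkpoints[epoch])
            assert np.array_equal(restore_generator(cfg, params).forward(z),
                                  restored.forward(z))


class TestLatentSampler:
    def test_empirical_draws_match_pool_distribution(self):
        rng = np.random.default_rng(0)
        pool = rng.gamma(2.0, 0.25, size=5000)
        sampler = LatentSampler(pool, seed=1)
        draws = sampler.sample(10000, 10).ravel()
        stat, _ = ks_2samp(draws, pool)
        assert stat < 0.02

    def test_gaussian_fallback_moments(self):
        sampler = LatentSampler(mode="gaussian", seed=2)
        z = sampler.sample(20000, 4)
        assert z.mean() == pytest.approx(0.5, abs=0.01)
        assert z.std() == pytest.approx(1 / 3.918, abs=0.01)

    def test_generate_zero_and_fixed_z(self):
        cfg = GanConfig(gene_count=9, latent_dim=4, gen_hidden=(6,))
        gen, _ = build_networks(cfg, np.random.default_rng(0))
        sampler = LatentSampler(mode="gaussian", seed=0)
        z, x = generate(gen, 0, sampler)
        assert z.shape == (0, 4) and x.shape == (0, 9)
        zfix = np.full((3, 4), 0.5)
        assert np.array_equal(gen.forward(zfix), gen.forward(zfix))


class TestGeneAssociation:
    def test_duplicate_genes_perfectly_correlated(self):
        cfg = GanConfig(gene_count=6, latent_dim=3, gen_hidden=(5,))
        gen, _ = build_networks(cfg, np.random.default_rng(0))
        gen.weights[-1][:, 1] = gen.weights[-1][:, 0]  # duplicate output unit
        corr, clusters = gene_association(gen, [f"g{i}" for i in range(6)], threshold=0.99)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        cluster_of = {g: i for i, c in enumerate(clusters) for g in c}
        assert cluster_of["g0"] == cluster_of["g1"]

    def test_threshold_one_gives_singletons(self):
        cfg = GanConfig(gene_count=8, latent_dim=3, gen_hidden=(10,))
        gen, _ = build_networks(cfg, np.random.default_rng(1))
        _, clusters = gene_association(gen, [f"g{i}" for i in range(8)], threshold=1.0)
        assert len(clusters) == 8 and all(len(c) == 1 for c in clusters)
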