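import math

import numpy as np
import pytest

from cellvae import models
from cellvae.models import (BetaTCVAE, BetaVAE, MEVAE, LossBreakdown,
                            ModelConfig, PosteriorParams, aggregate_latents,
                            beta_vae_loss, build_model, decode, encode,
                            kl_standard_normal, load_checkpoint,
                            me_vae_forward, reparameterize, save_checkpoint,
                            tc_decomposition, tcvae_loss)

SIZE = 16  # smallest allowed frame keeps these tests fast


@pytest.fixture(scope="module")
def config():
    return ModelConfig(kind="beta_vae", latent_dim=3, beta=6.0,
                       image_size=SIZE, encoder_widths=(32,),
                       decoder_widths=(32,))


@pytest.fixture(scope="module")
def model(config):
    return BetaVAE(config, seed=0)


@pytest.fixture
def images(rng):
    return rng.random((5, SIZE, SIZE))


class TestModelConfig:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="vanilla")

    def test_invalid_latent_dim(self):
        with pytest.raises(ValueError):
            ModelConfig(latent_dim=0)

    def test_mevae_encoder_count_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="me_vae", n_encoders=2)


class TestEncodeDecode:
    def test_encode_deterministic(self, model, images):
        a = encode(model, images)
        b = encode(model, images)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.logvar, b.logvar)

    def test_output_length(self, model, images):
        p = encode(model, images[0])
        assert p.mu.shape == (3,) and p.logvar.shape == (3,)

    def test_batch_order_preserved(self, model, images):
        batch = encode(model, images)
        assert batch.mu.shape == (5, 3)
        single = encode(model, images[2])
        np.testing.assert_allclose(batch.mu[2], single.mu)

    def test_shape_mismatch_rejected(self, model, rng):
        with pytest.raises(ValueError):
            encode(model, rng.random((5, 8, 8)))

    def test_decode_deterministic_and_bounded(self, model, rng):
        z = rng.normal(size=(4, 3))
        a, b = decode(model, z), decode(model, z)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (4, SIZE, SIZE)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_decode_wrong_length_rejected(self, model):
        with pytest.raises(ValueError):
            decode(model, np.zeros(5))

    def test_decode_of_tripled_aggregate_is_identity(self, model, rng):
        z = rng.normal(size=3)
        np.testing.assert_allclose(decode(model, aggregate_latents(z, z, z)),
                                   decode(model, z))


class TestReparameterize:
    def test_zero_variance_returns_mu(self):
        p = PosteriorParams(mu=np.array([1.0, -2.0]),
                            logvar=np.array([-700.0, -700.0]))
        z = reparameterize(p, np.random.default_rng(0))
        np.testing.assert_allclose(z, p.mu)

    def test_seeded_reproducibility(self):
        p = PosteriorParams(mu=np.zeros(4), logvar=np.zeros(4))
        a = reparameterize(p, np.random.default_rng(5))
        b = reparameterize(p, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_clt_bound(self):
        p = PosteriorParams(mu=np.zeros((10_000, 2)),
                            logvar=np.zeros((10_000, 2)))
        z = reparameterize(p, np.random.default_rng(1))
        assert np.all(np.abs(z.mean(axis=0)) < 3.0 / math.sqrt(10_000))


class TestKLStandardNormal:
    def test_prior_posterior_zero(self):
        p = PosteriorParams(mu=np.zeros(4), logvar=np.zeros(4))
        assert kl_standard_normal(p) == pytest.approx(0.0)

    def test_unit_mean_shift(self):
        p = PosteriorParams(mu=np.array([1.0]), logvar=np.array([0.0]))
        assert kl_standard_normal(p) == pytest.approx(0.5)

    def test_variance_four(self):
        p = PosteriorParams(mu=np.array([0.0]), logvar=np.array([math.log(4)]))
        assert kl_standard_normal(p) == pytest.approx(
            0.5 * (4 - math.log(4) - 1), abs=1e-10)
        assert kl_standard_normal(p) == pytest.approx(0.80685, abs=1e-5)

    def test_nonnegative_random(self, rng):
        p = PosteriorParams(mu=rng.normal(size=(100, 6)),
                            logvar=rng.normal(size=(100, 6)))
        assert np.all(kl_standard_normal(p) >= 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            PosteriorParams(mu=np.array([np.inf]), logvar=np.array([0.0]))


class TestBetaVAELoss:
    def test_perfect_reconstruction_prior_posterior(self, rng):
        x = rng.random((2, SIZE, SIZE))
        p = PosteriorParams(mu=np.zeros((2, 3)), logvar=np.zeros((2, 3)))
        loss = beta_vae_loss(x, x.copy(), p, beta=6.0)
        assert loss.total == pytest.approx(0.0)

    def test_beta_one_is_plain_elbo(self, rng):
        x = rng.random((2, SIZE, SIZE))
        recon = rng.random((2, SIZE, SIZE))
        p = PosteriorParams(mu=rng.normal(size=(2, 3)),
                            logvar=rng.normal(size=(2, 3)))
        loss = beta_vae_loss(x, recon, p, beta=1.0)
        assert loss.total == pytest.approx(loss.reconstruction + loss.kl)

    def test_linearity_in_beta(self, rng):
        x = rng.random((2, SIZE, SIZE))
        recon = rng.random((2, SIZE, SIZE))
        p = PosteriorParams(mu=rng.normal(size=(2, 3)),
                            logvar=rng.normal(size=(2, 3)))
        loss = beta_vae_loss(x, recon, p, beta=6.0)
        assert loss.total == pytest.approx(
            loss.reconstruction + 6.0 * loss.kl)


class TestTCVAE:
    def test_tc_zero_for_single_dimension(self, rng):
        mu = rng.normal(size=(16, 1))
        logvar = rng.normal(scale=0.2, size=(16, 1))
        z = mu + np.exp(logvar / 2) * rng.standard_normal((16, 1))
        _, tc, _ = tc_decomposition(mu, logvar, z, dataset_size=100)
        assert tc.item() == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_identity_unit_weights(self):
        # oracle: analytic batch-mean KL; identity holds in expectation
        rng = np.random.default_rng(2)
        m, latent = 256, 2
        mu = rng.normal(size=(m, latent))
        logvar = rng.normal(scale=0.3, size=(m, latent))
        analytic = kl_standard_normal(
            PosteriorParams(mu, logvar)).mean()
        estimates = []
        for _ in range(16):
            z = mu + np.exp(logvar / 2) * rng.standard_normal((m, latent))
            mi, tc, dw = tc_decomposition(mu, logvar, z, dataset_size=m)
            estimates.append(mi.item() + tc.item() + dw.item())
        assert abs(np.mean(estimates) - analytic) < 0.05

    def test_null_all_terms_zero(self):
        rng = np.random.default_rng(3)
        m, latent = 256, 2
        mu, logvar = np.zeros((m, latent)), np.zeros((m, latent))
        z = rng.standard_normal((m, latent))
        mi, tc, dw = tc_decomposition(mu, logvar, z, dataset_size=m)
        for term in (mi, tc, dw):
            assert abs(term.item()) < 0.05

    def test_batch_of_one_rejected(self, rng):
        with pytest.raises(ValueError):
            tc_decomposition(rng.normal(size=(1, 2)), rng.normal(size=(1, 2)),
                             rng.normal(size=(1, 2)), dataset_size=10)

    def test_tcvae_loss_weighted_combination(self, rng):
        x = rng.random((8, SIZE, SIZE))
        recon = rng.random((8, SIZE, SIZE))
        p = PosteriorParams(mu=rng.normal(size=(8, 3)),
                            logvar=rng.normal(scale=0.2, size=(8, 3)))
        z = reparameterize(p, rng)
        loss = tcvae_loss(x, recon, p, z, alpha=2.0, beta=6.0, gamma=0.5,
                          dataset_size=100)
        assert loss.total == pytest.approx(
            loss.reconstruction + 2.0 * loss.mi + 6.0 * loss.tc
            + 0.5 * loss.dimwise_kl)

    def test_beta_vae_and_tcvae_agree_at_unit_weights(self):
        # identical batch and weights: totals agree within estimator noise
        rng = np.random.default_rng(4)
        x = rng.random((256, SIZE, SIZE))
        recon = rng.random((256, SIZE, SIZE))
        mu = rng.normal(scale=0.7, size=(256, 3))
        logvar = rng.normal(scale=0.2, size=(256, 3))
        p = PosteriorParams(mu, logvar)
        totals = []
        for _ in range(8):
            z = reparameterize(p, rng)
            totals.append(tcvae_loss(x, recon, p, z, 1.0, 1.0, 1.0,
                                     dataset_size=256).total)
        bv = beta_vae_loss(x, recon, p, beta=1.0).total
        assert abs(np.mean(totals) - bv) < 0.1


class TestAggregateLatents:
    def test_arithmetic_mean(self):
        out = aggregate_latents([1.0, 1.0], [2.0, 2.0], [3.0, 3.0])
        np.testing.assert_allclose(out, [2.0, 2.0])

    def test_idempotent_on_equal_inputs(self, rng):
        z = rng.normal(size=6)
        np.testing.assert_allclose(aggregate_latents(z, z, z), z)

    def test_permutation_invariant(self, rng):
        z1, z2, z3 = rng.normal(size=(3, 4))
        np.testing.assert_allclose(aggregate_latents(z1, z2, z3),
                                   aggregate_latents(z3, z1, z2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_latents(np.zeros(3), np.zeros(4), np.zeros(3))


@pytest.fixture(scope="module")
def me_model():
    config = ModelConfig(kind="me_vae", latent_dim=3, beta=6.0,
                         image_size=SIZE, encoder_widths=(32,),
                         decoder_widths=(32,))
    return MEVAE(config, seed=0)


class TestMEVAE:
    def test_aggregated_mu_is_mean_of_encoder_mus(self, me_model, images):
        views = [images, images[:, ::-1].copy(), images[:, :, ::-1].copy()]
        p = me_model.encode_views(*views)
        mus = []
        for enc, v in zip(me_model.encoders, views):
            flat = v.reshape(v.shape[0], -1)
            from cellvae.autodiff import Tensor

            mu, _ = enc(Tensor(flat))
            mus.append(mu.data)
        np.testing.assert_allclose(p.mu, aggregate_latents(*mus))

    def test_weight_tied_identical_views_reduce_to_beta_vae(self, images):
        config = ModelConfig(kind="me_vae", latent_dim=3, beta=6.0,
                             image_size=SIZE, encoder_widths=(32,),
                             decoder_widths=(32,))
        me = MEVAE(config, seed=0)
        # tie all encoders to the first one's weights
        for enc in me.encoders[1:]:
            for p_dst, p_src in zip(enc.parameters(),
                                    me.encoders[0].parameters()):
                p_dst.data = p_src.data.copy()
        bv_config = ModelConfig(kind="beta_vae", latent_dim=3, beta=6.0,
                                image_size=SIZE, encoder_widths=(32,),
                                decoder_widths=(32,))
        bv = BetaVAE(bv_config, seed=1)
        for p_dst, p_src in zip(bv.encoder.parameters(),
                                me.encoders[0].parameters()):
            p_dst.data = p_src.data.copy()
        for p_dst, p_src in zip(bv.decoder.parameters(),
                                me.decoder.parameters()):
            p_dst.data = p_src.data.copy()
        recon, p, loss = me_vae_forward(me, images, images.copy(),
                                        images.copy())
        p_bv = bv.encode(images)
        np.testing.assert_allclose(p.mu, p_bv.mu)
        np.testing.assert_allclose(p.logvar, p_bv.logvar)
        np.testing.assert_allclose(recon, bv.decode(p_bv.mu))
        ref = beta_vae_loss(images, bv.decode(p_bv.mu), p_bv, beta=6.0)
        assert loss.total == pytest.approx(ref.total)

    def test_forward_components_finite(self, me_model, images, rng):
        recon, p, loss = me_vae_forward(
            me_model, images, images[:, ::-1].copy(),
            images[:, :, ::-1].copy(), rng=rng)
        assert loss.reconstruction >= 0
        assert np.isfinite([loss.total, loss.reconstruction, loss.kl]).all()
        assert recon.shape == images.shape

    def test_view_shape_mismatch_rejected(self, me_model, images):
        with pytest.raises(ValueError):
            me_model.encode_views(images, images[:2], images)


class TestCheckpoint:
    def test_roundtrip(self, model, images, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, seed=0)
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.encode(images).mu,
                                      model.encode(images).mu)
        assert loaded.config == model.config

    def test_roundtrip_all_kinds(self, tmp_path, rng):
        for kind in ("beta_vae", "beta_tcvae", "me_vae"):
            config = ModelConfig(kind=kind, latent_dim=2, image_size=SIZE,
                                 encoder_widths=(16,), decoder_widths=(16,))
            m = build_model(config, seed=3)
            save_checkpoint(m, tmp_path / f"{kind}.npz")
            loaded = load_checkpoint(tmp_path / f"{kind}.npz")
            z = rng.normal(size=(2, 2))
            np.testing.assert_array_equal(loaded.decode(z), m.decode(z))
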