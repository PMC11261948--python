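"""beta-VAE: loss closed forms, training behavior, latent usefulness."""

import numpy as np
import pytest

from conftest import blob_images
from hfomorph.vae import (
    VaeConfig,
    TrainedVae,
    encode_latent,
    init_params,
    reconstruction_error,
    train_vae,
    vae_forward,
    vae_loss,
)


def tiny_model(seed=0, **kw) -> TrainedVae:
    cfg = VaeConfig.small(width=32, epochs=2, **kw)
    return TrainedVae(config=cfg, params=init_params(cfg, seed))


class TestLossClosedForms:
    def test_kl_zero_at_prior(self):
        z = np.zeros((1, 8))
        img = np.zeros((1, 64 * 64))
        loss = vae_loss(img, img, z, z, beta=1.0, criterion="mse")
        assert abs(loss.kl) < 1e-9

    def test_kl_half_for_unit_mean(self):
        mu = np.zeros((1, 8))
        mu[0, 0] = 1.0
        img = np.zeros((1, 64 * 64))
        loss = vae_loss(img, img, mu, np.zeros((1, 8)), beta=1.0, criterion="mse")
        assert abs(loss.kl - 0.5) < 1e-9

    def test_perfect_reconstruction_mse(self):
        rng = np.random.default_rng(0)
        img = rng.random((2, 64 * 64))
        mu = rng.standard_normal((2, 8))
        loss = vae_loss(img, img, mu, np.zeros((2, 8)), beta=0.1, criterion="mse")
        assert loss.recon == 0.0
        assert abs(loss.total - 0.1 * loss.kl) < 1e-12

    def test_negative_beta_rejected(self):
        img = np.zeros((1, 64 * 64))
        with pytest.raises(ValueError):
            vae_loss(img, img, np.zeros((1, 8)), np.zeros((1, 8)), beta=-0.1)

    def test_kl_matches_monte_carlo(self):
        """Closed form vs brute-force MC estimate of KL(q || N(0,I)) within 2%."""
        rng = np.random.default_rng(1)
        mu = rng.uniform(-1, 1, (1, 8))
        logvar = rng.uniform(-0.5, 0.5, (1, 8))
        img = np.zeros((1, 64 * 64))
        analytic = vae_loss(img, img, mu, logvar, beta=1.0, criterion="mse").kl

        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * rng.standard_normal((200_000, 8))
        log_q = -0.5 * np.sum(((z - mu) / sigma) ** 2 + np.log(2 * np.pi) + logvar, axis=1)
        log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
        mc = float(np.mean(log_q - log_p))
        assert abs(analytic - mc) / abs(mc) < 0.02

    def test_beta_zero_is_plain_autoencoder(self):
        rng = np.random.default_rng(2)
        r, t = rng.random((3, 64 * 64)), rng.random((3, 64 * 64))
        loss = vae_loss(r, t, rng.standard_normal((3, 8)), rng.standard_normal((3, 8)),
                        beta=0.0, criterion="mse")
        assert loss.total == loss.recon


class TestForward:
    def test_shapes_and_determinism(self):
        model = tiny_model()
        img = np.random.default_rng(3).random((64, 64))
        recon, mu, logvar = vae_forward(model, img)
        assert recon.shape == (64, 64)
        assert mu.shape == (8,)
        _, mu2, _ = vae_forward(model, img)
        np.testing.assert_array_equal(mu, mu2)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            vae_forward(tiny_model(), np.zeros((32, 32)))

    def test_untrained_model_finite_loss(self):
        model = tiny_model()
        img = np.random.default_rng(4).random((1, 64, 64))
        recon, mu, logvar = vae_forward(model, img)
        loss = vae_loss(
            recon.reshape(1, -1), img.reshape(1, -1), mu, logvar, beta=0.1, criterion="mse"
        )
        assert np.isfinite(loss.total)

    def test_reconstruction_error_nonnegative(self):
        model = tiny_model()
        imgs = np.random.default_rng(5).random((10, 64, 64))
        assert (reconstruction_error(model, imgs) >= 0).all()


class TestTraining:
    def test_validation_loss_improves(self):
        imgs = blob_images(200, (10, 20), seed=0)
        subjects = np.repeat([f"s{i}" for i in range(5)], 40)
        cfg = VaeConfig.small(width=32, epochs=2)
        model = train_vae(imgs, subjects, cfg, seed=0)
        hist = model.history
        assert hist["val_loss"][hist["best_epoch"]] <= hist["val_loss"][0]

    def test_reproducible_given_seed(self):
        imgs = blob_images(100, (10, 20), seed=1)
        subjects = np.repeat(["a", "b", "c", "d"], 25)
        cfg = VaeConfig.small(width=32, epochs=3)
        m1 = train_vae(imgs, subjects, cfg, seed=5)
        m2 = train_vae(imgs, subjects, cfg, seed=5)
        assert m1.history["best_epoch"] == m2.history["best_epoch"]
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_per_subject_cap_enforced(self):
        imgs = blob_images(120, (10, 20), seed=2)
        subjects = np.array(["big"] * 100 + ["val"] * 20)
        cfg = VaeConfig.small(width=32, epochs=2, per_subject_cap=10)
        model = train_vae(imgs, subjects, cfg, seed=0, val_subjects={"val"})
        for counts in model.history["sampled_per_subject"]:
            assert counts["big"] == 10

    def test_empty_validation_rejected(self):
        imgs = blob_images(40, (10, 20), seed=3)
        with pytest.raises(ValueError):
            train_vae(imgs, ["only"] * 40, VaeConfig.small(width=32, epochs=1),
                      seed=0, val_subjects=set())

    def test_trained_model_fits_its_class_better_than_noise(self):
        """Reconstruction error is lower on in-distribution images than on
        structureless noise, averaged over 50 of each."""
        imgs = blob_images(150, (15, 25), seed=4)
        subjects = np.repeat(["a", "b", "c"], 50)
        model = train_vae(imgs, subjects, VaeConfig.small(width=64, epochs=30), seed=0)
        in_dist = reconstruction_error(model, imgs[:50]).mean()
        noise = np.random.default_rng(6).random((50, 64, 64))
        assert in_dist < reconstruction_error(model, noise).mean()

    def test_flip_changes_encoding(self):
        imgs = blob_images(100, (10, 30), seed=5)
        # asymmetric in time: shift column profile
        imgs = np.concatenate([imgs[:, :, 20:], imgs[:, :, :20]], axis=2)
        model = train_vae(imgs, np.repeat(["a", "b"], 50),
                          VaeConfig.small(width=64, epochs=20), seed=0)
        code = encode_latent(model, imgs[0]).mu
        flipped = encode_latent(model, imgs[0][:, ::-1]).mu
        assert not np.allclose(code, flipped)

    def test_linear_probe_separates_two_classes(self):
        """Latent smoke test: two well-separated synthetic classes are
        linearly separable from the trained posterior means (>=90%)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        a = blob_images(100, (8, 16), seed=7)
        b = blob_images(100, (44, 54), seed=8)
        imgs = np.concatenate([a, b])
        labels = np.array([0] * 100 + [1] * 100)
        subjects = np.tile(np.repeat(["s0", "s1", "s2", "s3"], 25), 2)
        model = train_vae(imgs, subjects, VaeConfig.small(width=64, epochs=15), seed=0)
        mu, _ = model.encode(imgs)
        acc = cross_val_score(LogisticRegression(max_iter=1000), mu, labels, cv=3).mean()
        assert acc >= 0.90
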