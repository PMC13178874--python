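"""VAE backbone: construction, loss terms and their oracles."""

import numpy as np
import pytest
from scipy import integrate

from fundusvae import nn
from fundusvae.vae import (
    ConvVAE,
    LossBreakdown,
    StreamConfig,
    build_stream,
    kl_divergence,
    reparameterize,
    sharpness_loss,
    vae_loss,
)


def _cfg(**kw):
    base = dict(stream="background", latent_dim=8, resolution=32, base_width=4, seed=3)
    base.update(kw)
    return StreamConfig(**base)


class TestBuildStream:
    def test_seeded_build_determinism(self):
        a, b = build_stream(_cfg()), build_stream(_cfg())
        assert a.param_checksum() == b.param_checksum()
        c = build_stream(_cfg(seed=4))
        assert a.param_checksum() != c.param_checksum()

    def test_conv_parameters_independent_of_latent_dim(self):
        small = build_stream(_cfg(latent_dim=8))
        large = build_stream(_cfg(latent_dim=256))
        assert small.conv_parameter_count() == large.conv_parameter_count()
        assert large.n_parameters() > small.n_parameters()

    def test_dropout_sites(self):
        vessel = build_stream(_cfg(stream="vessel", encoder_dropout=0.3, input_channels=1))
        assert vessel.dropout_sites() == 5
        assert build_stream(_cfg()).dropout_sites() == 0

    def test_resolution_must_be_divisible(self):
        with pytest.raises(ValueError):
            StreamConfig(stream="background", latent_dim=8, resolution=48)

    def test_non_vessel_streams_reject_vessel_extras(self):
        with pytest.raises(ValueError):
            StreamConfig(stream="background", sharpness_weight=0.5)
        with pytest.raises(ValueError):
            StreamConfig(stream="disc_cup", encoder_dropout=0.2)

    def test_forward_output_shape_matches_input(self):
        for stream, c in [("background", 3), ("vessel", 1), ("monolithic", 3)]:
            for d in (8, 16):
                cfg = _cfg(stream=stream, latent_dim=d, input_channels=c,
                           encoder_dropout=0.0 if stream == "vessel" else -1.0)
                model = build_stream(cfg)
                x = np.random.default_rng(0).random((2, c, 32, 32)).astype(np.float32)
                out = model.forward(x, rng=np.random.default_rng(1), training=True)
                assert out["xhat"].shape == x.shape
                assert out["mu"].shape == (2, d)


class TestReparameterize:
    def test_degenerate_variance_returns_mu(self):
        mu = np.random.default_rng(0).random((4, 6))
        z, _ = reparameterize(mu, np.full_like(mu, -50.0), np.random.default_rng(1))
        np.testing.assert_allclose(z, mu, atol=1e-10)

    def test_fixed_rng_state_repeats(self):
        mu, lv = np.zeros((3, 5)), np.zeros((3, 5))
        z1, _ = reparameterize(mu, lv, np.random.default_rng(9))
        z2, _ = reparameterize(mu, lv, np.random.default_rng(9))
        np.testing.assert_array_equal(z1, z2)

    def test_standard_normal_moments(self):
        mu = np.zeros((100_000, 4))
        z, _ = reparameterize(mu, np.zeros_like(mu), np.random.default_rng(5))
        assert np.abs(z.mean(axis=0)).max() < 0.02
        assert np.all((z.var(axis=0) > 0.95) & (z.var(axis=0) < 1.05))


class TestKLDivergence:
    def test_prior_matches_posterior(self):
        assert kl_divergence(np.zeros((2, 8)), np.zeros((2, 8))) == 0.0

    def test_closed_form_mean_shift(self):
        assert kl_divergence(np.ones((1, 4)), np.zeros((1, 4))) == pytest.approx(2.0)

    def test_matches_gaussian_quadrature(self):
        """KL(N(mu, s^2) || N(0,1)) by numerical integration, per dimension."""
        rng = np.random.default_rng(2)
        mu = rng.normal(0, 1, size=(1, 16))
        logvar = rng.normal(0, 0.5, size=(1, 16))
        total = 0.0
        for m, lv in zip(mu[0], logvar[0]):
            s = np.exp(lv / 2)

            def integrand(x):
                q = np.exp(-((x - m) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
                p = np.exp(-(x**2) / 2) / np.sqrt(2 * np.pi)
                return np.where(q > 0, q * np.log(q / p), 0.0)

            val, _ = integrate.quad(integrand, m - 12 * s, m + 12 * s, limit=200)
            total += val
        assert kl_divergence(mu, logvar) == pytest.approx(total, abs=1e-6)


class TestSharpnessLoss:
    def test_identical_images_zero(self):
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        assert sharpness_loss(x, x) == 0.0

    def test_constant_images_zero(self):
        x = np.full((1, 1, 8, 8), 0.2)
        y = np.full((1, 1, 8, 8), 0.9)
        assert sharpness_loss(x, y) == pytest.approx(0.0, abs=1e-10)

    def test_blur_penalized_more_than_matched_mse_noise(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        x = rng.random((1, 1, 24, 24))
        blurred = gaussian_filter(x[0, 0], sigma=1.5)[None, None]
        mse_blur = float(np.mean((x - blurred) ** 2))
        noise = rng.standard_normal(x.shape)
        noise *= np.sqrt(mse_blur / np.mean(noise**2))
        noisy = x + noise
        assert np.mean((x - noisy) ** 2) == pytest.approx(mse_blur, rel=1e-9)
        assert sharpness_loss(x, blurred) > 0
        assert sharpness_loss(x, blurred) > sharpness_loss(x, noisy)


class TestVaeLoss:
    def test_perfect_reconstruction_zero_total(self):
        x = np.random.default_rng(0).random((2, 3, 8, 8))
        loss = vae_loss(x, x, np.zeros((2, 4)), np.zeros((2, 4)), _cfg(latent_dim=4))
        assert loss.total == 0.0

    def test_beta_zero_ablation(self):
        rng = np.random.default_rng(1)
        x, xh = rng.random((2, 1, 8, 8)), rng.random((2, 1, 8, 8))
        mu, lv = rng.normal(size=(2, 4)), rng.normal(size=(2, 4))
        cfg = _cfg(stream="vessel", input_channels=1, latent_dim=4,
                   kl_weight=0.0, sharpness_weight=0.7, encoder_dropout=0.0)
        loss = vae_loss(x, xh, mu, lv, cfg)
        assert loss.total == pytest.approx(loss.mse + 0.7 * loss.sharpness, rel=1e-12)

    def test_term_sum_oracle(self):
        rng = np.random.default_rng(2)
        x, xh = rng.random((3, 3, 16, 16)), rng.random((3, 3, 16, 16))
        mu, lv = rng.normal(size=(3, 6)), rng.normal(size=(3, 6))
        cfg = _cfg(latent_dim=6, kl_weight=0.3)
        loss = vae_loss(x, xh, mu, lv, cfg)
        mse = float(np.mean((x - xh) ** 2))
        kl = kl_divergence(mu, lv)
        assert loss.total == pytest.approx(mse + 0.3 * kl, abs=1e-8)
        assert loss.sharpness == 0.0


def test_streams_share_no_parameters():
    models = [build_stream(_cfg(seed=s)) for s in (1, 2)]
    ids = [
        {id(p) for p in m.named_parameters().values()} for m in models
    ]
    assert ids[0] & ids[1] == set()


def test_overfit_step_decreases_mse():
    """Gradient flow sanity: a few optimizer steps on one repeated image
    strictly decrease the reconstruction error with beta = 0."""
    cfg = _cfg(kl_weight=0.0, base_width=4, latent_dim=8)
    model = build_stream(cfg)
    x = np.tile(np.random.default_rng(0).random((1, 3, 32, 32)), (4, 1, 1, 1)).astype(np.float32)
    opt = nn.Adam(model.param_slots(), lr=1e-3)
    first = model.train_step_grads(x, np.random.default_rng(1)).mse
    opt.step()
    losses = [first]
    for i in range(5):
        losses.append(model.train_step_grads(x, np.random.default_rng(1)).mse)
        opt.step()
    assert losses[-1] < losses[0]


def test_checkpoint_round_trip(tmp_path):
    model = build_stream(_cfg(seed=11))
    x = np.random.default_rng(0).random((3, 3, 32, 32)).astype(np.float32)
    model.forward(x, rng=None, training=True)  # populate running stats
    mu0, lv0 = model.encode(x)
    path = tmp_path / "model.npz"
    model.save(path)
    clone = ConvVAE.load(path)
    mu1, lv1 = clone.encode(x)
    np.testing.assert_array_equal(mu0, mu1)
    np.testing.assert_array_equal(lv0, lv1)


def test_checkpoint_dimension_mismatch_rejected(tmp_path):
    model = build_stream(_cfg(latent_dim=8))
    path = tmp_path / "model.npz"
    model.save(path)
    import json

    meta = json.loads(path.with_suffix(".json").read_text())
    meta["config"]["latent_dim"] = 16
    path.with_suffix(".json").write_text(json.dumps(meta))
    with pytest.raises(ValueError, match="mismatch"):
        ConvVAE.load(path)
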