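"""Convolutional VAE backbone shared by all four streams.

One architecture serves the three structure-specific streams (background,
disc/cup, vessel) and the monolithic baseline: a 5-block strided
convolutional encoder (each block: convolution, batch normalization,
leaky-ReLU; the vessel stream adds dropout after every block to avoid
overfitting sparse binary masks), two linear heads producing the posterior
mean and log-variance, and a mirrored 5-block upsampling decoder ending in a
sigmoid so reconstructions live in [0, 1].

The training objective is

    total = MSE(x, x_hat) + beta * KL(q(z|x) || N(0, I)) + lambda_s * sharpness

where the sharpness term (vessel stream only) is the mean squared difference
between Sobel gradient-magnitude maps of input and reconstruction — it
penalizes blurry edges that plain MSE tolerates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "GRID_DIMS",
    "DEFAULT_LATENT_DIMS",
    "StreamConfig",
    "LossBreakdown",
    "ConvVAE",
    "build_stream",
    "reparameterize",
    "kl_divergence",
    "sharpness_loss",
    "sobel_magnitude",
    "vae_loss",
]

GRID_DIMS = (8, 16, 32, 64, 128, 256)
DEFAULT_LATENT_DIMS = {"background": 64, "disc_cup": 64, "vessel": 128, "monolithic": 256}
N_BLOCKS = 5

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T
_EPS = 1e-12


@dataclass
class StreamConfig:
    stream: str
    latent_dim: int = 0  # 0 -> stream default
    input_channels: int = 0  # 0 -> stream default (1 for vessel, 3 otherwise)
    resolution: int = 32
    base_width: int = 16
    kl_weight: float = 1.0
    sharpness_weight: float = -1.0  # -1 -> stream default (0.5 vessel, 0 otherwise)
    encoder_dropout: float = -1.0  # -1 -> stream default (0.1 vessel, 0 otherwise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stream not in DEFAULT_LATENT_DIMS:
            raise ValueError(f"unknown stream {self.stream!r}")
        if self.latent_dim == 0:
            self.latent_dim = DEFAULT_LATENT_DIMS[self.stream]
        if self.input_channels == 0:
            self.input_channels = 1 if self.stream == "vessel" else 3
        if self.sharpness_weight < 0:
            self.sharpness_weight = 0.5 if self.stream == "vessel" else 0.0
        if self.encoder_dropout < 0:
            self.encoder_dropout = 0.1 if self.stream == "vessel" else 0.0
        if self.stream != "vessel" and (self.sharpness_weight != 0 or self.encoder_dropout != 0):
            raise ValueError("sharpness loss and encoder dropout are vessel-stream only")
        if self.resolution % (2**N_BLOCKS) != 0:
            raise ValueError(
                f"resolution {self.resolution} must be divisible by 2^{N_BLOCKS}"
            )
        if not (0.0 <= self.encoder_dropout < 1.0):
            raise ValueError("encoder_dropout must lie in [0, 1)")
        if self.latent_dim < 1 or self.kl_weight < 0 or self.sharpness_weight < 0:
            raise ValueError("invalid StreamConfig")


@dataclass
class LossBreakdown:
    total: float
    mse: float
    kl: float
    sharpness: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def reparameterize(mu: np.ndarray, logvar: np.ndarray, rng: np.random.Generator):
    """z = mu + exp(logvar/2) * eps with eps ~ N(0, I); returns (z, eps)."""
    eps = rng.standard_normal(mu.shape).astype(mu.dtype)
    return mu + np.exp(0.5 * logvar) * eps, eps


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(q || N(0,I)) = 0.5 sum_i (mu_i^2 + e^logvar_i - 1 - logvar_i), batch-averaged."""
    per_sample = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=tuple(range(1, mu.ndim)))
    return float(per_sample.mean())


def sobel_magnitude(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel Sobel gradient magnitude of an (N,C,H,W) batch (zero
    padding); returns (magnitude, gx, gy)."""
    from scipy.ndimage import correlate

    gx = np.empty_like(x, dtype=np.float64)
    gy = np.empty_like(x, dtype=np.float64)
    for n in range(x.shape[0]):
        for c in range(x.shape[1]):
            gx[n, c] = correlate(x[n, c].astype(np.float64), _SOBEL_X, mode="constant")
            gy[n, c] = correlate(x[n, c].astype(np.float64), _SOBEL_Y, mode="constant")
    return np.sqrt(gx**2 + gy**2 + _EPS), gx, gy


def sharpness_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared difference of Sobel gradient-magnitude maps.

    Averaged over the interior (valid) region so image borders contribute no
    phantom gradients; constant images therefore score exactly zero.
    """
    mx, _, _ = sobel_magnitude(np.asarray(x))
    mh, _, _ = sobel_magnitude(np.asarray(xhat))
    return float(np.mean((mx - mh)[..., 1:-1, 1:-1] ** 2))


def _sharpness_grad(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """d sharpness / d xhat, via the adjoint (convolution) of the Sobel operator."""
    from scipy.ndimage import convolve

    mx, _, _ = sobel_magnitude(x)
    mh, gx, gy = sobel_magnitude(xhat)
    interior = np.zeros_like(mx)
    interior[..., 1:-1, 1:-1] = 1.0
    dm = 2.0 * (mh - mx) * interior / interior.sum()
    dgx = dm * gx / mh
    dgy = dm * gy / mh
    out = np.zeros_like(xhat, dtype=np.float64)
    for n in range(x.shape[0]):
        for c in range(x.shape[1]):
            out[n, c] = convolve(dgx[n, c], _SOBEL_X, mode="constant") + convolve(
                dgy[n, c], _SOBEL_Y, mode="constant"
            )
    return out


def vae_loss(x, xhat, mu, logvar, config: StreamConfig) -> LossBreakdown:
    mse = float(np.mean((np.asarray(xhat, dtype=np.float64) - np.asarray(x, dtype=np.float64)) ** 2))
    kl = kl_divergence(mu, logvar)
    sharp = sharpness_loss(x, xhat) if config.sharpness_weight > 0 else 0.0
    total = mse + config.kl_weight * kl + config.sharpness_weight * sharp
    return LossBreakdown(total=total, mse=mse, kl=kl, sharpness=sharp)


class ConvVAE:
    """5-block convolutional VAE with hand-written backward pass."""

    def __init__(self, config: StreamConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        w, c_in = config.base_width, config.input_channels
        widths = [w * 2**i for i in range(N_BLOCKS)]
        self.bottleneck = config.resolution // 2**N_BLOCKS
        flat = widths[-1] * self.bottleneck**2

        enc: list[nn.Layer] = []
        cin = c_in
        for cw in widths:
            enc += [nn.Conv2d(cin, cw, k=3, stride=2, pad=1, rng=rng), nn.BatchNorm2d(cw), nn.LeakyReLU()]
            if config.encoder_dropout > 0:
                enc.append(nn.Dropout(config.encoder_dropout, self._dropout_rng))
            cin = cw
        enc.append(nn.Flatten())
        self.encoder = nn.Sequential(*enc)
        self.mu_head = nn.Linear(flat, config.latent_dim, rng=rng)
        self.logvar_head = nn.Linear(flat, config.latent_dim, rng=rng)

        dec: list[nn.Layer] = [
            nn.Linear(config.latent_dim, flat, rng=rng),
            nn.Reshape((widths[-1], self.bottleneck, self.bottleneck)),
        ]
        couts = widths[-2::-1] + [c_in]
        cin = widths[-1]
        for i, cw in enumerate(couts):
            dec.append(nn.Upsample2x())
            dec.append(nn.Conv2d(cin, cw, k=3, stride=1, pad=1, rng=rng))
            if i < len(couts) - 1:
                dec += [nn.BatchNorm2d(cw), nn.LeakyReLU()]
            cin = cw
        dec.append(nn.Sigmoid())
        self.decoder = nn.Sequential(*dec)

    # -- parameter plumbing ------------------------------------------------
    def param_slots(self):
        for seq, tag in ((self.encoder, "enc"), (self.decoder, "dec")):
            for _, layer, name in seq.named_params():
                yield layer, name
        for head in (self.mu_head, self.logvar_head):
            for name in head.params:
                yield head, name

    def named_parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for seq, tag in ((self.encoder, "enc"), (self.decoder, "dec")):
            for label, layer, name in seq.named_params(prefix=f"{tag}."):
                out[f"{label}"] = layer.params[name]
        out["mu_head.W"], out["mu_head.b"] = self.mu_head.params["W"], self.mu_head.params["b"]
        out["logvar_head.W"] = self.logvar_head.params["W"]
        out["logvar_head.b"] = self.logvar_head.params["b"]
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.named_parameters().values())

    def conv_parameter_count(self) -> int:
        """Parameters in convolutional layers only (independent of latent_dim)."""
        total = 0
        for seq in (self.encoder, self.decoder):
            for layer in seq.layers:
                if isinstance(layer, nn.Conv2d):
                    total += sum(p.size for p in layer.params.values())
        return total

    def param_checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.named_parameters()[name]).tobytes())
        return h.hexdigest()

    def dropout_sites(self) -> int:
        return sum(isinstance(layer, nn.Dropout) for layer in self.encoder.layers)

    # -- forward / backward ------------------------------------------------
    def encode(self, x: np.ndarray, training: bool = False):
        flat = self.encoder.forward(np.asarray(x, dtype=np.float32), training=training)
        mu = self.mu_head.forward(flat, training=training)
        logvar = np.clip(self.logvar_head.forward(flat, training=training), -12.0, 12.0)
        return mu, logvar

    def decode(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decoder.forward(z.astype(np.float32), training=training)

    def forward(self, x, rng: np.random.Generator | None = None, training: bool = False):
        mu, logvar = self.encode(x, training=training)
        if rng is None:
            z, eps = mu, None
        else:
            z, eps = reparameterize(mu, logvar, rng)
        xhat = self.decode(z, training=training)
        return {"xhat": xhat, "mu": mu, "logvar": logvar, "z": z, "eps": eps}

    def train_step_grads(self, x: np.ndarray, rng: np.random.Generator) -> LossBreakdown:
        """One forward + backward pass; gradients are left on the layers."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        out = self.forward(x, rng=rng, training=True)
        xhat, mu, logvar, z, eps = out["xhat"], out["mu"], out["logvar"], out["z"], out["eps"]
        loss = vae_loss(x, xhat, mu, logvar, cfg)

        g_xhat = 2.0 * (xhat.astype(np.float64) - x) / xhat.size
        if cfg.sharpness_weight > 0:
            g_xhat = g_xhat + cfg.sharpness_weight * _sharpness_grad(x, xhat)
        g_z = self.decoder.backward(g_xhat.astype(np.float32))

        n = mu.shape[0]
        g_mu = g_z + cfg.kl_weight * mu / n
        g_logvar = g_z * 0.5 * (z - mu) + cfg.kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n
        g_flat = self.mu_head.backward(g_mu.astype(np.float32)) + self.logvar_head.backward(
            g_logvar.astype(np.float32)
        )
        self.encoder.backward(g_flat)
        return loss

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        params = self.named_parameters()
        running = {}
        for tag, seq in (("enc", self.encoder), ("dec", self.decoder)):
            for i, layer in enumerate(seq.layers):
                if isinstance(layer, nn.BatchNorm2d):
                    running[f"{tag}.{i}.running_mean"] = layer.running_mean
                    running[f"{tag}.{i}.running_var"] = layer.running_var
        np.savez_compressed(path, **params, **running)
        meta = {"config": asdict(self.config), "param_checksum": self.param_checksum()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "ConvVAE":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(StreamConfig(**meta["config"]))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            own = model.named_parameters()
            for name, arr in own.items():
                if name not in data or data[name].shape != arr.shape:
                    raise ValueError(f"checkpoint mismatch for parameter {name!r}")
                arr[...] = data[name]
            for tag, seq in (("enc", model.encoder), ("dec", model.decoder)):
                for i, layer in enumerate(seq.layers):
                    if isinstance(layer, nn.BatchNorm2d):
                        layer.running_mean = data[f"{tag}.{i}.running_mean"]
                        layer.running_var = data[f"{tag}.{i}.running_var"]
        return model


def build_stream(config: StreamConfig) -> ConvVAE:
    """Construct one stream's VAE; parameter init is deterministic given config.seed."""
    return ConvVAE(config)
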