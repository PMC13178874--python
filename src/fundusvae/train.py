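"""Stream training (Model/Results API) and latent-dimension selection.

``StreamVAE`` holds the data and configuration of one stream; ``fit()``
optimizes the VAE objective with Adam and returns ``StreamVAEResults``
carrying the epoch history, the best (minimum validation loss) parameters
and convenience methods for encoding and decoding. Each stream is optimized
separately; models never share parameters.

Latent dimensionality is chosen by a saturation rule on validation SSIM over
the grid d in {8, 16, 32, 64, 128, 256}: the smallest d whose improvement
over the previous grid point has dropped below epsilon while already sitting
within epsilon of the best SSIM anywhere on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .vae import GRID_DIMS, ConvVAE, LossBreakdown, StreamConfig, build_stream, vae_loss

__all__ = [
    "TrainingDivergedError",
    "StreamVAE",
    "StreamVAEResults",
    "DimSearchResult",
    "train_stream",
    "select_latent_dim",
    "grid_search_latent_dim",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int, term: str, value: float):
        super().__init__(f"non-finite {term} loss ({value}) at epoch {epoch}")
        self.epoch, self.term = epoch, term


def _batch_ssim(x: np.ndarray, xhat: np.ndarray) -> float:
    from .disentangle import ssim

    vals = [ssim(np.moveaxis(a, 0, -1), np.moveaxis(b, 0, -1)) for a, b in zip(x, xhat)]
    return float(np.mean(vals))


@dataclass
class StreamVAEResults:
    """Fitted stream: best parameters, history and evaluation helpers."""

    model: ConvVAE
    history: pd.DataFrame
    best_epoch: int
    epochs: int
    batch_size: int
    learning_rate: float
    seed: int

    @property
    def config(self) -> StreamConfig:
        return self.model.config

    def encode_mu(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Posterior means for an (N,C,H,W) batch — the deterministic IDFs."""
        out = []
        for i in range(0, len(x), batch_size):
            mu, _ = self.model.encode(x[i : i + batch_size], training=False)
            out.append(mu)
        return np.concatenate(out, axis=0)

    def reconstruct(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            res = self.model.forward(x[i : i + batch_size], rng=None, training=False)
            out.append(res["xhat"])
        return np.concatenate(out, axis=0)

    def validation_loss(self, x: np.ndarray) -> LossBreakdown:
        return _evaluate(self.model, x)

    def summary(self) -> str:
        cfg = self.config
        h = self.history
        lines = [
            f"StreamVAE results: stream={cfg.stream}  d={cfg.latent_dim}  "
            f"base_width={cfg.base_width}  params={self.model.n_parameters()}",
            f"  beta={cfg.kl_weight}  lambda_sharp={cfg.sharpness_weight}  "
            f"dropout={cfg.encoder_dropout}",
            f"  epochs={self.epochs}  batch={self.batch_size}  lr={self.learning_rate}  "
            f"seed={self.seed}",
            f"  best epoch {self.best_epoch}: val loss {h['val_loss'][self.best_epoch - 1]:.5f}, "
            f"val SSIM {h['val_ssim'][self.best_epoch - 1]:.4f}",
        ]
        return "\n".join(lines)


def _evaluate(model: ConvVAE, x: np.ndarray, batch_size: int = 256) -> LossBreakdown:
    """Deterministic validation loss (z = mu, eval-mode normalization)."""
    tot = {"total": 0.0, "mse": 0.0, "kl": 0.0, "sharpness": 0.0}
    n = 0
    for i in range(0, len(x), batch_size):
        xb = x[i : i + batch_size]
        out = model.forward(xb, rng=None, training=False)
        loss = vae_loss(xb, out["xhat"], out["mu"], out["logvar"], model.config)
        for k in tot:
            tot[k] += getattr(loss, k) * len(xb)
        n += len(xb)
    return LossBreakdown(**{k: v / n for k, v in tot.items()})


class StreamVAE:
    """One stream's VAE together with its training/validation arrays."""

    def __init__(self, train_x: np.ndarray, val_x: np.ndarray, config: StreamConfig):
        if len(train_x) == 0 or len(val_x) == 0:
            raise ValueError("train and validation partitions must be nonempty")
        self.train_x = np.asarray(train_x, dtype=np.float32)
        self.val_x = np.asarray(val_x, dtype=np.float32)
        self.config = config

    def fit(
        self,
        epochs: int = 15,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        seed: int = 0,
        verbose: bool = False,
    ) -> StreamVAEResults:
        model = build_stream(self.config)
        rng = np.random.default_rng(seed)
        opt = nn.Adam(model.param_slots(), lr=learning_rate)
        records = []
        best = (np.inf, None, None, -1)  # val loss, params, running stats, epoch
        for epoch in range(1, epochs + 1):
            order = rng.permutation(len(self.train_x))
            train_tot = 0.0
            for i in range(0, len(order), batch_size):
                xb = self.train_x[order[i : i + batch_size]]
                loss = model.train_step_grads(xb, rng)
                for term in ("mse", "kl", "sharpness", "total"):
                    v = getattr(loss, term)
                    if not np.isfinite(v):
                        raise TrainingDivergedError(epoch, term, v)
                opt.step()
                train_tot += loss.total * len(xb)
            val = _evaluate(model, self.val_x)
            xhat = model.forward(self.val_x[:64], rng=None, training=False)["xhat"]
            val_ssim = _batch_ssim(self.val_x[:64], xhat)
            records.append(
                {
                    "epoch": epoch,
                    "train_loss": train_tot / len(self.train_x),
                    "val_loss": val.total,
                    "val_mse": val.mse,
                    "val_kl": val.kl,
                    "val_ssim": val_ssim,
                }
            )
            if verbose:
                print(
                    f"[{self.config.stream}] epoch {epoch}: train {records[-1]['train_loss']:.5f} "
                    f"val {val.total:.5f} ssim {val_ssim:.4f}"
                )
            if val.total < best[0]:
                params = {k: v.copy() for k, v in model.named_parameters().items()}
                running = _snapshot_running(model)
                best = (val.total, params, running, epoch)

        _restore(model, best[1], best[2])
        history = pd.DataFrame.from_records(records)
        return StreamVAEResults(
            model=model,
            history=history,
            best_epoch=best[3],
            epochs=epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            seed=seed,
        )


def _snapshot_running(model: ConvVAE):
    out = {}
    for tag, seq in (("enc", model.encoder), ("dec", model.decoder)):
        for i, layer in enumerate(seq.layers):
            if isinstance(layer, nn.BatchNorm2d):
                out[(tag, i)] = (layer.running_mean.copy(), layer.running_var.copy())
    return out


def _restore(model: ConvVAE, params, running):
    own = model.named_parameters()
    for name, arr in own.items():
        arr[...] = params[name]
    for tag, seq in (("enc", model.encoder), ("dec", model.decoder)):
        for i, layer in enumerate(seq.layers):
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean, layer.running_var = (
                    running[(tag, i)][0].copy(),
                    running[(tag, i)][1].copy(),
                )


def train_stream(
    train_x: np.ndarray,
    val_x: np.ndarray,
    config: StreamConfig,
    epochs: int = 15,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    verbose: bool = False,
) -> StreamVAEResults:
    """Functional wrapper: build, fit and return the results object."""
    return StreamVAE(train_x, val_x, config).fit(
        epochs=epochs, batch_size=batch_size, learning_rate=learning_rate, seed=seed, verbose=verbose
    )


@dataclass
class DimSearchResult:
    ssim_by_dim: dict[int, float]
    selected: int


def select_latent_dim(ssim_by_dim: Mapping[int, float], epsilon: float = 0.01) -> int:
    """Saturation rule: smallest d with marginal gain <= epsilon that is
    within epsilon of the grid maximum; if no plateau exists, argmax SSIM."""
    dims = sorted(ssim_by_dim)
    if len(dims) < 2:
        raise ValueError("need SSIM for at least two grid dimensions")
    unknown = [d for d in dims if d not in GRID_DIMS]
    if unknown:
        raise ValueError(f"dimensions {unknown} outside the search grid {GRID_DIMS}")
    vals = [float(ssim_by_dim[d]) for d in dims]
    best = max(vals)
    tol = epsilon + 1e-12
    prev = None
    for d, v in zip(dims, vals):
        gain = 0.0 if prev is None else v - prev
        if gain <= tol and best - v <= tol:
            return d
        prev = v
    return dims[int(np.argmax(vals))]


def grid_search_latent_dim(
    train_x: np.ndarray,
    val_x: np.ndarray,
    base_config: StreamConfig,
    dims: Sequence[int] = GRID_DIMS,
    epochs: int = 15,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    epsilon: float = 0.01,
) -> DimSearchResult:
    """Train one model per candidate d with identical data order and pick d*."""
    ssim_by_dim: dict[int, float] = {}
    for d in dims:
        cfg = StreamConfig(
            stream=base_config.stream,
            latent_dim=d,
            input_channels=base_config.input_channels,
            resolution=base_config.resolution,
            base_width=base_config.base_width,
            kl_weight=base_config.kl_weight,
            sharpness_weight=base_config.sharpness_weight,
            encoder_dropout=base_config.encoder_dropout,
            seed=base_config.seed,
        )
        res = StreamVAE(train_x, val_x, cfg).fit(
            epochs=epochs, batch_size=batch_size, learning_rate=learning_rate, seed=seed
        )
        ssim_by_dim[d] = float(res.history["val_ssim"].iloc[res.best_epoch - 1])
    return DimSearchResult(ssim_by_dim=ssim_by_dim, selected=select_latent_dim(ssim_by_dim, epsilon))
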