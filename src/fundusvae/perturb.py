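"""Latent traversal interpretability: sweeps, t-maps and anatomical locality.

A traversal decodes a base latent code while moving one coordinate across
[mu_i - 3 sigma_i, mu_i + 3 sigma_i] (sigma_i is the population standard
deviation of that latent across subjects) with all other coordinates held
fixed. The per-pixel variance across the decoded stack — the t-map — marks
the image region that coordinate controls; the locality score is the
fraction of t-map mass falling inside a given anatomical mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk

__all__ = [
    "TraversalMap",
    "traverse_latent",
    "compute_tmap",
    "locality_score",
    "mean_locality",
]

#: dilation (pixels) applied to locality masks to absorb rasterization misalignment
MASK_DILATION_PX = 2


@dataclass
class TraversalMap:
    stream: str
    latent_index: int
    step_values: np.ndarray  # the traversed coordinate values
    stack: np.ndarray  # (steps, C, H, W) decoded images
    tmap: np.ndarray  # (H, W) nonnegative, max 1 unless all-zero
    degenerate: bool  # True when the stack is constant (all-zero tmap)


def traverse_latent(
    results,
    base_code: np.ndarray,
    dim: int,
    sigma: float,
    steps: int = 7,
) -> TraversalMap:
    """Decode a +/-3 sigma sweep of one latent coordinate around a base code.

    ``results`` is a fitted stream (anything with ``.model`` or a ``decode``
    method); the center step reproduces the unperturbed decode exactly.
    """
    if steps < 3 or steps % 2 == 0:
        raise ValueError("steps must be odd and >= 3")
    base_code = np.asarray(base_code, dtype=np.float32).ravel()
    if not (0 <= dim < base_code.size):
        raise ValueError(f"latent index {dim} out of range for d={base_code.size}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    decode = results.model.decode if hasattr(results, "model") else results.decode
    stream = (
        results.config.stream
        if hasattr(results, "config")
        else getattr(results, "stream", "unknown")
    )

    offsets = np.linspace(-3.0, 3.0, steps)
    z = np.tile(base_code, (steps, 1))
    z[:, dim] = base_code[dim] + offsets * sigma
    stack = decode(z, training=False)
    tmap, degenerate = compute_tmap(stack, _return_flag=True)
    return TraversalMap(
        stream=stream,
        latent_index=dim,
        step_values=base_code[dim] + offsets * sigma,
        stack=stack,
        tmap=tmap,
        degenerate=degenerate,
    )


def compute_tmap(stack: np.ndarray, _return_flag: bool = False):
    """Per-pixel variance across the sweep, channel-averaged, max-normalized.

    A constant stack yields an all-zero map (no normalization) and is flagged.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 3:  # (steps, H, W)
        stack = stack[:, None]
    if stack.shape[0] < 3:
        raise ValueError("t-map needs at least 3 images in the stack")
    var = stack.var(axis=0).mean(axis=0)  # variance over sweep, mean over channels
    var[var < 1e-12] = 0.0  # float rounding floor: identical images score exactly zero
    peak = var.max()
    degenerate = peak <= 0
    tmap = var if degenerate else var / peak
    return (tmap, degenerate) if _return_flag else tmap


def locality_score(tmap: np.ndarray, region_mask: np.ndarray) -> float:
    """Fraction of t-map mass inside the mask; 0 for an all-zero map."""
    tmap = np.asarray(tmap, dtype=np.float64)
    region_mask = np.asarray(region_mask, dtype=bool)
    if tmap.shape != region_mask.shape:
        raise ValueError(f"shape mismatch {tmap.shape} vs {region_mask.shape}")
    total = tmap.sum()
    if total <= 0:
        return 0.0
    return float(tmap[region_mask].sum() / total)


def mean_locality(
    results,
    base_inputs: np.ndarray,
    region_masks: np.ndarray,
    sigmas: np.ndarray,
    steps: int = 5,
    dims: np.ndarray | None = None,
    dilate_px: int = MASK_DILATION_PX,
) -> float:
    """Mean locality over latent dims and base images.

    For each base image the posterior mean is the traversal anchor and its own
    (dilated) anatomical mask is the locality region; degenerate dimensions
    (constant decode) are skipped.
    """
    mu = results.encode_mu(np.asarray(base_inputs, dtype=np.float32))
    d = mu.shape[1]
    dims = np.arange(d) if dims is None else np.asarray(dims)
    selem = disk(dilate_px) if dilate_px > 0 else None
    scores = []
    for b in range(len(base_inputs)):
        mask = region_masks[b].astype(bool)
        if selem is not None:
            mask = dilation(mask, selem)
        for i in dims:
            if sigmas[i] <= 0:
                continue
            tm = traverse_latent(results, mu[b], int(i), float(sigmas[i]), steps=steps)
            if tm.degenerate:
                continue
            scores.append(locality_score(tm.tmap, mask))
    return float(np.mean(scores)) if scores else 0.0
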