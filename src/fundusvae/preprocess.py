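"""Structure-aware input construction.

Each anatomical stream sees a different view of the same fundus image:

* ``background`` — the image after a large median smoothing filter, which
  suppresses thin high-frequency structures (vessels) while preserving the
  low-frequency photometric field;
* ``disc_cup`` — intensities gated by the disc/cup masks and cropped to the
  disc bounding box with a fixed margin, so the encoder spends its capacity
  on disc geometry rather than position;
* ``vessel`` — the binary vessel mask itself (sparse, high-frequency);
* ``monolithic`` — the raw resized image, the ablation baseline's input.

Splitting into train/validation is done at the participant level so that the
two eyes of one subject can never straddle the partition boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import median_filter
from skimage.transform import resize

from .simulate import FundusSample

__all__ = [
    "STREAMS",
    "StreamInput",
    "SplitAssignment",
    "median_background",
    "scaled_kernel",
    "make_stream_input",
    "participant_split",
    "check_sample",
    "load_manifest",
    "stack_stream_inputs",
]

STREAMS = ("background", "disc_cup", "vessel", "monolithic")

#: reference resolution at which the canonical 17x17 median kernel is defined
REFERENCE_RESOLUTION = 512
REFERENCE_KERNEL = 17

# margin added around the disc bounding box, as a fraction of its size
DISC_CROP_MARGIN = 0.25


class InputError(ValueError):
    """A sample fails the input contract (missing mask, degenerate image)."""


@dataclass
class StreamInput:
    stream: str
    pixels: np.ndarray  # H x W x C float32 in [0, 1]
    subject_id: str
    eye: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.eye)


@dataclass
class SplitAssignment:
    """Participant-level train/validation assignment."""

    assignment: dict[str, str]  # subject_id -> "train" | "validation"
    train_fraction: float
    seed: int

    def partition(self, name: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == name)

    @property
    def train_subjects(self) -> list[str]:
        return self.partition("train")

    @property
    def validation_subjects(self) -> list[str]:
        return self.partition("validation")


def median_background(image: np.ndarray, kernel: int) -> np.ndarray:
    """Per-channel k x k sliding-window median with edge replication.

    Large kernels erase thin vascular strokes while keeping the smooth
    illumination and pigmentation field, which is exactly the signal the
    background stream is meant to encode.
    """
    if kernel % 2 == 0 or kernel < 1:
        raise InputError(f"median kernel must be odd and >= 1, got {kernel}")
    image = np.asarray(image)
    if image.ndim == 2:
        return median_filter(image, size=kernel, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = median_filter(image[..., c], size=kernel, mode="nearest")
    return out


def scaled_kernel(resolution: int, reference: int = REFERENCE_KERNEL) -> int:
    """Scale the reference kernel to the working resolution (nearest odd, >= 3)."""
    k = int(round(reference * resolution / REFERENCE_RESOLUTION))
    if k % 2 == 0:
        k += 1
    return max(k, 3)


def _resize_image(img: np.ndarray, resolution: int) -> np.ndarray:
    if img.shape[0] == resolution and img.shape[1] == resolution:
        return img.astype(np.float32)
    out = resize(img, (resolution, resolution), anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _resize_mask(mask: np.ndarray, resolution: int) -> np.ndarray:
    if mask.shape[0] == resolution and mask.shape[1] == resolution:
        return mask.astype(bool)
    out = resize(mask.astype(float), (resolution, resolution), anti_aliasing=False, order=1)
    return out >= 0.5


def check_sample(sample: FundusSample) -> None:
    """Basic input contract replacing learned image QC: reject degenerate samples."""
    if sample.image.size == 0 or float(sample.image.max()) == 0.0:
        raise InputError(f"sample {sample.key}: image is empty or all-black")
    h, w = sample.image.shape[:2]
    for name in ("disc_mask", "cup_mask", "vessel_mask"):
        m = getattr(sample, name, None)
        if m is None:
            raise InputError(f"sample {sample.key}: missing {name}")
        if m.shape != (h, w):
            raise InputError(f"sample {sample.key}: {name} shape mismatch {m.shape} vs {(h, w)}")


def make_stream_input(
    sample: FundusSample,
    stream: str,
    kernel: int | None = None,
    target_resolution: int = 64,
) -> StreamInput:
    """Build the tensorized input one stream sees for one sample."""
    if stream not in STREAMS:
        raise InputError(f"unknown stream {stream!r}; expected one of {STREAMS}")
    check_sample(sample)
    img = np.asarray(sample.image, dtype=np.float64)
    h, w = img.shape[:2]

    if stream == "monolithic":
        pixels = _resize_image(img, target_resolution)
    elif stream == "background":
        k = kernel if kernel is not None else scaled_kernel(h)
        pixels = _resize_image(median_background(img, k), target_resolution)
    elif stream == "vessel":
        if sample.vessel_mask is None:
            raise InputError(f"sample {sample.key}: vessel stream requires vessel_mask")
        m = _resize_mask(sample.vessel_mask, target_resolution)
        pixels = m.astype(np.float32)[..., None]
    else:  # disc_cup
        if sample.disc_mask is None or sample.cup_mask is None:
            raise InputError(f"sample {sample.key}: disc_cup stream requires disc and cup masks")
        gate = sample.disc_mask | sample.cup_mask
        gated = img * gate[..., None]
        if gate.any():
            rr, cc = np.nonzero(gate)
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            mr = int(round(DISC_CROP_MARGIN * (r1 - r0)))
            mc = int(round(DISC_CROP_MARGIN * (c1 - c0)))
            r0, r1 = max(0, r0 - mr), min(h, r1 + mr)
            c0, c1 = max(0, c0 - mc), min(w, c1 + mc)
            gated = gated[r0:r1, c0:c1]
        pixels = _resize_image(gated, target_resolution)

    return StreamInput(stream=stream, pixels=pixels, subject_id=sample.subject_id, eye=sample.eye)


def participant_split(
    subject_ids: Sequence[str], train_fraction: float = 0.75, seed: int = 0
) -> SplitAssignment:
    """Shuffle-then-cut split over unique subject ids; eyes travel together."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    unique = list(dict.fromkeys(subject_ids))
    if not unique:
        raise ValueError("subject_ids must be nonempty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_train = int(round(train_fraction * len(unique)))
    n_train = min(max(n_train, 1), len(unique) - 1) if len(unique) > 1 else len(unique)
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[unique[idx]] = "train" if rank < n_train else "validation"
    return SplitAssignment(assignment=assignment, train_fraction=train_fraction, seed=seed)


def load_manifest(manifest_path) -> list[FundusSample]:
    """Load PNG images and masks listed in a manifest CSV into FundusSamples.

    Expected columns: subject_id, eye, image_path, disc_mask_path,
    cup_mask_path, vessel_mask_path (the simulator's layout).
    """
    import pandas as pd
    from PIL import Image

    manifest = pd.read_csv(manifest_path)
    required = {
        "subject_id",
        "eye",
        "image_path",
        "disc_mask_path",
        "cup_mask_path",
        "vessel_mask_path",
    }
    missing = required - set(manifest.columns)
    if missing:
        raise InputError(f"manifest missing columns: {sorted(missing)}")
    samples = []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(row["image_path"]), dtype=np.float32) / 255.0
        masks = {}
        for name in ("disc", "cup", "vessel"):
            m = np.asarray(Image.open(row[f"{name}_mask_path"]))
            masks[f"{name}_mask"] = m > 127
        sample = FundusSample(
            subject_id=str(row["subject_id"]),
            eye=str(row["eye"]),
            image=img,
            resolution=img.shape[0],
            **masks,
        )
        check_sample(sample)
        samples.append(sample)
    return samples


def stack_stream_inputs(inputs: Iterable[StreamInput]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Stack StreamInputs into an (N, H, W, C) array plus aligned sample keys."""
    inputs = list(inputs)
    if not inputs:
        raise InputError("no stream inputs to stack")
    streams = {i.stream for i in inputs}
    if len(streams) != 1:
        raise InputError(f"cannot stack inputs from different streams: {sorted(streams)}")
    x = np.stack([i.pixels for i in inputs]).astype(np.float32)
    keys = [i.key for i in inputs]
    return x, keys
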