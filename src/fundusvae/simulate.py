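"""Synthetic fundus simulator with known generative factors.

Generates paired-eye fundus-like RGB images together with pixel-accurate
optic-disc, optic-cup and vessel masks, all driven by a per-subject table of
morphological factors (the ground truth against which disentanglement is
later scored). Three groups of factors map onto the three anatomical domains
a structure-aware encoder is meant to isolate:

* photometric background — illumination gradient, pigment density,
  tessellation texture amplitude;
* optic disc / cup — disc radius, cup-to-disc ratio, ovality, centre;
* vasculature — number of major vessels, tortuosity, caliber, branch depth.

Left and right eyes of one subject share subject-level factors (the disc
centre is mirrored horizontally) plus configurable per-eye noise, and
genetic effects can shift named factors additively per allele.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, skeletonize

__all__ = [
    "FACTOR_BOUNDS",
    "DEFAULT_SAMPLING_BOUNDS",
    "INTEGER_FACTORS",
    "FACTOR_NAMES",
    "STREAM_FACTORS",
    "FundusSample",
    "sample_factors",
    "render_fundus",
    "render_dataset",
    "apply_genetic_effects",
    "image_summary_stats",
    "save_dataset",
    "load_factor_table",
]

# Hard validity bounds of each generative factor (type-level invariants).
FACTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "illum_gradient": (-1.0, 1.0),
    "pigment_density": (0.0, 1.0),
    "tessellation_amp": (0.0, 1.0),
    "disc_radius": (0.05, 0.15),
    "cup_to_disc": (0.1, 0.9),
    "disc_ovality": (0.7, 1.3),
    "disc_cx": (0.0, 1.0),
    "disc_cy": (0.0, 1.0),
    "n_major_vessels": (4, 8),
    "vessel_tortuosity": (0.0, 1.0),
    "vessel_caliber": (0.004, 0.02),
    "branch_depth": (1, 4),
}

# Sampling defaults: the disc sits nasally and vertically centred so it stays
# inside the frame; all other factors are drawn over their full valid range.
DEFAULT_SAMPLING_BOUNDS: dict[str, tuple[float, float]] = {
    **FACTOR_BOUNDS,
    "disc_cx": (0.22, 0.42),
    "disc_cy": (0.38, 0.62),
}

INTEGER_FACTORS = frozenset({"n_major_vessels", "branch_depth"})
FACTOR_NAMES = tuple(FACTOR_BOUNDS)

# Which factors each stream is dedicated to (used by disentanglement scoring
# and by the genetic attribution bookkeeping).
STREAM_FACTORS: dict[str, tuple[str, ...]] = {
    "background": ("illum_gradient", "pigment_density", "tessellation_amp"),
    "disc_cup": ("disc_radius", "cup_to_disc", "disc_ovality", "disc_cx", "disc_cy"),
    "vessel": ("n_major_vessels", "vessel_tortuosity", "vessel_caliber", "branch_depth"),
}

# Colours (RGB in [0,1]) used by the painter.
_DISC_COLOR = np.array([0.96, 0.82, 0.50])
_CUP_COLOR = np.array([1.00, 0.94, 0.72])
_VESSEL_COLOR = np.array([0.38, 0.08, 0.06])

# Fraction of the frame vessels may cover; the renderer stops adding branches
# once the drawing budget is exhausted so the mask invariant always holds.
_VESSEL_BUDGET_FRACTION = 0.13


class ConfigurationError(ValueError):
    """Invalid configuration (bounds, fractions, unknown names)."""


class FactorValidationError(ValueError):
    """A generative factor lies outside its valid bounds."""


@dataclass
class FundusSample:
    """One rendered eye: image, structural masks and identity metadata."""

    subject_id: str
    eye: str
    image: np.ndarray  # H x W x 3 float32 in [0, 1]
    disc_mask: np.ndarray  # H x W bool
    cup_mask: np.ndarray  # H x W bool
    vessel_mask: np.ndarray  # H x W bool
    resolution: int

    def validate(self) -> None:
        h, w = self.image.shape[:2]
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise FactorValidationError("image must be H x W x 3")
        for name in ("disc_mask", "cup_mask", "vessel_mask"):
            m = getattr(self, name)
            if m.shape != (h, w):
                raise FactorValidationError(f"{name} shape {m.shape} != image {h, w}")
        if self.image.min() < 0.0 or self.image.max() > 1.0:
            raise FactorValidationError("image intensities outside [0, 1]")
        if np.any(self.cup_mask & ~self.disc_mask):
            raise FactorValidationError("cup_mask not contained in disc_mask")
        if self.vessel_mask.mean() > 0.15:
            raise FactorValidationError("vessel_mask covers more than 15% of pixels")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.eye)


def _check_bounds(bounds: Mapping[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    merged = dict(DEFAULT_SAMPLING_BOUNDS)
    for name, (lo, hi) in bounds.items():
        if name not in FACTOR_BOUNDS:
            raise ConfigurationError(f"unknown factor {name!r}")
        hard_lo, hard_hi = FACTOR_BOUNDS[name]
        if not (hard_lo <= lo <= hi <= hard_hi):
            raise ConfigurationError(
                f"bounds for {name!r} must satisfy {hard_lo} <= lo <= hi <= {hard_hi}, got ({lo}, {hi})"
            )
        merged[name] = (float(lo), float(hi))
    return merged


def _clip_factors(row: pd.Series) -> pd.Series:
    out = row.copy()
    for name, (lo, hi) in FACTOR_BOUNDS.items():
        v = float(np.clip(out[name], lo, hi))
        if name in INTEGER_FACTORS:
            v = int(round(v))
        out[name] = v
    return out


def sample_factors(
    n_subjects: int,
    pair_eyes: bool = True,
    eye_noise_sd: float = 0.02,
    seed: int = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Draw a ground-truth factor table for ``n_subjects``.

    Subject-level factors are uniform within ``bounds``; each eye then
    receives independent Gaussian noise with standard deviation
    ``eye_noise_sd`` expressed as a fraction of the factor's valid range,
    clipped back into bounds. For paired eyes the right eye's ``disc_cx``
    is mirrored (``1 - disc_cx``) before noise.
    """
    if n_subjects < 0:
        raise ConfigurationError("n_subjects must be >= 0")
    if eye_noise_sd < 0:
        raise ConfigurationError("eye_noise_sd must be >= 0")
    merged = _check_bounds(bounds or {})
    rng = np.random.default_rng(seed)

    cols = {name: rng.uniform(lo, hi, size=n_subjects) for name, (lo, hi) in merged.items()}
    base = pd.DataFrame(cols)
    # sorted: draw order must not depend on set iteration (hash randomization)
    for name in sorted(INTEGER_FACTORS):
        lo, hi = merged[name]
        base[name] = rng.integers(int(lo), int(hi) + 1, size=n_subjects)

    eyes = ("left", "right") if pair_eyes else ("left",)
    rows = []
    for s in range(n_subjects):
        sid = f"S{s:05d}"
        for eye in eyes:
            row = base.iloc[s].copy()
            if eye == "right":
                row["disc_cx"] = 1.0 - row["disc_cx"]
            if eye_noise_sd > 0:
                for name, (lo, hi) in FACTOR_BOUNDS.items():
                    row[name] = row[name] + rng.normal(0.0, eye_noise_sd * (hi - lo))
            row = _clip_factors(row)
            rows.append({"subject_id": sid, "eye": eye, **row[list(FACTOR_NAMES)].to_dict()})
    table = pd.DataFrame(rows, columns=["subject_id", "eye", *FACTOR_NAMES])
    if table.empty:
        table = pd.DataFrame(columns=["subject_id", "eye", *FACTOR_NAMES])
    else:
        for name in INTEGER_FACTORS:
            table[name] = table[name].astype(int)
    return table


def _sample_seed(global_seed: int, subject_id: str, eye: str) -> int:
    """Stable per-sample seed so datasets are reproducible sample-by-sample."""
    return zlib.crc32(f"{global_seed}|{subject_id}|{eye}".encode()) & 0x7FFFFFFF


def _validate_row(factors: Mapping[str, float]) -> dict[str, float]:
    vals = {}
    for name, (lo, hi) in FACTOR_BOUNDS.items():
        if name not in factors:
            raise FactorValidationError(f"missing factor {name!r}")
        v = float(factors[name])
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise FactorValidationError(f"factor {name}={v} outside [{lo}, {hi}]")
        vals[name] = v
    return vals


def _paint_background(f: Mapping[str, float], xx: np.ndarray, yy: np.ndarray, rng) -> np.ndarray:
    # Base retinal colour darkened by pigment; illumination varies linearly
    # across the horizontal axis; tessellation is a band-limited sinusoidal
    # texture with sample-specific frequencies and phases.
    lum = 0.55 + 0.30 * (1.0 - f["pigment_density"])
    illum = 1.0 + 0.22 * f["illum_gradient"] * (2.0 * xx - 1.0)
    tex = np.zeros_like(xx)
    for _ in range(3):
        fx, fy = rng.uniform(3.0, 7.0, size=2)
        phx, phy = rng.uniform(0.0, 2 * np.pi, size=2)
        tex += np.sin(2 * np.pi * fx * xx + phx) * np.sin(2 * np.pi * fy * yy + phy)
    tex = 0.05 * f["tessellation_amp"] * tex / 3.0
    base = np.stack(
        [lum * illum * 1.00 + tex, lum * illum * 0.52 + 0.6 * tex, lum * illum * 0.30 + 0.3 * tex],
        axis=-1,
    )
    return base


def _vessel_tree(f: Mapping[str, float], rng, a: float, b: float):
    """Grow the vessel tree as normalized polylines with per-branch width.

    Returns a list of (points, width_fraction) where points is an (n, 2)
    array of normalized (x, y) vertices. Major vessels start on the disc
    boundary at spread angles; curvature follows a seeded random walk whose
    angular step scales with tortuosity; children inherit a reduced width.
    """
    n_major = int(round(f["n_major_vessels"]))
    depth_max = int(round(f["branch_depth"]))
    tort = f["vessel_tortuosity"]
    cx, cy = f["disc_cx"], f["disc_cy"]
    branches = []

    def grow(x, y, theta, width, depth, length):
        # tortuosity enters as a deterministic sinusoidal displacement
        # perpendicular to the local direction (amplitude grows with the
        # factor), on top of a gentle random walk of the heading
        pts = [(x, y)]
        step = 0.018
        n_steps = max(4, int(length / step))
        branch_at = max(2, int(0.3 * n_steps)) if depth < depth_max else -1
        amp = 0.030 * tort
        lam = 0.07
        phase = rng.uniform(0.0, 2 * np.pi)
        for i in range(n_steps):
            theta += rng.normal(0.0, 0.05)
            # mild outward bias keeps vessels from doubling back into the disc
            out = np.arctan2(y - cy, x - cx)
            d = np.arctan2(np.sin(out - theta), np.cos(out - theta))
            theta += 0.10 * d
            x += step * np.cos(theta)
            y += step * np.sin(theta)
            off = amp * np.sin(2 * np.pi * (i + 1) * step / lam + phase)
            px = x - off * np.sin(theta)
            py = y + off * np.cos(theta)
            if not (0.0 <= px <= 1.0 and 0.0 <= py <= 1.0):
                break
            pts.append((px, py))
            if i == branch_at:
                child_theta = theta + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 0.9)
                grow(x, y, child_theta, width * 0.8, depth + 1, length * 0.75)
        if len(pts) >= 2:
            branches.append((np.asarray(pts), width))

    base_angles = 2 * np.pi * (np.arange(n_major) + 0.5) / n_major
    for theta0 in base_angles:
        theta = theta0 + rng.uniform(-0.25, 0.25) * np.pi / n_major
        x0 = cx + 1.05 * a * np.cos(theta)
        y0 = cy + 1.05 * b * np.sin(theta)
        grow(x0, y0, theta, f["vessel_caliber"], 1, rng.uniform(0.26, 0.36))
    return branches


def _rasterize_vessels(branches, resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the tree into a binary mask and a coverage (alpha) map.

    Strokes narrower than one pixel are drawn as single-pixel lines whose
    coverage equals the sub-pixel width (anti-aliasing), so caliber stays
    visible in the image at any resolution even when the binary mask cannot
    express it.
    """
    h = w = resolution
    mask = np.zeros((h, w), dtype=bool)
    alpha = np.zeros((h, w), dtype=np.float64)
    budget = int(_VESSEL_BUDGET_FRACTION * h * w)
    for pts, width in branches:
        if mask.sum() >= budget:
            break
        stroke = np.zeros((h, w), dtype=bool)
        pix = np.clip((pts * (resolution - 1)).round().astype(int), 0, resolution - 1)
        for (x0, y0), (x1, y1) in zip(pix[:-1], pix[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            stroke[rr, cc] = True
        width_px = width * resolution
        extra = int(round((width_px - 1.0) / 2.0))
        if extra > 0:
            stroke = dilation(stroke, disk(extra))
        mask |= stroke
        np.maximum(alpha, np.where(stroke, min(1.0, width_px / 1.3), 0.0), out=alpha)
    return mask, alpha


def render_fundus(factors, resolution: int = 64, seed: int = 0, vessels: bool = True) -> FundusSample:
    """Render one eye from a factor row; pure function of (factors, resolution, seed).

    ``vessels=False`` renders the identical background and disc but skips the
    vascular tree (an oracle for vessel-suppression checks); the vessel mask
    is then empty.
    """
    if resolution < 32:
        raise ConfigurationError("resolution must be >= 32")
    if isinstance(factors, pd.Series):
        factors = factors.to_dict()
    subject_id = str(factors.get("subject_id", "S00000"))
    eye = str(factors.get("eye", "left"))
    f = _validate_row(factors)
    rng = np.random.default_rng(_sample_seed(seed, subject_id, eye))

    ys, xs = np.mgrid[0:resolution, 0:resolution]
    xx = (xs + 0.5) / resolution
    yy = (ys + 0.5) / resolution

    img = _paint_background(f, xx, yy, rng)

    # Disc / cup: concentric ellipses with area preserved under ovality, so
    # cup area / disc area == cup_to_disc ** 2 exactly (up to rasterization).
    a = f["disc_radius"] * np.sqrt(f["disc_ovality"])
    b = f["disc_radius"] / np.sqrt(f["disc_ovality"])
    q = ((xx - f["disc_cx"]) / a) ** 2 + ((yy - f["disc_cy"]) / b) ** 2
    disc_mask = q <= 1.0
    cup_mask = q <= f["cup_to_disc"] ** 2
    # soft-edged blending keeps gradients informative for reconstruction
    disc_soft = np.clip((1.0 - q) / 0.25, 0.0, 1.0)
    cup_soft = np.clip((f["cup_to_disc"] ** 2 - q) / 0.10, 0.0, 1.0)
    img = img * (1 - disc_soft[..., None]) + _DISC_COLOR * disc_soft[..., None]
    img = img * (1 - cup_soft[..., None]) + _CUP_COLOR * cup_soft[..., None]

    if vessels:
        branches = _vessel_tree(f, rng, a, b)
        vessel_mask, vessel_alpha = _rasterize_vessels(branches, resolution)
        img = img * (1 - vessel_alpha[..., None]) + _VESSEL_COLOR * vessel_alpha[..., None]
    else:
        vessel_mask = np.zeros((resolution, resolution), dtype=bool)

    sample = FundusSample(
        subject_id=subject_id,
        eye=eye,
        image=np.clip(img, 0.0, 1.0).astype(np.float32),
        disc_mask=disc_mask,
        cup_mask=cup_mask,
        vessel_mask=vessel_mask,
        resolution=resolution,
    )
    sample.validate()
    return sample


def render_dataset(factors: pd.DataFrame, resolution: int = 64, seed: int = 0) -> list[FundusSample]:
    return [render_fundus(row, resolution=resolution, seed=seed) for _, row in factors.iterrows()]


def apply_genetic_effects(
    base: pd.DataFrame,
    genotypes: np.ndarray,
    effects: Sequence[tuple[int, str, float]],
) -> pd.DataFrame:
    """Shift factors additively per allele: factor += sum_j beta_j * g_j.

    ``genotypes`` rows align with the unique subjects of ``base`` in order of
    first appearance; both eyes of a subject receive the same shift. Values
    are clipped back into bounds; clipped cells are recorded in
    ``result.attrs['clipped_cells']`` as (subject_id, eye, factor) tuples.
    """
    subjects = list(dict.fromkeys(base["subject_id"]))
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[0] != len(subjects):
        raise ConfigurationError(
            f"genotype rows ({genotypes.shape[0] if genotypes.ndim == 2 else '?'}) "
            f"must align with {len(subjects)} subjects"
        )
    for snp, factor, _ in effects:
        if factor not in FACTOR_BOUNDS:
            raise ConfigurationError(f"unknown factor {factor!r} in effects")
        if not (0 <= snp < genotypes.shape[1]):
            raise ConfigurationError(f"SNP index {snp} out of range")

    sub_index = {s: i for i, s in enumerate(subjects)}
    out = base.copy()
    clipped: list[tuple[str, str, str]] = []
    shifts: dict[str, np.ndarray] = {}
    for snp, factor, beta in effects:
        shifts[factor] = shifts.get(factor, np.zeros(len(subjects))) + beta * genotypes[:, snp]
    for factor, shift in shifts.items():
        lo, hi = FACTOR_BOUNDS[factor]
        raw = out[factor].to_numpy(dtype=float) + shift[
            out["subject_id"].map(sub_index).to_numpy()
        ]
        clip = np.clip(raw, lo, hi)
        hit = np.abs(clip - raw) > 1e-12
        for idx in np.flatnonzero(hit):
            clipped.append((out.iloc[idx]["subject_id"], out.iloc[idx]["eye"], factor))
        if factor in INTEGER_FACTORS:
            clip = np.round(clip).astype(int)
        out[factor] = clip
    out.attrs["clipped_cells"] = clipped
    return out


def image_summary_stats(sample: FundusSample) -> dict[str, float]:
    """Hand-crafted image statistics used to check factor recoverability.

    These are deliberately simple measurements (mask areas, centroids, mean
    intensities, skeleton lengths) a reader could recompute by hand; ordinary
    least squares of each generative factor on this vector should explain
    most of its variance if the renderer actually expresses the factors.
    """
    img = sample.image
    h, w = img.shape[:2]
    fg = dilation(sample.disc_mask | sample.vessel_mask, disk(2))
    bg = ~fg
    ys, xs = np.mgrid[0:h, 0:w]
    xx = (xs + 0.5) / w
    yy = (ys + 0.5) / h

    stats: dict[str, float] = {}
    red = img[..., 0]
    stats["bg_mean"] = float(red[bg].mean()) if bg.any() else 0.0
    # horizontal illumination slope via least squares of intensity on x
    if bg.sum() > 2:
        xb = xx[bg] - xx[bg].mean()
        stats["bg_slope_x"] = float((xb * red[bg]).sum() / (xb**2).sum())
    else:
        stats["bg_slope_x"] = 0.0
    gy, gx = np.gradient(red)
    stats["bg_highpass_sd"] = float(np.hypot(gx, gy)[bg].std()) if bg.any() else 0.0

    disc_area = sample.disc_mask.mean()
    stats["disc_sqrt_area"] = float(np.sqrt(disc_area))
    cup_area = sample.cup_mask.mean()
    stats["cup_disc_sqrt_ratio"] = float(np.sqrt(cup_area / disc_area)) if disc_area > 0 else 0.0
    if sample.disc_mask.any():
        rr, cc = np.nonzero(sample.disc_mask)
        stats["disc_cx"] = float((cc.mean() + 0.5) / w)
        stats["disc_cy"] = float((rr.mean() + 0.5) / h)
        # second-moment aspect is less quantized than a bounding-box ratio
        stats["disc_aspect"] = float(np.sqrt((cc.var() + 1 / 12) / (rr.var() + 1 / 12)))
    else:
        stats["disc_cx"] = stats["disc_cy"] = 0.5
        stats["disc_aspect"] = 1.0

    vm = sample.vessel_mask
    stats["vessel_fraction"] = float(vm.mean())
    # thin vessels are drawn with sub-pixel coverage, so mean intensity on
    # the vessel mask carries the caliber signal
    stats["vessel_mean_red"] = float(red[vm].mean()) if vm.any() else 0.0
    # invert the alpha blend against the known vessel paint colour to get a
    # direct sub-pixel coverage estimate
    if vm.any() and stats["bg_mean"] > _VESSEL_COLOR[0] + 0.05:
        stats["vessel_alpha_hat"] = (stats["bg_mean"] - stats["vessel_mean_red"]) / (
            stats["bg_mean"] - _VESSEL_COLOR[0]
        )
    else:
        stats["vessel_alpha_hat"] = 0.0
    labels = cc_label(vm, connectivity=2)
    n_comp = int(labels.max())
    stats["vessel_components"] = float(n_comp)
    skel = skeletonize(vm)

    # orientation-corrected arc length: 4-adjacencies count 1, diagonals sqrt(2)
    s = skel.astype(np.int8)
    n4 = float((s[:, 1:] & s[:, :-1]).sum() + (s[1:, :] & s[:-1, :]).sum())
    nd = float((s[1:, 1:] & s[:-1, :-1]).sum() + (s[1:, :-1] & s[:-1, 1:]).sum())
    arc_len = n4 + np.sqrt(2.0) * nd
    stats["vessel_skeleton_len"] = arc_len / (h * w) ** 0.5
    stats["vessel_caliber_proxy"] = float(vm.sum() / max(arc_len, 1.0))

    # branch points: skeleton pixels with >= 3 skeleton neighbours
    from scipy.ndimage import convolve as _conv

    nb = _conv(s, np.ones((3, 3), dtype=np.int8), mode="constant") - s
    n_branch = float(((nb >= 3) & skel).sum())
    stats["vessel_branchpoints_per_comp"] = n_branch / max(n_comp, 1)
    # skeleton tips: one per branch, so tips per tree tracks branching depth
    stats["vessel_endpoints_per_comp"] = float(((nb == 1) & skel).sum()) / max(n_comp, 1)

    # ring crossings just outside the disc count the major vessels directly
    a_px = np.sqrt(sample.disc_mask.mean() / np.pi)  # mean normalized radius
    r_norm = np.hypot(xx - stats["disc_cx"], (yy - stats["disc_cy"]))
    ring = (r_norm >= 1.3 * a_px) & (r_norm <= 1.3 * a_px + 2.5 / min(h, w))
    stats["vessel_ring_crossings"] = float(cc_label(vm & ring, connectivity=2).max())

    if skel.any():
        r = r_norm[vm]
        stats["vessel_mean_reach"] = float(r.mean())
        stats["vessel_p95_reach"] = float(np.quantile(r, 0.95))
        # classic arc-over-chord tortuosity on simple segments: prune branch
        # points first so branching does not inflate the index
        from scipy.spatial.distance import pdist

        pruned = skel & ~dilation((nb >= 3) & skel, disk(1))
        ps = pruned.astype(np.int8)
        arcs, spans = [], []
        skl = cc_label(pruned, connectivity=2)
        for k in range(1, int(skl.max()) + 1):
            pts = np.argwhere(skl == k).astype(float)
            if len(pts) >= 6:
                seg = skl == k
                s4 = float((seg[:, 1:] & seg[:, :-1]).sum() + (seg[1:, :] & seg[:-1, :]).sum())
                sd = float(
                    (seg[1:, 1:] & seg[:-1, :-1]).sum() + (seg[1:, :-1] & seg[:-1, 1:]).sum()
                )
                arcs.append(s4 + np.sqrt(2.0) * sd)
                spans.append(float(pdist(pts).max()))
        if spans:
            arcs_a = np.asarray(arcs)
            stats["vessel_tort_index"] = float((arcs_a / np.asarray(spans)).mean())
        else:
            stats["vessel_tort_index"] = 1.0
    else:
        stats["vessel_mean_reach"] = stats["vessel_p95_reach"] = 0.0
        stats["vessel_tort_index"] = 0.0
    stats["vessel_len_per_comp"] = arc_len / max(n_comp, 1) / (h * w) ** 0.5
    return stats


def save_dataset(samples: Sequence[FundusSample], factors: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Write PNG images/masks plus manifest.csv and factors.csv; returns the manifest."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        stem = f"{s.subject_id}_{s.eye}"
        img_path = out / "images" / f"{stem}.png"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(img_path)
        mask_paths = {}
        for name in ("disc", "cup", "vessel"):
            m = getattr(s, f"{name}_mask")
            p = out / "masks" / f"{stem}_{name}.png"
            Image.fromarray((m.astype(np.uint8)) * 255).save(p)
            mask_paths[f"{name}_mask_path"] = str(p)
        rows.append({"subject_id": s.subject_id, "eye": s.eye, "image_path": str(img_path), **mask_paths})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    factors.to_csv(out / "factors.csv", index=False)
    return manifest


def load_factor_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ("subject_id", "eye", *FACTOR_NAMES) if c not in table.columns]
    if missing:
        raise ConfigurationError(f"factor table missing columns: {missing}")
    return table
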