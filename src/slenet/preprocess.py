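"""Image preprocessing: bicubic rescaling, photometric augmentation, data split.

Bicubic resampling uses the cubic convolution kernel

    W(x) = (a+2)|x|^3 - (a+3)|x|^2 + 1          for |x| <= 1
           a|x|^3 - 5a|x|^2 + 8a|x| - 4a        for 1 < |x| < 2
           0                                     otherwise

with sharpness constant a (default -0.5, the Keys kernel, which is a
partition of unity).  Each output pixel is the weighted sum of its 4 x 4
source neighbourhood; the two image axes are separable, so the resize is
evaluated as two matrix products against per-axis weight matrices, which is
exactly the double sum evaluated at every pixel.  Output-pixel source
positions use half-pixel centres and out-of-grid neighbours are clamped to
the edge.

Augmentation follows the training recipe: random horizontal/vertical flips,
rotation drawn from {0, 90, 180, 270} degrees, brightness scaled by up to
+/-15% and contrast by up to +/-10% (per-channel contrast about the channel
mean).  The dataset split is a seeded global permutation cut at the 6:2:2
boundaries with largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BicubicKernelParams",
    "AugmentConfig",
    "SplitRatios",
    "bicubic_weight",
    "resize_bicubic",
    "photometric_adjust",
    "augment_image",
    "split_sizes",
    "split_manifest",
]


@dataclass
class BicubicKernelParams:
    a: float = -0.5

    def __post_init__(self):
        if self.a not in (-0.5, -0.75, 1.0, 1):
            raise ValueError("kernel constant a must be -0.5, -0.75 or 1")


def bicubic_weight(x, params: BicubicKernelParams | float = -0.5):
    """Cubic convolution kernel W(x); accepts scalars or arrays."""
    a = params.a if isinstance(params, BicubicKernelParams) else float(params)
    ax = np.abs(np.asarray(x, dtype=np.float64))
    near = (a + 2) * ax**3 - (a + 3) * ax**2 + 1
    far = a * ax**3 - 5 * a * ax**2 + 8 * a * ax - 4 * a
    out = np.where(ax <= 1, near, np.where(ax < 2, far, 0.0))
    return out if out.ndim else float(out)


def _axis_weights(n_src: int, n_dst: int, a: float) -> np.ndarray:
    """(n_dst, n_src) matrix: rows hold the 4 kernel taps, edges clamped."""
    mat = np.zeros((n_dst, n_src))
    for i in range(n_dst):
        src = (i + 0.5) * n_src / n_dst - 0.5
        base = int(np.floor(src))
        for k in range(base - 1, base + 3):
            w = bicubic_weight(src - k, a)
            mat[i, min(max(k, 0), n_src - 1)] += w
    return mat


def resize_bicubic(image, target=(224, 224), params: BicubicKernelParams | None = None):
    """Resample H x W (x C) image to ``target`` with the 4 x 4 cubic kernel.

    Returns float64 clamped to [0, 255]; channels are processed independently.
    """
    params = params or BicubicKernelParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return resize_bicubic(img[:, :, None], target, params)[:, :, 0]
    if img.ndim != 3:
        raise ValueError("image must be H x W or H x W x C")
    h, w, _ = img.shape
    if h < 4 or w < 4:
        raise ValueError("image must be at least 4 x 4 for bicubic resampling")
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target size must be positive")
    rows = _axis_weights(h, th, params.a)
    cols = _axis_weights(w, tw, params.a)
    # separable evaluation: rows first, then columns, per channel
    tmp = (rows @ img.reshape(h, -1)).reshape(th, w, -1)
    out = (tmp.transpose(0, 2, 1) @ cols.T).transpose(0, 2, 1)
    return np.clip(out, 0.0, 255.0)


@dataclass
class AugmentConfig:
    brightness_max_frac: float = 0.15
    contrast_max_frac: float = 0.10
    hflip: bool = True
    vflip: bool = True
    rotation_set: tuple = (0, 90, 180, 270)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.brightness_max_frac <= 1.0:
            raise ValueError("brightness fraction must lie in [0, 1]")
        if not 0.0 <= self.contrast_max_frac <= 1.0:
            raise ValueError("contrast fraction must lie in [0, 1]")
        if any(r % 90 != 0 for r in self.rotation_set):
            raise ValueError("rotations are restricted to multiples of 90 degrees")

    @classmethod
    def identity(cls):
        return cls(0.0, 0.0, False, False, (0,))


def photometric_adjust(image, brightness=1.0, contrast=1.0):
    """Scale brightness, then stretch per-channel contrast about the mean."""
    img = np.asarray(image, dtype=np.float64)
    if brightness != 1.0:
        img = img * brightness
    if contrast != 1.0:
        mean = img.mean(axis=(0, 1), keepdims=True) if img.ndim == 3 else img.mean()
        img = (img - mean) * contrast + mean
    return np.clip(img, 0.0, 255.0)


def augment_image(image, cfg: AugmentConfig, rng: np.random.Generator):
    """One stochastic draw of the training-time augmentation. H x W (x C) input."""
    img = np.asarray(image, dtype=np.float64)
    if cfg.hflip and rng.random() < 0.5:
        img = img[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        img = img[::-1, :]
    rot = int(rng.choice(cfg.rotation_set))
    if rot % 360:
        img = np.rot90(img, k=(rot // 90) % 4)
    b = rng.uniform(1 - cfg.brightness_max_frac, 1 + cfg.brightness_max_frac)
    c = rng.uniform(1 - cfg.contrast_max_frac, 1 + cfg.contrast_max_frac)
    return photometric_adjust(np.ascontiguousarray(img), b, c)


@dataclass
class SplitRatios:
    train: float = 0.6
    val: float = 0.2
    test: float = 0.2

    def __post_init__(self):
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split ratios must be non-negative")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def split_sizes(n: int, ratios: SplitRatios) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n records to train/val/test."""
    quotas = np.array([ratios.train, ratios.val, ratios.test]) * n
    sizes = np.floor(quotas).astype(int)
    frac = quotas - sizes
    # ties broken in train, val, test order (stable sort on -fraction)
    for idx in np.argsort(-frac, kind="stable")[: n - sizes.sum()]:
        sizes[idx] += 1
    return tuple(int(s) for s in sizes)


def split_manifest(manifest, ratios: SplitRatios, seed: int):
    """Assign splits by a seeded global permutation; returns a new manifest."""
    from .cytosim import DatasetManifest  # local import to avoid a cycle

    frame = manifest.frame if isinstance(manifest, DatasetManifest) else manifest
    if not (frame["split"] == "unassigned").all():
        raise ValueError("manifest records must all be unassigned before splitting")
    n = len(frame)
    n_train, n_val, _ = split_sizes(n, ratios)
    order = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_val]] = "val"
    split[order[n_train + n_val :]] = "test"
    out = frame.copy()
    out["split"] = split
    if isinstance(manifest, DatasetManifest):
        return DatasetManifest(out, generator_seed=manifest.generator_seed)
    return out
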