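"""Per-slice normalization, volume-level augmentation, and slice tiling.

The evaluation-time pipeline is deterministic: robust contrast stretching
(2nd/98th percentile), bilinear resize to the backbone's input side, gray
channel replication to three channels, and fixed per-channel normalization
(means 0.485/0.456/0.406, stds 0.229/0.224/0.225) so weights transferred
from natural-image pretraining remain compatible. Stochastic augmentations
(horizontal flip, random resized crop) are sampled once per volume and
applied identically to every slice, preserving the 3D structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume_data import Volume

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class AugmentPolicy:
    """Volume-level stochastic augmentation parameters.

    Crop defaults are the conventional random-resized-crop ranges:
    scale (0.08, 1.0) of the source area and aspect ratio (3/4, 4/3).
    """

    horizontal_flip_prob: float = 0.5
    crop_scale_range: tuple = (0.08, 1.0)
    crop_ratio_range: tuple = (0.75, 4.0 / 3.0)
    crop_enabled: bool = True
    enabled: bool = True

    def __post_init__(self):
        if not (0.0 <= self.horizontal_flip_prob <= 1.0):
            raise ValueError("flip probability must lie in [0, 1]")
        for lo, hi in (self.crop_scale_range, self.crop_ratio_range):
            if not (0 < lo <= hi):
                raise ValueError("range bounds must satisfy 0 < lo <= hi")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key in ("crop_scale_range", "crop_ratio_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ElongatedImage:
    """The (N*side) x side x 3 image formed by vertically tiling slices."""

    pixels: np.ndarray
    n_slices: int

    @property
    def slice_row_span(self) -> int:
        return self.pixels.shape[0] // self.n_slices

    def slice_block(self, i: int) -> np.ndarray:
        s = self.slice_row_span
        return self.pixels[i * s:(i + 1) * s]


def contrast_stretch(frame: np.ndarray) -> np.ndarray:
    """Linearly map the 2nd..98th percentile range to [0, 1], clipping tails.

    Constant frames (and frames whose percentiles coincide) come back as
    all-zeros rather than dividing by zero.
    """
    frame = np.asarray(frame, dtype=np.float32)
    if not np.all(np.isfinite(frame)):
        raise ValueError("non-finite frame")
    lo, hi = np.percentile(frame, [2.0, 98.0])
    if hi <= lo:
        return np.zeros_like(frame)
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def standardize_slice(frame: np.ndarray, side: int = 256, normalize: bool = True) -> np.ndarray:
    """Resize to side x side (bilinear), replicate to 3 channels, normalize."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim != 2 or min(frame.shape) < 2:
        raise ValueError("frame must be a 2D array of at least 2x2")
    if not np.all(np.isfinite(frame)):
        raise ValueError("non-finite frame")
    if frame.shape != (side, side):
        frame = _sk_resize(frame, (side, side), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True).astype(np.float32)
    rgb = np.repeat(frame[:, :, None], 3, axis=2)
    if normalize:
        rgb = (rgb - IMAGENET_MEAN) / IMAGENET_STD
    return rgb.astype(np.float32)


def _sample_crop(rng: np.random.Generator, h: int, w: int, policy: AugmentPolicy):
    """Draw a random-resized-crop window; center crop as the fallback."""
    area = h * w
    log_lo, log_hi = math.log(policy.crop_ratio_range[0]), math.log(policy.crop_ratio_range[1])
    for _ in range(10):
        target = area * rng.uniform(*policy.crop_scale_range)
        ratio = math.exp(rng.uniform(log_lo, log_hi))
        cw = int(round(math.sqrt(target * ratio)))
        ch = int(round(math.sqrt(target / ratio)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            return top, left, ch, cw
    side = min(h, w)
    return (h - side) // 2, (w - side) // 2, side, side


def augment_volume(volume: Volume, policy: AugmentPolicy, seed: int) -> Volume:
    """Apply ONE sampled geometric transform identically to every slice."""
    if not policy.enabled:
        return volume
    rng = np.random.default_rng(seed)
    frames = volume.frames
    n, h, w = frames.shape
    flip = rng.random() < policy.horizontal_flip_prob
    if policy.crop_enabled:
        top, left, ch, cw = _sample_crop(rng, h, w, policy)
        cropped = frames[:, top:top + ch, left:left + cw]
        if (ch, cw) != (h, w):
            out = np.stack([
                _sk_resize(f, (h, w), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
                for f in cropped
            ]).astype(np.float32)
        else:
            out = cropped.astype(np.float32)
    else:
        out = frames
    if flip:
        out = out[:, :, ::-1]
    return Volume(volume.id, np.ascontiguousarray(out))


def tile_volume(frames_or_volume) -> ElongatedImage:
    """Vertically concatenate standardized (side x side x 3) slices.

    Accepts either an (N, side, side, 3) array of standardized slices or a
    list of such slices. Row block i of the result derives solely from
    slice i.
    """
    if isinstance(frames_or_volume, Volume):
        raise TypeError("tile_volume expects standardized slices; run standardize_volume first")
    stack = np.asarray(frames_or_volume, dtype=np.float32)
    if stack.ndim != 4 or stack.shape[3] != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError(f"expected (N, side, side, 3) standardized slices, got {stack.shape}")
    n = stack.shape[0]
    side = stack.shape[1]
    pixels = stack.reshape(n * side, side, 3)
    return ElongatedImage(pixels=pixels, n_slices=n)


def standardize_volume(volume: Volume, side: int = 256, stretch: bool = True,
                       normalize: bool = True) -> np.ndarray:
    """Deterministic per-slice pipeline -> (N, side, side, 3) array."""
    out = np.empty((volume.n_frames, side, side, 3), dtype=np.float32)
    for i, frame in enumerate(volume.frames):
        f = contrast_stretch(frame) if stretch else frame
        out[i] = standardize_slice(f, side=side, normalize=normalize)
    return out


def prepare_volume(volume: Volume, side: int = 256, stretch: bool = True,
                   normalize: bool = True, policy: AugmentPolicy | None = None,
                   seed: int = 0) -> ElongatedImage:
    """Full pipeline: (augment) -> stretch -> resize/normalize -> tile."""
    if policy is not None and policy.enabled:
        volume = augment_volume(volume, policy, seed)
    return tile_volume(standardize_volume(volume, side=side, stretch=stretch,
                                          normalize=normalize))
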