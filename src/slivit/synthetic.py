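"""Synthetic volumetric datasets with the statistical structure of the three
target modalities, so the whole pipeline trains and evaluates with no
downloads.

Generated at desk scale by default (64x64 frames, 16 slices per volume,
a few hundred volumes) with anti-aliased analytic masks:

* ``gen_pretrain_images`` — four separable 2D texture classes (horizontal
  bands, bright blobs, speckle, smooth gradient) for backbone pretraining.
* ``gen_structural_volumes`` — OCT-biomarker analog: a bright lesion whose
  slice extent and per-slice area are drawn independently; the binary label
  is defined by total lesion voxel volume exceeding a threshold, so no
  single slice determines it.
* ``gen_dynamic_videos`` — echocardiogram analog: a dark chamber whose area
  oscillates across frames with random phase and period; the continuous
  target is the fractional area change (A_max - A_min)/A_max of the
  generated frame sequence.
* ``gen_slab_volumes`` — fat-fraction analog: a stored fraction of voxels
  drawn from a bright intensity distribution, varying slice to slice around
  the volume mean.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_data import LabeledDataset, LabelTable, Volume, make_split


@dataclass
class SyntheticSpec:
    task: str  # pretrain_2d | biomarker_cls | dynamic_reg | slab_reg
    n_volumes: int = 300
    n_frames: int = 16
    frame_side: int = 64
    noise_sigma: float = 0.05
    seed: int = 0
    # biomarker_cls effect parameters
    lesion_base_radius: float = 20.0
    lesion_scale_range: tuple = (0.75, 1.25)
    lesion_slices_range: tuple = (3, 12)
    lesion_threshold: float = 1256.0
    lesion_contrast: float = 0.5
    # dynamic_reg effect parameters
    amplitude_range: tuple = (0.15, 0.7)
    period_range: tuple = (10.0, 14.0)
    # slab_reg effect parameters
    fat_fraction_range: tuple = (0.02, 0.5)
    slice_fraction_jitter: float = 0.03
    # split
    split_fractions: tuple = (0.7, 0.15, 0.15)

    def __post_init__(self):
        if min(self.n_volumes, self.n_frames, self.frame_side) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _disc_mask(side: int, cy: float, cx: float, r: float) -> np.ndarray:
    """Anti-aliased disc: 1 inside, 0 outside, linear ramp across the edge."""
    yy, xx = np.mgrid[0:side, 0:side]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return np.clip(r - dist + 0.5, 0.0, 1.0).astype(np.float32)


def _ellipse_mask(side: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    # signed distance approximation via normalized radius
    rho = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    edge = min(ry, rx)
    return np.clip((1.0 - rho) * edge + 0.5, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# 2D pretraining images

def gen_pretrain_images(spec: SyntheticSpec):
    """Balanced 4-class image set -> (images (n, side, side), labels (n,))."""
    if spec.task != "pretrain_2d":
        raise ValueError("spec.task must be 'pretrain_2d'")
    rng = np.random.default_rng(spec.seed)
    side = spec.frame_side
    n = spec.n_volumes
    per_class = n // 4
    counts = [per_class + (1 if c < n % 4 else 0) for c in range(4)]
    images, labels = [], []
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)
    for cls, cnt in enumerate(counts):
        for _ in range(cnt):
            if cls == 0:  # horizontal bands
                freq = rng.uniform(2, 6)
                phase = rng.uniform(0, 2 * np.pi)
                img = 0.5 + 0.35 * np.sin(2 * np.pi * freq * yy / side + phase)
            elif cls == 1:  # bright blobs
                img = np.full((side, side), 0.3, dtype=np.float32)
                for _ in range(rng.integers(2, 6)):
                    cy, cx = rng.uniform(8, side - 8, size=2)
                    r = rng.uniform(4, 9)
                    img = np.maximum(img, 0.3 + 0.6 * _disc_mask(side, cy, cx, r))
            elif cls == 2:  # speckle
                img = 0.5 + 0.4 * np.sign(rng.standard_normal((side, side)))
                img = img.astype(np.float32)
            else:  # smooth gradient, random direction
                theta = rng.uniform(0, 2 * np.pi)
                proj = np.cos(theta) * xx + np.sin(theta) * yy
                proj = (proj - proj.min()) / (proj.max() - proj.min())
                img = 0.15 + 0.7 * proj
            img = img + rng.normal(0, spec.noise_sigma, (side, side))
            images.append(np.clip(img, 0, 1).astype(np.float32))
            labels.append(cls)
    order = rng.permutation(len(images))
    return (np.stack([images[i] for i in order]),
            np.asarray([labels[i] for i in order], dtype=np.int64))


# ---------------------------------------------------------------------------
# Structural-biomarker volumes (binary)

def gen_structural_volumes(spec: SyntheticSpec) -> LabeledDataset:
    """Bright-lesion volumes labeled by total lesion voxel volume > threshold.

    Per-slice radius is drawn as base_radius * u / sqrt(n_slices) with the
    overall scale u and the slice extent n_slices independent, so the total
    lesion volume (≈ pi * base_radius^2 * u^2) carries the label while the
    extent does not: short lesions have large cross-sections and long
    lesions medium ones, and their per-slice area distributions overlap on
    both sides of the threshold. No single slice — neither its presence nor
    its area — determines the label.
    """
    if spec.task != "biomarker_cls":
        raise ValueError("spec.task must be 'biomarker_cls'")
    side, nf = spec.frame_side, spec.n_frames
    s_lo, s_hi = spec.lesion_slices_range
    u_lo, u_hi = spec.lesion_scale_range
    r_max = spec.lesion_base_radius * u_hi / np.sqrt(s_lo)
    if r_max * 2 + 4 > side or s_hi > nf:
        raise ValueError("lesion larger than the volume")
    rng = np.random.default_rng(spec.seed)
    volumes, rows = {}, []
    for i in range(spec.n_volumes):
        vid = f"vol{i:04d}"
        frames = rng.normal(0.25, spec.noise_sigma, (nf, side, side)).astype(np.float32)
        n_sl = int(rng.integers(s_lo, s_hi + 1))
        u = rng.uniform(u_lo, u_hi)
        r_mean = spec.lesion_base_radius * u / np.sqrt(n_sl)
        z0 = int(rng.integers(0, nf - n_sl + 1))
        cy = rng.uniform(r_max + 2, side - r_max - 2)
        cx = rng.uniform(r_max + 2, side - r_max - 2)
        voxels = 0
        for j in range(n_sl):
            r_j = r_mean * rng.uniform(0.9, 1.1)
            mask = _disc_mask(side, cy, cx, r_j)
            voxels += int((mask > 0.5).sum())
            frames[z0 + j] += spec.lesion_contrast * mask
        label = int(voxels > spec.lesion_threshold)
        volumes[vid] = Volume(vid, np.clip(frames, 0, 1))
        rows.append((vid, label, voxels))
    table = pd.DataFrame(rows, columns=["id", "label", "lesion_voxels"]).set_index("id")
    split = make_split(list(volumes), spec.split_fractions, seed=spec.seed + 1)
    return LabeledDataset(volumes=volumes, labels=LabelTable(table), split=split,
                          meta={"task": "biomarker_cls", "spec_seed": spec.seed})


# ---------------------------------------------------------------------------
# Dynamic "videos" (continuous fractional-change target)

def gen_dynamic_videos(spec: SyntheticSpec) -> LabeledDataset:
    """Dark oscillating chamber; target = (A_max - A_min)/A_max over frames.

    Phase is random, so no single frame reveals where in the cycle it sits;
    recovering the target requires comparing areas across frames.
    """
    if spec.task != "dynamic_reg":
        raise ValueError("spec.task must be 'dynamic_reg'")
    side, nf = spec.frame_side, spec.n_frames
    rng = np.random.default_rng(spec.seed)
    volumes, rows = {}, []
    t = np.arange(nf)
    for i in range(spec.n_volumes):
        vid = f"vid{i:04d}"
        ry = rng.uniform(9, 13)
        rx = rng.uniform(7, 11)
        cy = side / 2 + rng.uniform(-6, 6)
        cx = side / 2 + rng.uniform(-6, 6)
        ef = rng.uniform(*spec.amplitude_range)
        period = rng.uniform(*spec.period_range)
        phase = rng.uniform(0, 2 * np.pi)
        # chamber area over the cycle; A_max at cos = -1
        frac = 1.0 - ef * (1.0 + np.cos(2 * np.pi * t / period + phase)) / 2.0
        frames = rng.normal(0.65, spec.noise_sigma, (nf, side, side)).astype(np.float32)
        areas = np.empty(nf)
        for j in range(nf):
            s = np.sqrt(frac[j])
            mask = _ellipse_mask(side, cy, cx, ry * s, rx * s)
            areas[j] = float(mask.sum())
            frames[j] -= 0.5 * mask
        target = float((areas.max() - areas.min()) / areas.max())
        volumes[vid] = Volume(vid, np.clip(frames, 0, 1))
        rows.append((vid, target))
    table = pd.DataFrame(rows, columns=["id", "target"]).set_index("id")
    split = make_split(list(volumes), spec.split_fractions, seed=spec.seed + 1)
    return LabeledDataset(volumes=volumes, labels=LabelTable(table), split=split,
                          meta={"task": "dynamic_reg", "spec_seed": spec.seed})


# ---------------------------------------------------------------------------
# Textured slabs (continuous intensity-fraction target)

def gen_slab_volumes(spec: SyntheticSpec) -> LabeledDataset:
    """Two-component texture; target = fraction of bright ('fat') voxels."""
    if spec.task != "slab_reg":
        raise ValueError("spec.task must be 'slab_reg'")
    f_lo, f_hi = spec.fat_fraction_range
    if not (0 <= f_lo <= f_hi <= 1):
        raise ValueError("fat fractions must lie in [0, 1]")
    side, nf = spec.frame_side, spec.n_frames
    rng = np.random.default_rng(spec.seed)
    volumes, rows = {}, []
    for i in range(spec.n_volumes):
        vid = f"slab{i:04d}"
        f = rng.uniform(f_lo, f_hi)
        frames = np.empty((nf, side, side), dtype=np.float32)
        for j in range(nf):
            f_j = float(np.clip(f + rng.normal(0, spec.slice_fraction_jitter), 0, 1))
            fat = rng.random((side, side)) < f_j
            tissue = rng.normal(0.3, 0.05, (side, side))
            bright = rng.normal(0.8, 0.05, (side, side))
            frames[j] = np.where(fat, bright, tissue)
        volumes[vid] = Volume(vid, np.clip(frames, 0, 1))
        rows.append((vid, f))
    table = pd.DataFrame(rows, columns=["id", "target"]).set_index("id")
    split = make_split(list(volumes), spec.split_fractions, seed=spec.seed + 1)
    return LabeledDataset(volumes=volumes, labels=LabelTable(table), split=split,
                          meta={"task": "slab_reg", "spec_seed": spec.seed})


# ---------------------------------------------------------------------------
# Frame-order shuffling

def shuffle_copies(dataset: LabeledDataset, m: int, seed: int) -> list:
    """m copies of the dataset with every volume's frame order permuted.

    Labels and the split are unchanged; permutations are reproducible from
    the seed and independent across copies and volumes.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    copies = []
    for _ in range(m):
        vols = {}
        for vid, vol in dataset.volumes.items():
            perm = rng.permutation(vol.n_frames)
            vols[vid] = Volume(vid, vol.frames[perm])
        copies.append(LabeledDataset(volumes=vols, labels=dataset.labels,
                                     split=dataset.split,
                                     meta={**dataset.meta, "shuffled": True}))
    return copies


# ---------------------------------------------------------------------------
# Disk round-trip (NPZ volumes + CSV labels/split, readable by volume_data)

def write_dataset(dataset: LabeledDataset, out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for vid, vol in dataset.volumes.items():
        np.savez(out_dir / f"{vid}.npz", volume=vol.frames)
    dataset.labels.table.reset_index().to_csv(out_dir / "labels.csv", index=False)
    if dataset.split is not None:
        dataset.split.save(out_dir / "split.csv")
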