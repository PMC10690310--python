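"""Volume and label-table IO, frame-count standardization, and dataset splits.

A :class:`Volume` is an ordered stack of N grayscale frames. Loaders accept
NIfTI, multi-page TIFF, directories of PNG/JPEG frames (lexicographic order)
and NPZ archives with a single 3D array under the key ``"volume"``; integer
intensities are rescaled to [0, 1] by the dtype maximum.

Split sizes follow a floor-based rounding rule: the train count is
``floor(f_train * n)``; when the validation and test fractions are equal the
remainder is halved with the floor going to validation. This single rule
yields 483/104/104 from n=691 at 70/15/15 and 5972/1991/1991 from n=9954 at
60/20/20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d


@dataclass
class Volume:
    """Ordered stack of N grayscale frames of identical shape H x W."""

    id: str
    frames: np.ndarray  # (N, H, W) float32 in [0, 1]

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"volume {self.id!r}: frames must be a non-empty (N, H, W) stack")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError(f"volume {self.id!r}: non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class LabelTable:
    """Per-volume labels keyed by volume id; binary columns hold {0, 1}."""

    table: pd.DataFrame  # indexed by id
    n_dropped: int = 0

    def labels_for(self, ids, column: str) -> np.ndarray:
        return self.table.loc[list(ids), column].to_numpy(dtype=np.float64)

    @property
    def ids(self):
        return list(self.table.index)


@dataclass
class SplitAssignment:
    train_ids: list
    val_ids: list
    test_ids: list
    fractions: tuple
    seed: int

    def sizes(self) -> tuple:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))

    def to_frame(self) -> pd.DataFrame:
        rows = ([(i, "train") for i in self.train_ids]
                + [(i, "val") for i in self.val_ids]
                + [(i, "test") for i in self.test_ids])
        return pd.DataFrame(rows, columns=["id", "split"])

    def save(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass
class LabeledDataset:
    """Volumes plus their label table and split assignment."""

    volumes: dict  # id -> Volume
    labels: LabelTable
    split: SplitAssignment | None = None
    meta: dict = field(default_factory=dict)

    @property
    def ids(self):
        return list(self.volumes)

    def subset(self, ids):
        return [self.volumes[i] for i in ids]


# ---------------------------------------------------------------------------
# Loaders

def _rescale(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float32) / np.iinfo(arr.dtype).max
    return arr.astype(np.float32)


def read_volume(path, format: str, volume_id: str | None = None) -> Volume:
    """Read a volume from disk. ``format`` is one of nifti/tiff_stack/png_dir/npz."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vid = volume_id if volume_id is not None else path.stem.split(".")[0]

    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI, got shape {arr.shape}")
        # store slices along the first axis
        frames = np.moveaxis(arr, -1, 0)
    elif format == "tiff_stack":
        import tifffile

        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"{path}: expected a grayscale multi-page TIFF, got shape {frames.shape}")
    elif format == "png_dir":
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise ValueError(f"{path}: no image frames found")
        slices = []
        for f in files:
            frame = iio.imread(f)
            if frame.ndim == 3:  # collapse any color channels
                frame = frame.mean(axis=-1)
            slices.append(frame)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"{path}: inconsistent frame shapes {shapes}")
        return Volume(vid, np.stack([_rescale(s) for s in slices]))
    elif format == "npz":
        with np.load(path) as data:
            if "volume" not in data:
                raise ValueError(f"{path}: NPZ must contain a 'volume' array")
            frames = data["volume"]
        if frames.ndim != 3:
            raise ValueError(f"{path}: 'volume' must be 3D, got shape {frames.shape}")
    else:
        raise ValueError(f"unknown format {format!r}")

    if frames.shape[0] == 0:
        raise ValueError(f"{path}: zero frames")
    return Volume(vid, _rescale(frames))


def load_labels(path, id_column: str, label_columns) -> LabelTable:
    """Load a label CSV restricted to the requested columns.

    Rows with missing values in the requested columns are dropped (and
    counted); duplicate ids or non-numeric label cells raise.
    """
    label_columns = list(label_columns)
    df = pd.read_csv(path)
    if df[id_column].duplicated().any():
        dups = df[id_column][df[id_column].duplicated()].tolist()
        raise ValueError(f"duplicate ids in label table: {dups[:5]}")
    sub = df[[id_column] + label_columns].copy()
    for col in label_columns:
        vals = pd.to_numeric(sub[col], errors="coerce")
        bad = vals.isna() & sub[col].notna()
        if bad.any():
            raise ValueError(f"non-numeric values in label column {col!r}")
        sub[col] = vals
    n_before = len(sub)
    sub = sub.dropna(subset=label_columns)
    sub = sub.set_index(id_column)
    for col in label_columns:
        vals = sub[col].to_numpy()
        uniq = np.unique(vals)
        if set(uniq) <= {0.0, 1.0}:
            sub[col] = vals.astype(np.int64)
        elif not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in label column {col!r}")
    return LabelTable(sub, n_dropped=n_before - len(sub))


# ---------------------------------------------------------------------------
# Frame-count standardization

def sample_equally_spaced(volume: Volume, k: int) -> Volume:
    """Keep k frames at indices round(i*(N-1)/(k-1)); endpoints included.

    Videos of arbitrary length are standardized this way (echocardiograms
    to 32 frames, for instance). When N < k the rounded indices repeat.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = volume.n_frames
    if k == 1:
        idx = np.array([0])
    else:
        # numpy rounding is round-half-to-even, matching the index contract
        idx = np.round(np.arange(k) * (n - 1) / (k - 1)).astype(int)
    return Volume(volume.id, volume.frames[idx])


def decimate_every_other(volume: Volume, antialias: bool = True) -> Volume:
    """Keep even-indexed frames (N -> ceil(N/2)), e.g. 97 B-scans -> 49.

    With ``antialias``, a depth-only Gaussian (sigma = 1 slice, truncated at
    two sigma, reflective boundary) is applied along the slice axis first.
    """
    frames = volume.frames
    if antialias and volume.n_frames > 1:
        frames = gaussian_filter1d(frames, sigma=1.0, axis=0, truncate=2.0, mode="reflect")
    return Volume(volume.id, frames[::2])


# ---------------------------------------------------------------------------
# Splits and subsampling

def make_split(ids, fractions, seed: int) -> SplitAssignment:
    """Deterministic shuffled split with the floor/equal-remainder rule."""
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 ids to split")
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(np.array(ids, dtype=object)[rng.permutation(n)])
    n_train = math.floor(f_train * n)
    rem = n - n_train
    if abs(f_val - f_test) < 1e-12:
        n_val = rem // 2
    else:
        n_val = math.floor(f_val * n)
    n_test = n - n_train - n_val
    return SplitAssignment(
        train_ids=order[:n_train],
        val_ids=order[n_train:n_train + n_val],
        test_ids=order[n_train + n_val:n_train + n_val + n_test],
        fractions=tuple(fractions),
        seed=seed,
    )


def subsample_indices(ids, fraction: float, seed: int) -> list:
    """Sample floor(fraction * n) ids without replacement, seeded."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ids = list(ids)
    k = math.floor(fraction * len(ids))
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(len(ids))[:k]
    return [ids[i] for i in chosen]


def binarize_ef(ef: float) -> int:
    """1 (cardiomyopathy) iff ejection fraction < 0.5; >= 0.5 is normal."""
    if not (0.0 <= ef <= 1.0):
        raise ValueError("ejection fraction must lie in [0, 1]")
    return int(ef < 0.5)


def load_split(path) -> SplitAssignment:
    df = pd.read_csv(path)
    groups = {k: list(v) for k, v in df.groupby("split")["id"]}
    return SplitAssignment(
        train_ids=groups.get("train", []),
        val_ids=groups.get("val", []),
        test_ids=groups.get("test", []),
        fractions=(0, 0, 0),
        seed=-1,
    )
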