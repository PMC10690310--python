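"""Volume IO, frame standardization, and split arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slivit import (Volume, binarize_ef, decimate_every_other, load_labels,
                    load_split, make_split, read_volume, sample_equally_spaced,
                    subsample_indices)


class TestReadVolume:
    def test_tiff_stack(self, tmp_path):
        import tifffile

        arr = (np.random.default_rng(0).random((49, 64, 64)) * 255).astype(np.uint8)
        path = tmp_path / "vol.tif"
        tifffile.imwrite(path, arr)
        vol = read_volume(path, "tiff_stack")
        assert vol.n_frames == 49 and vol.frame_shape == (64, 64)
        assert vol.frames.max() <= 1.0 and vol.frames.min() >= 0.0
        np.testing.assert_allclose(vol.frames, arr / 255.0, atol=1e-6)

    def test_png_dir_lexicographic_order(self, tmp_path):
        import imageio.v3 as iio

        d = tmp_path / "frames"
        d.mkdir()
        for i in range(32):
            iio.imwrite(d / f"{i:03d}.png",
                        np.full((16, 16), i * 8, dtype=np.uint8))
        vol = read_volume(d, "png_dir")
        assert vol.n_frames == 32
        # frame i must come from file i (constant value i*8/255)
        np.testing.assert_allclose(vol.frames[:, 0, 0],
                                   np.arange(32) * 8 / 255.0, atol=1e-6)

    def test_npz_mri_series_shape(self, tmp_path):
        # a 36-slice abdominal series at 284x288
        arr = np.random.default_rng(1).random((36, 284, 288)).astype(np.float32)
        path = tmp_path / "vol.npz"
        np.savez(path, volume=arr)
        vol = read_volume(path, "npz")
        assert vol.n_frames == 36 and vol.frame_shape == (284, 288)

    def test_nifti(self, tmp_path):
        import nibabel as nib

        arr = np.random.default_rng(2).random((32, 32, 7)).astype(np.float32)
        path = tmp_path / "vol.nii.gz"
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
        vol = read_volume(path, "nifti")
        assert vol.n_frames == 7 and vol.frame_shape == (32, 32)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.tif", "tiff_stack")

    def test_inconsistent_shapes(self, tmp_path):
        import imageio.v3 as iio

        d = tmp_path / "bad"
        d.mkdir()
        iio.imwrite(d / "000.png", np.zeros((8, 8), dtype=np.uint8))
        iio.imwrite(d / "001.png", np.zeros((9, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            read_volume(d, "png_dir")

    def test_zero_frames(self, tmp_path):
        np.savez(tmp_path / "empty.npz", volume=np.zeros((0, 8, 8)))
        with pytest.raises(ValueError):
            read_volume(tmp_path / "empty.npz", "npz")


class TestLoadLabels:
    def _write(self, tmp_path, df):
        path = tmp_path / "labels.csv"
        df.to_csv(path, index=False)
        return path

    def test_binary_biomarker_columns(self, tmp_path):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"id": [f"v{i}" for i in range(691)]}
                          | {c: rng.integers(0, 2, 691)
                             for c in ("DV", "IHRF", "SDD", "hDC")})
        table = load_labels(self._write(tmp_path, df), "id",
                            ["DV", "IHRF", "SDD", "hDC"])
        assert len(table.table) == 691
        for c in ("DV", "IHRF", "SDD", "hDC"):
            assert set(np.unique(table.table[c])) <= {0, 1}

    def test_continuous_ef_range(self, tmp_path):
        df = pd.DataFrame({"id": ["a", "b", "c"], "EF": [0.069, 0.558, 0.97]})
        table = load_labels(self._write(tmp_path, df), "id", ["EF"])
        np.testing.assert_allclose(table.labels_for(["a", "c"], "EF"), [0.069, 0.97])

    def test_missing_row_dropped_and_counted(self, tmp_path):
        df = pd.DataFrame({"id": ["a", "b", "c"], "EF": [0.4, None, 0.6]})
        table = load_labels(self._write(tmp_path, df), "id", ["EF"])
        assert len(table.table) == 2 and table.n_dropped == 1

    def test_duplicate_ids_error(self, tmp_path):
        df = pd.DataFrame({"id": ["a", "a"], "EF": [0.4, 0.5]})
        with pytest.raises(ValueError, match="duplicate"):
            load_labels(self._write(tmp_path, df), "id", ["EF"])

    def test_non_numeric_error(self, tmp_path):
        df = pd.DataFrame({"id": ["a", "b"], "EF": [0.4, "high"]})
        with pytest.raises(ValueError, match="non-numeric"):
            load_labels(self._write(tmp_path, df), "id", ["EF"])


class TestSampleEquallySpaced:
    def _vol(self, n):
        # frame j is constant j so sampled indices are readable off the data
        return Volume("v", np.tile(np.arange(n, dtype=np.float32)[:, None, None] / max(n, 1),
                                   (1, 4, 4)))

    def _indices(self, vol, n):
        return np.round(vol.frames[:, 0, 0] * n).astype(int)

    def test_identity_when_k_equals_n(self):
        vol = self._vol(32)
        out = sample_equally_spaced(vol, 32)
        np.testing.assert_array_equal(self._indices(out, 32), np.arange(32))

    def test_exact_stride_two(self):
        out = sample_equally_spaced(self._vol(63), 32)
        np.testing.assert_array_equal(self._indices(out, 63), np.arange(0, 63, 2))

    def test_long_video_first_indices(self):
        # round(i * 1001 / 31) for i = 0, 1, 2 -> 0, 32, 65
        out = sample_equally_spaced(self._vol(1002), 32)
        assert list(self._indices(out, 1002)[:3]) == [0, 32, 65]

    def test_k_one_takes_first_frame(self):
        out = sample_equally_spaced(self._vol(10), 1)
        assert out.n_frames == 1 and self._indices(out, 10)[0] == 0

    def test_short_video_repeats_frames(self):
        out = sample_equally_spaced(self._vol(5), 8)
        assert out.n_frames == 8
        idx = self._indices(out, 5)
        assert idx[0] == 0 and idx[-1] == 4 and np.all(np.diff(idx) >= 0)

    def test_k_nonpositive_error(self):
        with pytest.raises(ValueError):
            sample_equally_spaced(self._vol(5), 0)

    @settings(deadline=None, max_examples=30)
    @given(n=st.integers(2, 120), k=st.integers(2, 40))
    def test_idempotent(self, n, k):
        vol = self._vol(n)
        once = sample_equally_spaced(vol, k)
        twice = sample_equally_spaced(once, k)
        np.testing.assert_array_equal(once.frames, twice.frames)


class TestDecimate:
    def test_97_to_49(self):
        vol = Volume("v", np.random.default_rng(0).random((97, 8, 8)))
        assert decimate_every_other(vol).n_frames == 49

    def test_two_to_one_keeps_first(self):
        frames = np.stack([np.zeros((4, 4)), np.ones((4, 4))])
        out = decimate_every_other(Volume("v", frames), antialias=False)
        assert out.n_frames == 1 and out.frames[0].max() == 0.0

    def test_no_antialias_keeps_even_frames_exactly(self):
        frames = np.random.default_rng(1).random((11, 6, 6)).astype(np.float32)
        out = decimate_every_other(Volume("v", frames), antialias=False)
        np.testing.assert_array_equal(out.frames, frames[::2])

    def test_length_is_ceil_half(self):
        for n in range(1, 201):
            vol = Volume("v", np.zeros((n, 2, 2), dtype=np.float32))
            assert decimate_every_other(vol).n_frames == -(-n // 2)

    def test_filter_preserves_constant_volume(self):
        frames = np.full((12, 5, 5), 0.37, dtype=np.float32)
        out = decimate_every_other(Volume("v", frames), antialias=True)
        np.testing.assert_allclose(out.frames, 0.37, atol=1e-6)


class TestMakeSplit:
    @pytest.mark.parametrize("n,fractions,expected", [
        (691, (0.70, 0.15, 0.15), (483, 104, 104)),
        (9954, (0.60, 0.20, 0.20), (5972, 1991, 1991)),
        (10, (0.5, 0.25, 0.25), (5, 2, 3)),
    ])
    def test_printed_size_triples(self, n, fractions, expected):
        split = make_split([f"i{k}" for k in range(n)], fractions, seed=0)
        assert split.sizes() == expected

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(3, 500), seed=st.integers(0, 2 ** 16))
    def test_partition(self, n, seed):
        ids = [f"i{k}" for k in range(n)]
        split = make_split(ids, (0.7, 0.15, 0.15), seed=seed)
        parts = [set(split.train_ids), set(split.val_ids), set(split.test_ids)]
        assert parts[0] | parts[1] | parts[2] == set(ids)
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) \
            and not (parts[1] & parts[2])
        assert sum(split.sizes()) == n

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"i{k}" for k in range(100)]
        a = make_split(ids, (0.7, 0.15, 0.15), seed=5)
        b = make_split(ids, (0.7, 0.15, 0.15), seed=5)
        c = make_split(ids, (0.7, 0.15, 0.15), seed=6)
        assert a.train_ids == b.train_ids
        assert a.train_ids != c.train_ids

    def test_errors(self):
        with pytest.raises(ValueError):
            make_split(["a", "b"], (0.5, 0.25, 0.25), 0)
        with pytest.raises(ValueError):
            make_split(list("abcdef"), (1.0, 0.0, 0.0), 0)
        with pytest.raises(ValueError):
            make_split(list("abcdef"), (0.5, 0.3, 0.3), 0)

    def test_csv_round_trip(self, tmp_path):
        split = make_split([f"i{k}" for k in range(30)], (0.7, 0.15, 0.15), 3)
        split.save(tmp_path / "split.csv")
        loaded = load_split(tmp_path / "split.csv")
        assert set(loaded.train_ids) == set(split.train_ids)
        assert set(loaded.test_ids) == set(split.test_ids)


class TestSubsample:
    def test_quarter_of_echo_train_split(self):
        ids = [f"i{k}" for k in range(7465)]
        assert len(subsample_indices(ids, 0.25, seed=0)) == 1866

    def test_full_fraction_returns_all(self):
        ids = [f"i{k}" for k in range(7465)]
        assert sorted(subsample_indices(ids, 1.0, seed=0)) == sorted(ids)

    def test_half_is_subset_without_repeats(self):
        ids = [f"i{k}" for k in range(100)]
        sub = subsample_indices(ids, 0.5, seed=1)
        assert len(sub) == 50 and len(set(sub)) == 50 and set(sub) <= set(ids)

    def test_fraction_bounds(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                subsample_indices(["a", "b"], bad, 0)


class TestBinarizeEF:
    @pytest.mark.parametrize("ef,label", [(0.5, 0), (0.069, 1), (0.97, 0),
                                          (0.499, 1)])
    def test_threshold(self, ef, label):
        assert binarize_ef(ef) == label

    def test_out_of_range(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                binarize_ef(bad)
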