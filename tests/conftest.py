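import numpy as np
import pytest

from slivit import (SyntheticSpec, Volume, gen_structural_volumes,
                    gen_dynamic_videos)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_volume():
    r = np.random.default_rng(7)
    return Volume("v0", r.random((12, 40, 48)).astype(np.float32))


@pytest.fixture(scope="session")
def tiny_structural_dataset():
    """60 volumes, 8 slices of 32x32 — plumbing-scale classification data."""
    spec = SyntheticSpec(task="biomarker_cls", n_volumes=60, n_frames=8,
                         frame_side=32, lesion_base_radius=8.0,
                         lesion_slices_range=(2, 6), lesion_threshold=200.0,
                         seed=42)
    return gen_structural_volumes(spec)


@pytest.fixture(scope="session")
def tiny_dynamic_dataset():
    spec = SyntheticSpec(task="dynamic_reg", n_volumes=48, n_frames=12,
                         frame_side=32, seed=43)
    return gen_dynamic_videos(spec)
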