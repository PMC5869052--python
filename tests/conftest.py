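import numpy as np
import pytest

from voxpipe.phantoms import PhantomSpec, write_phantom_dataset
from voxpipe.volume_io import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(arr, section="image", spacing=(1.0, 1.0, 1.0), n_channels=None):
    """Wrap a plain array as an ImageVolume with a diagonal affine."""
    arr = np.asarray(arr)
    affine = np.diag(list(spacing) + [1.0])
    names = None
    if arr.ndim == 5:
        names = [f"modality{i}" for i in range(arr.shape[4])]
    return ImageVolume(arr, affine, section=section,
                       modality_names=names or ["modality0"])


def dyadic(rng, shape, denom=16, high=32):
    """Random array of small dyadic rationals: sums and means stay exact."""
    return rng.integers(0, high, size=shape).astype(np.float64) / denom


@pytest.fixture(scope="session")
def seg_dataset(tmp_path_factory):
    """A small on-disk phantom dataset (3 subjects, image+label)."""
    out = tmp_path_factory.mktemp("segdata")
    spec = PhantomSpec(shape=(24, 24, 24), n_organs=2, noise_sd=0.05, seed=7)
    manifest = write_phantom_dataset(spec, 3, out)
    return out, manifest
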