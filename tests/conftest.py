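import numpy as np
import pytest

from stormdistill import simulate


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small dense-emitter dataset shared across training tests.

    Two 48x48 frames at 13 emitters/um^2 and background 200, 40 random 16x16
    patches each (divisible by 8 so the teacher accepts them), normalized.
    """
    ds = simulate.make_dataset(
        n_images=2,
        image_size=48,
        density_per_um2=13.0,
        patch_size=16,
        patches_per_image=40,
        rng_seed=7,
    )
    # the shared fixture must exercise all three splits
    assert all((ds.labels == s).sum() > 0 for s in simulate.SPLITS)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
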