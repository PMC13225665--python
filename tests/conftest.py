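import numpy as np
import pytest

from mmtissue.images import MultichannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_image(rng):
    """8×8×3 random raster."""
    return MultichannelImage(
        rng.random((8, 8, 3)).astype(np.float32), ["a", "b", "c"]
    )


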