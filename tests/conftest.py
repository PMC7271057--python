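import numpy as np
import pytest

from renoseg.distributions import KernelSpec
from renoseg.image_model import DomainPartition, IntensityImage
from renoseg.segmentation import EnergyParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_valued_instance(rng, gamma=0.0, lo=10.0, hi=200.0, shape=(4, 4)):
    """A tiny two-valued segmentation problem with a constant model region.

    The model half is all-background (value ``lo``); the segmentation half
    mixes background with a well-separated "kidney" value ``hi``.  Returns
    (image, partition, params).
    """
    h, w = shape
    vals = np.empty((h, 2 * w))
    vals[:, w:] = lo
    phi = rng.choice([lo, hi], size=shape, p=[0.6, 0.4])
    if (phi == lo).sum() == 0:
        phi[0, 0] = lo
    if (phi == hi).sum() == 0:
        phi[0, 1] = hi
    vals[:, :w] = phi
    image = IntensityImage(values=vals)
    phi_s = np.zeros((h, 2 * w), dtype=bool)
    phi_s[:, :w] = True
    partition = DomainPartition(
        phi_s=phi_s, phi_s_bar=~phi_s, split_kind="vertical",
        split_index=w, side_choice="right_kidney",
    )
    params = EnergyParams(gamma=gamma, kernel=KernelSpec("dirac"), n_bins=256)
    return image, partition, params
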