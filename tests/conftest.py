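import numpy as np
import pytest

from heartchip import synthetic as syn


@pytest.fixture
def plus_sign_skeleton():
    """Thin plus-sign: two crossing 51-px one-pixel lines sharing a center."""
    sk = np.zeros((61, 61), dtype=bool)
    sk[30, 5:56] = True
    sk[5:56, 30] = True
    return sk


@pytest.fixture
def small_vessel_world():
    """One small rendered network with its ground truth (fast unit fixture)."""
    params = syn.VesselNetworkParams(
        image_shape=(512, 512), target_coverage=0.4, seed=7
    )
    img, gt = syn.gen_vessel_network(params)
    return params, img, gt
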