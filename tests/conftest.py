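import numpy as np
import pytest

import gaitpath as gp


@pytest.fixture(scope="session")
def normal_walk():
    """Three uncorrupted cycles of the default normal walker (seeded)."""
    params = gp.style_preset("normal", 1)
    seq, boundaries, skels = gp.generate_sequence(params, 3, seed=7)
    return {"params": params, "seq": seq, "boundaries": boundaries, "skeletons": skels}


@pytest.fixture()
def blob_frame():
    """A 40x40 frame with a 10x4 solid rectangle of foreground."""
    mask = np.zeros((40, 40), dtype=np.uint8)
    mask[10:20, 18:22] = 1
    return gp.SilhouetteFrame(mask)
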