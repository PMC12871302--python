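import warnings

import numpy as np
import pytest

from axonsynkit import synthetic as syn
from axonsynkit.config import PRESETS


@pytest.fixture(scope="session")
def wt_small_run():
    """10 wild-type axons rendered with realistic noise, traced once."""
    from axonsynkit import transport as tp

    axons = syn.gen_svp_tracks(PRESETS["WT"], 10, 300.0, 100.0, seed=11)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (axon_id, tracks) in enumerate(axons.items()):
            kymo = syn.render_kymograph(tracks, 100.0, 300.0, noise_sd=10.0,
                                        seed=k)
            out.append((axon_id, tracks, kymo, tp.trace_tracks(kymo)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
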