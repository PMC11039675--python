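import numpy as np
import pandas as pd
import pytest

from nearshoredsm import detection, dsm, synthetic
from nearshoredsm.synthetic import simulate_halfnormal_distances  # re-export


@pytest.fixture(scope="session")
def small_env():
    """A 3-year synthetic environment shared across model tests."""
    return synthetic.make_environment([2001, 2002, 2003], seed=11)


@pytest.fixture(scope="session")
def small_survey(small_env):
    truth = synthetic.TruthBundle(seed=11)
    seg, sight = synthetic.simulate_survey(truth, small_env, seed=11)
    esw_km = {
        b: detection.hn_esw(s, truth.truncation_m) / 1000.0
        for b, s in truth.detection_sigma_by_bss.items()
    }
    seg = seg.copy()
    seg["offset"] = dsm.build_offset(
        [esw_km[b] for b in seg["bss"]], seg["length_km"]
    )
    return truth, seg, sight


@pytest.fixture(scope="session")
def fitted_dsm(small_survey):
    _, seg, _ = small_survey
    return dsm.fit_dsm(seg, dsm.DsmConfig(region=1))
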