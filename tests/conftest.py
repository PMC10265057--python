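import numpy as np
import pytest

from tilescan import screen_stats as ss
from tilescan import synthetic_data as sd

LIBRARY_SEED = 123


@pytest.fixture(scope="session")
def tiling_library():
    """One fixed synthetic screen library: ~200 guides tiling a 456-codon
    CDS plus 30 negative and 30 positive controls."""
    cds, lib = sd.synthetic_tiling_library(456, seed=LIBRARY_SEED)
    return cds, lib


@pytest.fixture(scope="session")
def peak_profile():
    """Planted essentiality landscape: exponential peak at residue 108
    supported on residues 63-135."""
    return sd.EssentialityProfile.exponential_peak(456)


@pytest.fixture(scope="session")
def simulated_screen(tiling_library, peak_profile):
    """One simulated screen (seed 7) with its ground truth and scores."""
    _, lib = tiling_library
    config = sd.ScreenSimConfig(seed=7)
    counts, truth = sd.simulate_tiling_screen(lib, peak_profile, config, return_truth=True)
    scan = ss.score_screen(counts, lib)
    return {"library": lib, "config": config, "counts": counts, "truth": truth, "scan": scan}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
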