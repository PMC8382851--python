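import numpy as np
import pytest

from vfrecon import (HRFSpec, StimulusDesign, build_prediction_bank,
                     build_wedge_ring)
from vfrecon.prf import GridSpec, build_grid


@pytest.fixture(scope="session")
def design_small():
    """Short two-cycle design for fast unit tests (48 frames)."""
    return StimulusDesign(cycle_s=40.0, n_cycles=2, blank_s=16.0,
                          frame_duration_s=2.0)


@pytest.fixture(scope="session")
def apertures_small(design_small):
    return (build_wedge_ring(design_small, n_pix=41),
            build_wedge_ring(design_small.reversed_direction(), n_pix=41))


@pytest.fixture(scope="session")
def hrf():
    return HRFSpec()


@pytest.fixture(scope="session")
def bank_small(apertures_small, hrf):
    return build_prediction_bank(list(apertures_small), hrf)


@pytest.fixture(scope="session")
def grid_small(bank_small):
    return build_grid(bank_small, GridSpec(n_positions=21, n_sigmas=6))


@pytest.fixture(scope="session")
def design_paper():
    """The full mapping design: 2 x 120 s cycles + 48 s blank at TR 2 s."""
    return StimulusDesign()


@pytest.fixture(scope="session")
def apertures_paper(design_paper):
    return (build_wedge_ring(design_paper, n_pix=101),
            build_wedge_ring(design_paper.reversed_direction(), n_pix=101))


@pytest.fixture(scope="session")
def bank_paper(apertures_paper, hrf):
    return build_prediction_bank(list(apertures_paper), hrf)


def gaussian_series(bank, rfs, noise_sd=0.0, seed=0, gains=None):
    """Cycle-averaged concatenated series for a set of true RFs."""
    rng = np.random.default_rng(seed)
    gains = gains or [1.0] * len(rfs)
    s = sum(g * bank.gaussian_prediction(rf.x0, rf.y0, rf.sigma)
            for g, rf in zip(gains, rfs))
    return s + rng.normal(0.0, noise_sd, s.shape)
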