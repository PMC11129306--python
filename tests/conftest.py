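import numpy as np
import pytest

from memgrad import LipidSpec, layout_patches, predict_thickness_profile
from memgrad.surrogate import (
    PeptideTemplate,
    constant_sampler,
    synthesize_membrane_trajectory,
    uniform_azimuth_sampler,
)
from memgrad.thickness import ThicknessProfile


@pytest.fixture
def four_lipids():
    """Four PC-like lipids spanning pure-membrane thicknesses 3.34-4.95 nm."""
    return [
        LipidSpec("DYPC", 3.34, 330),
        LipidSpec("DOPC", 3.88, 330),
        LipidSpec("DGPC", 4.41, 330),
        LipidSpec("DNPC", 4.95, 330),
    ]


@pytest.fixture
def gradient_layout(four_lipids):
    """Four equal patches with 2 nm overlaps in a 40 nm box."""
    return layout_patches(four_lipids, 40.0, [2.0, 2.0, 2.0])


@pytest.fixture
def flat_profile():
    """Constant 4 nm thickness over a 20 nm box, 0.5 nm bins."""
    centers = 0.5 * (np.arange(40) + 0.5)
    return ThicknessProfile(centers, np.full(40, 4.0), None, 0.5)


@pytest.fixture
def flat_frames(flat_profile):
    """Noiseless flat membrane with a 23-degree rod peptide at the centre."""
    peptide = PeptideTemplate(
        l_tm=3.45,
        x_com=10.0,
        tilt_sampler=constant_sampler(23.0),
        azimuth_sampler=uniform_azimuth_sampler(),
    )
    return synthesize_membrane_trajectory(
        flat_profile, n_lipids_per_leaflet=600, n_frames=20,
        positional_noise_sd=0.0, peptide=peptide, seed=11,
    )
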