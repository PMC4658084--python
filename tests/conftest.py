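import numpy as np
import pytest

from echofish.echogram_model import ColourScale, EchogramFrame
from echofish.pixel_calibration import PixelMapping
from echofish.synthetic_echogram import SchoolSpec, SurveySpec, default_school_field


def make_frame(
    pixels,
    depth_min=0.0,
    depth_max=None,
    metres_per_col=1.0,
    n_colours=8,
    t0=1.4e9,
    dt=0.5,
    lat0=-33.85,
    lon0=25.70,
):
    """Frame with linear georeference; depth range defaults to 1 m/row."""
    pixels = np.asarray(pixels)
    rows, cols = pixels.shape
    if depth_max is None:
        depth_max = depth_min + rows
    j = np.arange(cols)
    return EchogramFrame(
        pixels=pixels,
        depth_min_m=depth_min,
        depth_max_m=depth_max,
        col_times=t0 + j * dt,
        col_lats=np.full(cols, lat0),
        col_lons=lon0 + j * 1e-5,
        metres_per_col=metres_per_col,
        scale=ColourScale(n_colours),
        frame_file="test.png",
    )


@pytest.fixture
def blank_frame():
    return make_frame(np.zeros((20, 30), dtype=int))


@pytest.fixture
def survey_spec():
    spec = SurveySpec(seed=11, n_frames=5, overlap_cols=0)
    rng = np.random.default_rng(5)
    spec.schools = default_school_field(spec, 4, rng)
    return spec


@pytest.fixture
def noisy_survey_spec():
    spec = SurveySpec(
        seed=23,
        n_frames=6,
        overlap_cols=8,
        speckle_density=0.01,
        noise_col_rate=0.02,
    )
    rng = np.random.default_rng(9)
    spec.schools = default_school_field(spec, 5, rng)
    return spec


@pytest.fixture
def mapping():
    return PixelMapping(-65.0, 1.3)
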