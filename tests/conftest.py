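"""Shared fixtures: the default synthetic scene is expensive to build, so
everything derived from it is session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from thermofuse.ingest import IntensificationParams, intensify, temperature_to_grayscale
from thermofuse.synthetic import (
    SceneSpec,
    make_bust,
    make_temperature_field,
    rasterize_volume,
    render_thermal_views,
)


@pytest.fixture(scope="session")
def spec():
    return SceneSpec()


@pytest.fixture(scope="session")
def bust(spec):
    return make_bust(spec)


@pytest.fixture(scope="session")
def temp_field(bust, spec):
    return make_temperature_field(bust, spec)


@pytest.fixture(scope="session")
def rendered(bust, temp_field, spec):
    """(frames, ground truth) for the default 12-view arc."""
    return render_thermal_views(bust, temp_field, spec)


@pytest.fixture(scope="session")
def volume_and_masks(spec):
    return rasterize_volume(spec)


@pytest.fixture(scope="session")
def intensified_images(rendered):
    frames, _ = rendered
    t_lo = min(f.temperatures.min() for f in frames)
    t_hi = max(f.temperatures.max() for f in frames)
    params = IntensificationParams(local_equalize=False)
    return {
        f.frame_index: intensify(temperature_to_grayscale(f, t_lo, t_hi), params)
        for f in frames
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
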