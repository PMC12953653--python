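"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from psf4d.dictionary import build_dictionary
from psf4d.pupil import PupilModel


@pytest.fixture(scope="session")
def small_dict():
    """A desk-scale dictionary: 512x512 sensor, 256 px patches (2x2 grid),
    two zoom levels, three wavelengths."""
    d = build_dictionary(sensor_shape=(512, 512), patch_size=256,
                         zoom_levels=(20.0, 60.0), pad=256)
    d.validate()
    return d


@pytest.fixture(scope="session")
def six_level_dict():
    """Six zoom levels on the small 2x2 field grid (fast stand-in geometry)."""
    d = build_dictionary(sensor_shape=(512, 512), patch_size=256,
                         zoom_levels=(10.0, 20.0, 40.0, 60.0, 80.0, 100.0),
                         pad=256)
    d.validate()
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def aberration_free_pupil():
    return PupilModel(defocus_w=0.0, astig_w=0.0, coma_w=0.0, spherical_w=0.0,
                      chromatic_defocus={})
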