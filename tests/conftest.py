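"""Shared fixtures: small phantoms and reconstructions, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from sparsect.preprocessing import WindowConfig, apply_window
from sparsect.projection import Geometry, make_view_series
from sparsect.synthetic import CohortConfig, PhantomSlice, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """64 px grid at 2 mm/px: a 1 cm nodule spans 5 px."""
    return CohortConfig(n_subjects=4, diseased_fraction=0.5, image_size=64, pixel_spacing=2.0, seed=11)


@pytest.fixture(scope="session")
def diseased_slice(small_config) -> PhantomSlice:
    return generate_phantom("D000", diseased=True, config=small_config)


@pytest.fixture(scope="session")
def healthy_slice(small_config) -> PhantomSlice:
    return generate_phantom("H000", diseased=False, config=small_config)


@pytest.fixture(scope="session")
def small_geometry() -> Geometry:
    """Reduced full-view count so unit tests stay fast; 16..256 still divide it."""
    return Geometry(n_views_full=512)


@pytest.fixture(scope="session")
def small_series(diseased_slice, small_geometry):
    return make_view_series(
        diseased_slice.image, small_geometry, (16, 32, 64, 128, 256), subject_id="D000"
    )


@pytest.fixture(scope="session")
def windowed_pair(small_series):
    """(full, sparse-64) windowed reconstruction pair."""
    window = WindowConfig()
    full = apply_window(small_series.full_view, window)
    sparse = apply_window(small_series.reconstructions[64], window)
    return full, sparse


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
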