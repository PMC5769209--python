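"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from nemaphen.config import PeakParams, ThresholdParams
from nemaphen.synthetic import SyntheticSpec, generate_dimorphic_population, generate_plate


@pytest.fixture(scope="session")
def default_plate():
    """Default synthetic plate: 20 separated hermaphrodite-like worms."""
    spec = SyntheticSpec(n_worms=20, seed=0)
    return generate_plate(spec)


@pytest.fixture(scope="session")
def small_plate():
    """Small, fast plate for pipeline plumbing tests."""
    spec = SyntheticSpec(n_worms=4, image_size=(700, 700), seed=7)
    return generate_plate(spec)


@pytest.fixture(scope="session")
def dimorphic_crops():
    """60 hermaphrodite-like + 60 male-like crops with ground truth."""
    return generate_dimorphic_population(60, seed=11)


@pytest.fixture()
def threshold_params():
    return ThresholdParams(neighborhood=101, threshold=0.10, min_object_area=200)


@pytest.fixture()
def peak_params():
    return PeakParams(neighborhood=11, threshold_frac=0.5)


def bar_mask(height: int, width: int, canvas: tuple[int, int] | None = None,
             offset: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Axis-aligned solid bar in a padded canvas."""
    ch = canvas[0] if canvas else height + 4
    cw = canvas[1] if canvas else width + 4
    mask = np.zeros((ch, cw), dtype=bool)
    r0 = (ch - height) // 2 + offset[0]
    c0 = (cw - width) // 2 + offset[1]
    mask[r0 : r0 + height, c0 : c0 + width] = True
    return mask


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    size = 2 * radius + 1 + 2 * pad
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
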