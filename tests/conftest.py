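"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from hepatoseg.phantom import default_spec, make_phantom, scaled_spec


@pytest.fixture(scope="session")
def default_truth():
    """Default seeded phantom at full study resolution (96x128x128)."""
    return make_phantom(default_spec(0))


@pytest.fixture(scope="session")
def small_truth():
    """Same scene at 48x64x64 for cheap structural tests."""
    return make_phantom(scaled_spec(default_spec(1), (48, 64, 64)))


def eroded_init(truth, k: int, keep_fraction: float = 0.6) -> np.ndarray:
    """Initial contour: the true cross-section eroded to a fraction of its
    area, emulating a rough user-drawn seed."""
    sec = truth.liver.as_bool()[k]
    er = sec.copy()
    while er.sum() > keep_fraction * sec.sum():
        nxt = ndimage.binary_erosion(er)
        if not nxt.any():
            break
        er = nxt
    return er


@pytest.fixture(scope="session")
def default_liver_seg(default_truth):
    """Level-set liver segmentation of the default phantom (shared: this is
    the most expensive single computation in the suite)."""
    from hepatoseg.liver_levelset import segment_liver

    k = 48
    return segment_liver(default_truth.volume, k, eroded_init(default_truth, k))
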