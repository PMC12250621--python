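import logging

import numpy as np
import pytest

from ciliametry.cilia import Contour
from ciliametry.io import Image2D

logging.getLogger("ciliametry").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bar_image(shape=(64, 64), row0=30, row1=34, col0=10, col1=50,
                   fg=200, bg=0, dtype=np.uint8):
    """Axis-aligned bright bar on constant background."""
    px = np.full(shape, bg, dtype=dtype)
    px[row0:row1, col0:col1] = fg
    return px


def rect_contour(length_px: float, width_px: float, x0: float = 5.0, y0: float = 5.0):
    """Synthetic rectangular contour with exactly known min-area-rect dims."""
    pts = np.array([
        [x0, y0],
        [x0 + length_px, y0],
        [x0 + length_px, y0 + width_px],
        [x0, y0 + width_px],
    ])
    rc = np.array([[int(y0), int(x0)], [int(y0) + 1, int(x0)], [int(y0), int(x0) + 1]])
    return Contour(points=pts, filled_rc=rc)


@pytest.fixture
def bar_image():
    return Image2D(make_bar_image(), pixel_size_um=0.5, hemisphere="right", channel="ADCY3")
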