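import numpy as np
import pytest

from cc_centile import MidsagittalMask


@pytest.fixture
def rect_mask():
    """80 x 10 mm solid bar at 1 mm spacing (with background margin)."""
    grid = np.zeros((20, 90), dtype=bool)
    grid[5:15, 5:85] = True
    return MidsagittalMask(grid=grid, spacing=(1.0, 1.0))


@pytest.fixture
def annulus_mask():
    """Half annulus, outer r = 50 mm, inner r = 40 mm, at 0.25 mm spacing.

    Arch opens downward (flat ends at the bottom); analytic values:
    width 10 mm, centreline length pi*45, area pi*450.
    """
    sp = 0.25
    yy, xx = np.mgrid[0:260, 0:440]
    x = (xx - 220) * sp
    y = (yy - 20) * sp
    r = np.hypot(x, y)
    grid = (r >= 40) & (r <= 50) & (y >= 0)
    return MidsagittalMask(grid=grid[::-1], spacing=(sp, sp))


@pytest.fixture
def disk_mask():
    yy, xx = np.mgrid[0:200, 0:200]
    grid = np.hypot(xx - 100, yy - 100) < 80
    return MidsagittalMask(grid=grid, spacing=(0.25, 0.25))
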