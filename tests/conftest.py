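import numpy as np
import pytest
from skimage import draw

from vicmorph.morphometry import CellMask


@pytest.fixture
def disc_mask() -> CellMask:
    """Rasterized disc, radius 50 px, 1 µm/px."""
    m = np.zeros((121, 121), bool)
    rr, cc = draw.disk((60, 60), 50)
    m[rr, cc] = True
    return CellMask(mask=m, pixel_size=1.0, cell_id="disc")


@pytest.fixture
def rect_mask() -> CellMask:
    """Axis-aligned 100 x 50 px rectangle, 1 µm/px."""
    m = np.zeros((60, 110), bool)
    m[5:55, 5:105] = True
    return CellMask(mask=m, pixel_size=1.0, cell_id="rect")


@pytest.fixture
def ellipse_mask() -> CellMask:
    """2:1 ellipse, semi-axes 100 and 50 px."""
    m = np.zeros((121, 221), bool)
    rr, cc = draw.ellipse(60, 110, 50, 100, shape=m.shape)
    m[rr, cc] = True
    return CellMask(mask=m, pixel_size=1.0, cell_id="ellipse")
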