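import numpy as np
import pytest

from octava import TreeSpec, clean_mask, generate_scene, generate_tree, rasterize_tree
from octava.segmentation import BinaryVesselMask
from octava.synth.raster import _paint_polyline


@pytest.fixture(scope="session")
def tree5():
    """Single 5-level Murray tree (exponent 3) with its ground truth."""
    return generate_tree(TreeSpec(seed=0, branch_levels=5))


@pytest.fixture(scope="session")
def scene_mask():
    """Rasterized macula-like scene at 512 px: cleaned mask + ground truth."""
    scene = generate_scene(TreeSpec(seed=0))
    mask_arr, truth = rasterize_tree(scene, 512)
    mask = clean_mask(
        BinaryVesselMask(mask=mask_arr, scale_um_per_px=truth.scale_um_per_px), 30, 20
    )
    return mask, truth


@pytest.fixture()
def y_mask():
    """Y-shaped vessel mask: one junction, three endpoints."""
    mask = np.zeros((200, 200), dtype=bool)
    _paint_polyline(mask, np.linspace(180, 100, 200), np.full(200, 100.0), 4.0)
    _paint_polyline(mask, np.linspace(100, 30, 200), np.linspace(100, 40, 200), 3.0)
    _paint_polyline(mask, np.linspace(100, 30, 200), np.linspace(100, 160, 200), 3.0)
    return BinaryVesselMask(mask=mask, scale_um_per_px=5.86)


def straight_tube_mask(width_px: int, scale: float = 5.86, length: int = 150, shape=(220, 220)):
    """Horizontal tube covering exactly ``width_px`` pixel rows."""
    mask = np.zeros(shape, dtype=bool)
    r0 = shape[0] // 2 - width_px // 2
    mask[r0 : r0 + width_px, 30 : 30 + length] = True
    return BinaryVesselMask(mask=mask, scale_um_per_px=scale)
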