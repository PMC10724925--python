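import numpy as np
import pytest

from cellstitch.volumes import LabelVolume


def disc_mask(shape, center, radius):
    """Rasterized disc: pixels with squared distance <= radius**2."""
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def iou(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def stacked_cells_scene():
    """Two cells with identical XY footprints in consecutive layer pairs.

    Ground truth: cell 1 fills a square footprint in layers 0-1, cell 2 the
    same footprint in layers 2-3.  Only orthogonal information can tell the
    transition at layers 1->2 apart from a single tall cell.
    """
    gt = np.zeros((4, 12, 12), dtype=np.uint32)
    gt[0:2, 3:9, 3:9] = 1
    gt[2:4, 3:9, 3:9] = 2
    return LabelVolume(gt)
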