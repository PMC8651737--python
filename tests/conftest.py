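import numpy as np
import pytest

from rbcmorph.morphometry import BinaryMask
from rbcmorph.synthetic import CellSpec, render_cell_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def render_mask(kind, a, b, lobe_factor=1.0, orientation=90.0, phase=(0.31, 0.57), pad=12):
    """Render one cell footprint on a grid just large enough to hold it.

    ``phase`` is the sub-pixel offset of the cell centre (off-lattice by
    default so boundaries do not sit exactly on pixel centres).
    """
    reach = a * (lobe_factor if kind == "two_lobe" else 1.0)
    side = int(2 * (reach + pad)) + 1
    center = (side / 2 + phase[0], side / 2 + phase[1])
    spec = CellSpec(kind, center, a, b, lobe_factor=lobe_factor, orientation=orientation)
    return BinaryMask.from_array(render_cell_mask(spec, (side, side)))


@pytest.fixture
def ellipse_mask():
    return render_mask("symmetric_ellipse", 40, 20)
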