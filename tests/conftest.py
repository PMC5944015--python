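import numpy as np
import pytest

from phenoshoot import segmentation as seg
from phenoshoot import skeleton_graph as sg
from phenoshoot import synthetic_plants as synth


@pytest.fixture(scope="session")
def plant_spec():
    """A representative 6-leaf plant specification."""
    return synth.sample_plant_spec(42, n_leaves=6)


@pytest.fixture(scope="session")
def day20_frame(plant_spec):
    return synth.render_frame(plant_spec, 20)


@pytest.fixture(scope="session")
def day20_graph(plant_spec, day20_frame):
    background = synth.render_background(plant_spec)
    mask = seg.segment(day20_frame.rgb, background)
    return sg.mask_to_graph(mask)


def y_plant_mask(height=80, arm=30, width=5):
    """Filled Y-shape: a vertical stem splitting into two diagonal arms."""
    from skimage.draw import line
    from skimage.morphology import dilation, disk

    canvas = np.zeros((120, 120), dtype=bool)
    rr, cc = line(110, 60, 110 - height, 60)
    canvas[rr, cc] = True
    top = 110 - height
    for dc in (-1, 1):
        rr, cc = line(top, 60, top - arm, 60 + dc * arm)
        canvas[rr, cc] = True
    return dilation(canvas, disk(width // 2))


@pytest.fixture()
def y_mask():
    return y_plant_mask()
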