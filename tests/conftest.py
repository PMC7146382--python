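import numpy as np
import pytest

from nestseg.synthdata import SlideImage, SynthParams


@pytest.fixture
def small_params():
    """Generator parameters for fast 128/192-px fixtures."""
    return SynthParams(image_height=128, image_width=128,
                       nest_count_range=(1, 3), nest_radius_range=(18, 30))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_slide(h, w, mask_boxes=(), labeled=True, image_id="toy", seed=0):
    """Deterministic toy slide: flat background, optional rectangular nest
    boxes given as (r0, r1, c0, c1)."""
    gen = np.random.default_rng(seed)
    rgb = np.clip(0.8 + 0.05 * gen.standard_normal((h, w, 3)), 0, 1)
    rgb = rgb.astype(np.float32)
    mask = None
    if labeled:
        mask = np.zeros((h, w), np.uint8)
        for r0, r1, c0, c1 in mask_boxes:
            mask[r0:r1, c0:c1] = 1
            rgb[r0:r1, c0:c1] = 0.3
    return SlideImage(image_id, rgb, mask, labeled)
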