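import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_attention_params():
    """Tiny attention parameter set (L=5, D=4) for formula checks."""
    from milsurv.model import AttentionParams

    r = np.random.default_rng(7)
    return AttentionParams(V=r.normal(size=(5, 4)), U=r.normal(size=(5, 4)),
                          w=r.normal(size=5))


def make_pink_square_slide(size=4096, square=1024, downscale_for_pos=4):
    """White slide with one saturated pink square; returns (slide, gt_mask)."""
    from milsurv.wsi import SlideHandle

    img = np.full((size, size, 3), 255, dtype=np.uint8)
    y0 = x0 = (size - square) // 2
    img[y0:y0 + square, x0:x0 + square] = (230, 60, 140)
    gt = np.zeros((size, size), dtype=bool)
    gt[y0:y0 + square, x0:x0 + square] = True
    return SlideHandle.from_array(img, id="pink", base_mag=40.0), gt
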