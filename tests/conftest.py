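import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from vesiquant.profiling import ImagePlane
from vesiquant.segmentation import VesicleDetection
from vesiquant.synthetic import render_ring


def make_detection(cy, cx, radius, det_id=0):
    return VesicleDetection(
        id=det_id,
        centroid_row_px=cy,
        centroid_col_px=cx,
        area_px2=np.pi * radius**2,
        perimeter_px=2 * np.pi * radius,
        radius_px=radius,
        radius_area_px=radius,
        circularity=1.0,
        touches_border=False,
    )


@pytest.fixture
def ring_plane():
    """A single noise-free Gaussian ring, well-sampled (sigma = 3 px)."""
    center, radius, sigma, amp = (64.3, 63.6), 20.0, 3.0, 1000.0
    img = render_ring((128, 128), center, radius, sigma, amp)
    return ImagePlane(img, pixel_size_um=0.2), center, radius, sigma, amp
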