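import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def blob_frame():
    """uint16 frame with 12 large and 3 small bright disks on a dark
    background (plus one anchor pixel so the histogram has a tail)."""
    img = np.zeros((200, 200), dtype=np.float64)
    centers_big = [(20 + 40 * (i // 4), 25 + 45 * (i % 4)) for i in range(12)]
    for c in centers_big:
        img[disk_mask(img.shape, c, 3.2)] = 200.0  # area ~ 33 px
    for c in [(180, 20), (180, 100), (180, 180)]:
        img[disk_mask(img.shape, c, 1.0)] = 200.0  # area ~ 5 px
    return img.astype(np.uint16)
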