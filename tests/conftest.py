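import numpy as np
import pytest

from stainquant import composite_from_arrays, promote_to_float


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_composite(rng, shape=(32, 32), promoted=True, low=0, high=65535):
    """A random 16-bit composite, optionally float-promoted."""
    arrs = [rng.integers(low, high + 1, size=shape, dtype=np.uint16) for _ in range(3)]
    comp = composite_from_arrays(*arrs)
    return promote_to_float(comp) if promoted else comp


def gray_composite(value, shape=(16, 16), promoted=True):
    """A uniform neutral-gray composite (all channels equal)."""
    arr = np.full(shape, value, dtype=np.uint16)
    comp = composite_from_arrays(arr.copy(), arr.copy(), arr.copy())
    return promote_to_float(comp) if promoted else comp


def rectangular_section(body_px, stained_px, shape=(64, 64)):
    """A tissue cross section with exact body and stained pixel counts.

    Bright background, neutral dark tissue rectangle (ratio (g+b)/r = 2,
    below the cartilage-stain threshold), and `stained_px` pixels with red
    suppressed so (g+b)/r = 6."""
    h, w = shape
    arr_r = np.full(shape, 55000, dtype=np.uint16)
    arr_g = arr_r.copy()
    arr_b = arr_r.copy()
    cols = 20
    rows = body_px // cols
    assert rows * cols == body_px
    body = np.zeros(shape, dtype=bool)
    body[10 : 10 + rows, 10 : 10 + cols] = True
    flat = np.flatnonzero(body)[:stained_px]
    stained = np.zeros(h * w, dtype=bool)
    stained[flat] = True
    stained = stained.reshape(shape)
    for a in (arr_r, arr_g, arr_b):
        a[body] = 15000
    arr_r[stained] = 5000
    return composite_from_arrays(arr_r, arr_g, arr_b)
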