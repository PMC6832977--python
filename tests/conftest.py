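import numpy as np
import pytest

from octava.image_io import OCTAImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, extent_mm=3.0, plexus="SCP", laterality="OD", visit_id="t"):
    return OCTAImage(
        pixels=np.asarray(pixels, dtype=np.uint8),
        extent_mm=extent_mm,
        plexus=plexus,
        laterality=laterality,
        visit_id=visit_id,
    )


def brute_force_otsu(arr):
    """Independent exhaustive-search oracle: maximize between-class variance
    over all 256 candidate thresholds via per-pixel partitioning."""
    arr = np.asarray(arr, dtype=np.float64)
    n = arr.size
    best_t, best_b = -1, -np.inf
    for t in range(256):
        lo = arr[arr <= t]
        hi = arr[arr > t]
        if lo.size == 0 or hi.size == 0:
            continue
        b = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if b > best_b:  # strict >: ties keep the smallest t
            best_t, best_b = t, b
    return best_t, best_b


def has_2x2_block(mask):
    m = np.asarray(mask, bool)
    return bool((m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).any())
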