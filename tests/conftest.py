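import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def random_rgb(rng):
    def make(h=32, w=32, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return r.integers(0, 256, (h, w, 3), dtype=np.uint8)
    return make


def random_blob_mask(rng, h, w):
    """Random binary mask: Bernoulli noise, disc unions, or annuli."""
    kind = rng.integers(0, 3)
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == 0:
        mask = rng.random((h, w)) < rng.uniform(0.35, 0.9)
    elif kind == 1:
        mask = np.zeros((h, w), bool)
        for _ in range(rng.integers(1, 4)):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            r = rng.uniform(2, min(h, w) / 2)
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    else:
        cx, cy = w / 2 + rng.uniform(-3, 3), h / 2 + rng.uniform(-3, 3)
        r1 = rng.uniform(min(h, w) / 4, min(h, w) / 2)
        r0 = rng.uniform(0, r1 / 2)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = (d2 <= r1 * r1) & (d2 >= r0 * r0)
    if not mask.any():
        mask[h // 2, w // 2] = True
    return (mask * 255).astype(np.uint8)
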