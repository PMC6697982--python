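import numpy as np
import pytest

from synspread import synthetic_data as sd


@pytest.fixture
def small_stack_cfg():
    """Down-scaled confocal-stack config used throughout the image tests.

    Small frames and shallow stacks keep the suite quick; noise and
    intensity parameters stay at the generator defaults.
    """
    def _make(seed=1, **kw):
        kw.setdefault("width", 256)
        kw.setdefault("height", 256)
        kw.setdefault("n_z", 16)
        kw.setdefault("n_cells", 8)
        return sd.StackSimConfig(seed=seed, **kw)
    return _make


@pytest.fixture
def paint_section():
    """Directly paint DAB-colored discs onto a background RGB image."""
    from skimage import draw as skdraw

    from synspread.morphometry import RGBSection

    def _paint(shape=(400, 400), discs=(), noise_sd=2.0, seed=0,
               stain=(120, 80, 40), background=(235, 230, 225)):
        rng = np.random.default_rng(seed)
        img = np.empty((*shape, 3), float)
        img[:] = background
        for (cy, cx, r) in discs:
            rr, cc = skdraw.disk((cy, cx), r, shape=shape)
            img[rr, cc] = stain
        img += rng.normal(0, noise_sd, img.shape)
        return RGBSection(np.clip(np.round(img), 0, 255).astype(np.uint8), 0.25)
    return _paint


def bh_step_up_oracle(p):
    """Brute-force Benjamini-Hochberg: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj
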