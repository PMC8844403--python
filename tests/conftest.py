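import numpy as np
import pytest

from sferakit.mask_morphology import LabelMask
from sferakit.phantom_generator import PhantomSpec, make_phantom_subject


def disk_mask(shape, center, radius):
    """Binary disk over pixel centers."""
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def brute_force_sdt(mask):
    """All-pairs Euclidean signed distance: positive inside, negative outside.

    Independent oracle: for every pixel, the exact distance to the nearest
    pixel of the opposite region.
    """
    from scipy.spatial.distance import cdist

    mask = np.asarray(mask, dtype=bool)
    fg = np.argwhere(mask).astype(float)
    bg = np.argwhere(~mask).astype(float)
    out = np.zeros(mask.shape)
    if len(bg):
        d_fg = cdist(fg, bg).min(axis=1)
        out[mask] = d_fg
    if len(fg):
        d_bg = cdist(bg, fg).min(axis=1)
        out[~mask] = -d_bg
    return out


@pytest.fixture
def small_phantom():
    """One 6-slice phantom subject with analytic ground truth (EF 0.55)."""
    taper = np.sqrt(np.clip(1 - (np.arange(6) / 6) ** 2, 0.15, None))
    spec = PhantomSpec(
        lv_radius_profile=tuple((float(24 * t), float(22 * t)) for t in taper),
        target_ef=0.55,
        seed=3,
    )
    stack, analytic = make_phantom_subject(spec)
    return stack, analytic, spec


@pytest.fixture
def simple_mask():
    grid = np.zeros((20, 20), dtype=np.int64)
    grid[5:15, 5:15] = 1
    grid[3:5, 5:15] = 2
    return LabelMask(grid)
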