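import numpy as np
import pytest

from scanpix.fixation_io import FixationRecord, Scanpath


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scanpath(points, durations=None, subject="s1", stimulus="p1",
                  label="adult", screen_dims=(1920, 1080)):
    durations = durations or [300.0] * len(points)
    records = [
        FixationRecord(x=float(x), y=float(y), duration_ms=float(d),
                       subject=subject, stimulus=stimulus, label=label)
        for (x, y), d in zip(points, durations)
    ]
    return Scanpath(records=records, screen_dims=screen_dims)


def random_scanpath(rng, n, screen_dims=(1920, 1080), **kw):
    w, h = screen_dims
    pts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    durs = rng.uniform(50, 800, n).tolist()
    return make_scanpath([tuple(p) for p in pts], durs, screen_dims=screen_dims, **kw)


@pytest.fixture
def square_scanpath():
    """Four fixations on the corners of a square plus a revisit."""
    return make_scanpath(
        [(100, 100), (500, 100), (500, 400), (100, 400), (100, 100)],
        [100, 200, 300, 400, 500],
    )
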