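import numpy as np
import pytest

from endotrack.model import Cohort, Track


def make_track(
    xs,
    ys=None,
    dt=1.0,
    widths=None,
    animal="a1",
    group="g",
    axon="x1",
    track="t1",
    start_frame=0,
):
    """Build a Track from axial positions (one per consecutive frame)."""
    xs = np.asarray(xs, dtype=float)
    n = xs.size
    ys = np.zeros(n) if ys is None else np.asarray(ys, dtype=float)
    frames = np.arange(start_frame, start_frame + n)
    return Track(
        animal_id=animal,
        group=group,
        axon_id=axon,
        track_id=track,
        frames=frames,
        t_s=frames * dt,
        x_um=xs,
        y_um=ys,
        width_um=np.full(n, np.nan) if widths is None else np.asarray(widths, float),
    )


def make_cohort(tracks, dt=1.0, paired=False):
    dt_s = {tr.animal_id: dt for tr in tracks}
    return Cohort(tracks=tracks, dt_s=dt_s, paired=paired)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
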