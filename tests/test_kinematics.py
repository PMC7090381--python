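"""Frame-to-frame speeds, pause detection, filtering, per-animal metrics."""

import itertools

import numpy as np
import pytest

from endotrack.kinematics import (
    EXCLUDE_ANTEROGRADE,
    EXCLUDE_LONG_PAUSE,
    EXCLUDE_TOO_SHORT,
    EmptyTrackError,
    compute_steps,
    detect_pause_runs,
    filter_track,
    speed_histogram,
    summarize_animal,
    summarize_cohort,
    summarize_track,
)
from endotrack.simulate import GroupParams, SimParams, simulate_cohort

from conftest import make_track


# ---------------------------------------------------------------- steps

def test_eleven_frames_give_ten_speeds():
    """A track observed over 11 consecutive frames yields 10 step speeds."""
    tr = make_track(np.linspace(0, 10, 11), dt=2.5)
    steps = compute_steps(tr, dt=2.5)
    assert len(steps) == 10


def test_stationary_track_all_paused():
    tr = make_track(np.zeros(5))
    steps = compute_steps(tr, dt=1.0, eps=0.1)
    assert len(steps) == 4
    assert all(s.paused and s.speed_um_s == 0.0 for s in steps)


def test_speed_arithmetic():
    tr = make_track([0.0, 2.5, 5.0], dt=2.5)
    steps = compute_steps(tr, dt=2.5)
    assert [s.speed_um_s for s in steps] == pytest.approx([1.0, 1.0])


def test_single_point_track_errors():
    with pytest.raises(EmptyTrackError):
        compute_steps(make_track([0.0]), dt=1.0)


def test_speed_is_euclidean_not_axial():
    tr = make_track([0.0, 3.0], ys=[0.0, 4.0], dt=1.0)
    (s,) = compute_steps(tr, dt=1.0)
    assert s.speed_um_s == pytest.approx(5.0)
    assert s.axial_um == pytest.approx(3.0)


# ----------------------------------------------------------- pause runs

def brute_force_runs(flags):
    """Independent scan: maximal runs of consecutive True values."""
    runs, i = [], 0
    flags = list(flags)
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def test_no_pauses_empty_runs():
    assert detect_pause_runs([False, False, False]) == []


def test_single_maximal_run():
    flags = [False, False, True, True, True, False]
    assert detect_pause_runs(flags) == [(2, 3)]


@pytest.mark.parametrize("n", range(0, 13))
def test_pause_runs_match_exhaustive_scan(n):
    """Every boolean step sequence of length <= 12 matches the scan oracle."""
    for bits in itertools.product([False, True], repeat=n):
        assert detect_pause_runs(list(bits)) == brute_force_runs(bits)


# -------------------------------------------------------------- filter

def _metrics_for(xs, dt=1.0, eps=0.1):
    return summarize_track(make_track(xs, dt=dt), dt=dt, eps=eps)


def test_short_track_excluded():
    m = _metrics_for([0.0, 1.0, 2.0, 3.0])  # 4 frames < 5
    assert (m.included, m.exclusion_reason) == (False, EXCLUDE_TOO_SHORT)


def test_long_pause_excluded():
    # stationary for 11 consecutive images = 10 paused steps, within 20 frames
    xs = list(np.arange(5.0)) + [4.0] * 10 + list(np.arange(5.0, 10.0))
    m = _metrics_for(xs)
    assert m.longest_pause_images == 11
    assert (m.included, m.exclusion_reason) == (False, EXCLUDE_LONG_PAUSE)


def test_ten_image_pause_still_included():
    xs = list(np.arange(5.0)) + [4.0] * 9 + list(np.arange(5.0, 10.0))
    m = _metrics_for(xs)
    assert m.longest_pause_images == 10
    assert m.included


def test_solely_anterograde_excluded():
    m = _metrics_for(np.arange(8.0)[::-1])  # monotonically decreasing x
    assert (m.included, m.exclusion_reason) == (False, EXCLUDE_ANTEROGRADE)


def test_anterograde_with_pauses_still_excluded():
    xs = [7.0, 6.0, 6.0, 5.0, 4.0, 4.0, 3.0]
    m = _metrics_for(xs)
    assert (m.included, m.exclusion_reason) == (False, EXCLUDE_ANTEROGRADE)


def test_retrograde_with_one_anterograde_step_included():
    xs = [0.0, 1.0, 0.5, 1.5, 2.5, 3.5]
    m = _metrics_for(xs)
    assert m.included


def test_reason_order_short_before_pause():
    m = _metrics_for([0.0, 0.0, 0.0])  # both too short and stationary
    assert m.exclusion_reason == EXCLUDE_TOO_SHORT


# ------------------------------------------------------- track metrics

def test_mean_speed_includes_pauses():
    """Steps of 2,0,2,0 um over dt=2 s average 0.5 um/s, pauses included."""
    tr = make_track([0.0, 2.0, 2.0, 4.0, 4.0], dt=2.0)
    m = summarize_track(tr, dt=2.0, eps=0.1)
    assert m.mean_speed_um_s == pytest.approx(0.5)
    assert m.has_pause
    assert m.n_paused_steps == 2


def test_fully_stationary_mean_zero():
    m = _metrics_for(np.zeros(6))
    assert m.mean_speed_um_s == 0.0


def test_mean_speed_matches_raw_recomputation(rng):
    """Track mean speed equals an independent recomputation from coordinates."""
    for _ in range(20):
        n = rng.integers(2, 30)
        xs = rng.normal(0, 3, n)
        ys = rng.normal(0, 3, n)
        dt = rng.uniform(2.4, 3.2)
        tr = make_track(xs, ys=ys, dt=dt)
        m = summarize_track(tr, dt=dt, eps=0.1)
        expected = np.mean(
            [
                np.sqrt((xs[i + 1] - xs[i]) ** 2 + (ys[i + 1] - ys[i]) ** 2) / dt
                for i in range(n - 1)
            ]
        )
        assert m.mean_speed_um_s == pytest.approx(expected)
        assert m.n_steps == n - 1


def test_mean_with_pauses_below_motile_only_mean(rng):
    """Including paused steps can only lower the mean speed."""
    for _ in range(20):
        n = rng.integers(6, 25)
        xs = np.cumsum(rng.choice([0.0, 1.0, 2.0], n))
        tr = make_track(xs)
        m = summarize_track(tr, dt=1.0, eps=0.1)
        speeds = np.abs(np.diff(xs))
        motile = speeds[speeds >= 0.1]
        if m.has_pause and motile.size:
            assert m.mean_speed_um_s < motile.mean()


# ------------------------------------------------------ animal summary

def test_animal_summary_examples():
    t1 = summarize_track(make_track(np.arange(0, 6.0, 1.0), axon="x1"), 1.0, 0.1)
    t2 = summarize_track(
        make_track(np.arange(0, 12.0, 2.0), axon="x2", track="t2"), 1.0, 0.1
    )
    with pytest.warns(UserWarning):  # below the 6-track advisory minimum
        s = summarize_animal([t1, t2])
    assert s.mean_speed_um_s == pytest.approx(1.5)
    assert s.max_speed_um_s == pytest.approx(2.0)
    assert s.pct_time_paused == 0.0
    assert s.pct_pausing_endosomes == 0.0


def test_pct_pausing_endosomes_fraction():
    tracks = []
    for i, xs in enumerate(
        [
            [0, 1, 2, 3, 4, 5],
            [0, 1, 1, 2, 3, 4],  # pauses once
            [0, 2, 4, 6, 8, 10],
            [0, 1, 2, 2, 3, 4],  # pauses once
        ]
    ):
        tracks.append(
            summarize_track(
                make_track(np.array(xs, float), axon=f"x{i % 2}", track=f"t{i}"),
                1.0,
                0.1,
            )
        )
    with pytest.warns(UserWarning):
        s = summarize_animal(tracks)
    assert s.pct_pausing_endosomes == pytest.approx(50.0)


def test_animal_summary_matches_brute_force(rng):
    """All four animal metrics equal recomputation from the pooled step table."""
    params = SimParams(
        groups={"g": GroupParams(n_animals=1, tracks_per_animal=30)}, seed=11
    )
    cohort, _ = simulate_cohort(params)
    eps = 0.1
    summaries, metrics, steps = summarize_cohort(
        cohort, eps=eps, collect_steps=True, with_histograms=False
    )
    s = summaries[0]
    inc = [m for m in metrics if m.included]
    # oracle: recompute from the audited per-step table
    per_track = steps.groupby("track_id")
    track_means = per_track["speed_um_s"].mean()
    assert s.mean_speed_um_s == pytest.approx(track_means.mean())
    assert s.max_speed_um_s == pytest.approx(track_means.max())
    assert s.pct_time_paused == pytest.approx(100.0 * steps["paused"].mean())
    pausing = per_track["paused"].any()
    assert s.pct_pausing_endosomes == pytest.approx(100.0 * pausing.mean())
    assert s.n_tracks == len(inc) == pausing.size


def test_empty_animal_errors():
    m = _metrics_for([0.0, 1.0, 2.0, 3.0])  # excluded
    with pytest.raises(EmptyTrackError):
        summarize_animal([m])


def test_step_count_conservation():
    """Total steps per animal = sum over included tracks of (n_points - 1)."""
    params = SimParams(
        groups={"g": GroupParams(n_animals=2, tracks_per_animal=20)}, seed=5
    )
    cohort, _ = simulate_cohort(params)
    summaries, metrics, steps = summarize_cohort(cohort, collect_steps=True)
    for s in summaries:
        inc = [m for m in metrics if m.included and m.animal_id == s.animal_id]
        assert s.n_steps == sum(m.n_points - 1 for m in inc)
        assert (steps["animal_id"] == s.animal_id).sum() == s.n_steps


def test_monotone_in_eps():
    """Shrinking eps to zero can only decrease paused-step counts."""
    params = SimParams(
        groups={"g": GroupParams(n_animals=1, tracks_per_animal=15)}, seed=9
    )
    cohort, _ = simulate_cohort(params)
    for eps_hi, eps_lo in [(0.2, 0.1), (0.1, 0.0)]:
        _, m_hi, _ = summarize_cohort(cohort, eps=eps_hi, with_histograms=False)
        _, m_lo, _ = summarize_cohort(cohort, eps=eps_lo, with_histograms=False)
        assert sum(m.n_paused_steps for m in m_lo) <= sum(
            m.n_paused_steps for m in m_hi
        )


def test_steps_per_animal_order_of_magnitude():
    """Default cohort structure yields a few hundred steps per animal."""
    params = SimParams(groups={"g": GroupParams(n_animals=3)}, seed=21)
    cohort, _ = simulate_cohort(params)
    summaries, _, _ = summarize_cohort(cohort, with_histograms=False)
    for s in summaries:
        assert 150 <= s.n_steps <= 1000


# ----------------------------------------------------------- histogram

def test_histogram_single_bin():
    edges, pct = speed_histogram([0.55, 0.5, 0.45], bin_width=0.2)
    assert pct[-1] == pytest.approx(100.0)
    assert pct[:-1].sum() == 0.0
    assert edges[-1] == pytest.approx(0.4)


def test_histogram_sums_to_100(rng):
    for _ in range(10):
        speeds = rng.exponential(1.5, rng.integers(1, 200))
        _, pct = speed_histogram(speeds, bin_width=0.2)
        assert pct.sum() == pytest.approx(100.0)


def test_histogram_matches_counting_oracle(rng):
    speeds = rng.uniform(0, 3, 500)
    w = 0.25
    edges, pct = speed_histogram(speeds, bin_width=w)
    for k, e in enumerate(edges):
        expected = 100.0 * np.sum((speeds >= e) & (speeds < e + w)) / speeds.size
        assert pct[k] == pytest.approx(expected)
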