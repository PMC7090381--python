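"""Track filtering, frame-to-frame speeds, pause detection, per-animal metrics.

The quantification follows the intravital signaling-endosome workflow:

* a track of n consecutive frames yields n-1 frame-to-frame steps; the
  step speed is the Euclidean in-plane displacement over the frame
  interval;
* a step is *paused* when the displacement magnitude is below a
  tolerance ``eps`` (a pause run of L steps means the endosome held the
  same position over L+1 consecutive images);
* tracks are excluded if shorter than 5 frames, if they pause for more
  than 10 consecutive images, or if they move solely anterogradely;
* per-track mean speed is taken over ALL steps, pauses included, and
  per-animal statistics aggregate the included tracks of that animal.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import AnimalSummary, StepRecord, Track, TrackMetrics

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EPS_UM",
    "MIN_TRACK_POINTS",
    "MAX_PAUSE_IMAGES",
    "MIN_TRACKS_PER_ANIMAL",
    "MIN_AXONS_PER_ANIMAL",
    "compute_steps",
    "detect_pause_runs",
    "summarize_track",
    "filter_track",
    "summarize_animal",
    "speed_histogram",
    "group_histogram",
    "summarize_cohort",
]

#: default pause tolerance, um (~single-pixel localization granularity)
DEFAULT_EPS_UM = 0.1
#: minimum consecutive frames for a track to be analyzed
MIN_TRACK_POINTS = 5
#: a track pausing for more than this many consecutive images is excluded
MAX_PAUSE_IMAGES = 10
#: advisory per-animal minima (warnings, not errors)
MIN_TRACKS_PER_ANIMAL = 6
MIN_AXONS_PER_ANIMAL = 2

EXCLUDE_TOO_SHORT = "too-short"
EXCLUDE_LONG_PAUSE = "long-pause"
EXCLUDE_ANTEROGRADE = "anterograde"
EXCLUSION_REASONS = (EXCLUDE_TOO_SHORT, EXCLUDE_LONG_PAUSE, EXCLUDE_ANTEROGRADE)


class EmptyTrackError(ValueError):
    """Raised when a kinematic quantity needs >= 2 points and has fewer."""


def _step_arrays(track: Track, dt: float, eps: float):
    dx = np.diff(track.x_um)
    dy = np.diff(track.y_um)
    disp = np.hypot(dx, dy)
    speed = disp / dt
    paused = disp < eps
    return dx, disp, speed, paused


def compute_steps(track: Track, dt: float, eps: float = DEFAULT_EPS_UM) -> list[StepRecord]:
    """Frame-to-frame step records for one track.

    A track observed over n consecutive frames yields exactly n-1 steps.
    Speed is the in-plane Euclidean displacement magnitude divided by the
    frame interval ``dt``; a step with displacement below ``eps`` um is
    classified as paused.
    """
    if dt <= 0:
        raise ValueError("frame interval dt must be positive")
    if eps < 0:
        raise ValueError("pause tolerance eps must be >= 0")
    if track.n_points < 2:
        raise EmptyTrackError(
            f"track {track.key()} has {track.n_points} point(s); "
            "at least 2 are needed for a frame-to-frame step"
        )
    dx, disp, speed, paused = _step_arrays(track, dt, eps)
    return [
        StepRecord(
            animal_id=track.animal_id,
            group=track.group,
            axon_id=track.axon_id,
            track_id=track.track_id,
            step=i,
            disp_um=float(disp[i]),
            axial_um=float(dx[i]),
            speed_um_s=float(speed[i]),
            paused=bool(paused[i]),
        )
        for i in range(disp.size)
    ]


def detect_pause_runs(paused: Sequence[bool] | Sequence[StepRecord]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive paused steps as (start, length) pairs.

    Accepts either a boolean sequence or a list of :class:`StepRecord`.
    A run of L paused steps corresponds to the endosome holding the same
    position for L+1 consecutive images.
    """
    if len(paused) and isinstance(paused[0], StepRecord):
        flags = np.array([s.paused for s in paused], dtype=bool)
    else:
        flags = np.asarray(paused, dtype=bool)
    runs: list[tuple[int, int]] = []
    if flags.size == 0:
        return runs
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def summarize_track(track: Track, dt: float, eps: float = DEFAULT_EPS_UM) -> TrackMetrics:
    """Per-track kinematics; mean speed includes paused steps.

    The returned metrics carry the inclusion decision from
    :func:`filter_track` already applied.
    """
    if track.n_points < 2:
        # too short to have steps; still a valid (excluded) observation
        m = TrackMetrics(
            animal_id=track.animal_id,
            group=track.group,
            axon_id=track.axon_id,
            track_id=track.track_id,
            n_points=track.n_points,
            n_steps=0,
            mean_speed_um_s=np.nan,
            max_step_speed_um_s=np.nan,
            n_paused_steps=0,
            longest_pause_steps=0,
            has_pause=False,
            net_axial_um=0.0,
        )
        m.included, m.exclusion_reason = filter_track(m)
        return m
    dx, disp, speed, paused = _step_arrays(track, dt, eps)
    runs = detect_pause_runs(paused)
    longest = max((L for _, L in runs), default=0)
    m = TrackMetrics(
        animal_id=track.animal_id,
        group=track.group,
        axon_id=track.axon_id,
        track_id=track.track_id,
        n_points=track.n_points,
        n_steps=int(speed.size),
        mean_speed_um_s=float(speed.mean()),
        max_step_speed_um_s=float(speed.max()),
        n_paused_steps=int(paused.sum()),
        longest_pause_steps=int(longest),
        has_pause=bool(paused.any()),
        net_axial_um=float(dx.sum()),
    )
    m._axial_steps = dx  # kept for the anterograde rule
    m._paused_steps = paused
    m.included, m.exclusion_reason = filter_track(m)
    return m


def filter_track(
    metrics: TrackMetrics,
    *,
    min_points: int = MIN_TRACK_POINTS,
    max_pause_images: int = MAX_PAUSE_IMAGES,
) -> tuple[bool, Optional[str]]:
    """Inclusion decision for one track; returns (included, reason).

    Exclusion rules, checked in order (first match reported):

    a. observed for fewer than ``min_points`` consecutive frames;
    b. paused for more than ``max_pause_images`` consecutive images
       (a pause run of L steps spans L+1 images);
    c. moved solely anterogradely: every non-paused step has negative
       axial displacement and the net axial displacement is negative.
    """
    if metrics.n_points < min_points:
        return False, EXCLUDE_TOO_SHORT
    if metrics.longest_pause_images > max_pause_images:
        return False, EXCLUDE_LONG_PAUSE
    axial = getattr(metrics, "_axial_steps", None)
    paused = getattr(metrics, "_paused_steps", None)
    if axial is not None and paused is not None:
        moving_axial = np.asarray(axial)[~np.asarray(paused)]
        if (
            metrics.net_axial_um < 0
            and (moving_axial.size == 0 or np.all(moving_axial < 0))
        ):
            return False, EXCLUDE_ANTEROGRADE
    return True, None


def summarize_animal(
    metrics: Sequence[TrackMetrics],
    *,
    animal_id: Optional[str] = None,
    group: Optional[str] = None,
) -> AnimalSummary:
    """Aggregate the included tracks of one animal.

    mean speed   = mean over included tracks of per-track mean speeds
    max speed    = fastest per-track mean speed
    %time paused = 100 * (paused steps pooled over tracks) / (all steps)
    %pausing     = 100 * (tracks with >= 1 pause) / (tracks)

    Fewer than 6 included tracks or fewer than 2 distinct axons triggers
    a warning (the advisory per-animal minima), not an error.
    """
    included = [m for m in metrics if m.included]
    if not included:
        raise EmptyTrackError("no included tracks for this animal")
    animal_id = animal_id if animal_id is not None else included[0].animal_id
    group = group if group is not None else included[0].group
    n_axons = len({m.axon_id for m in included})
    if len(included) < MIN_TRACKS_PER_ANIMAL or n_axons < MIN_AXONS_PER_ANIMAL:
        warnings.warn(
            f"animal {animal_id}: {len(included)} included tracks from "
            f"{n_axons} axon(s) fall below the advisory minima "
            f"({MIN_TRACKS_PER_ANIMAL} tracks from {MIN_AXONS_PER_ANIMAL} axons)",
            stacklevel=2,
        )
    track_means = np.array([m.mean_speed_um_s for m in included])
    n_steps = sum(m.n_steps for m in included)
    n_paused = sum(m.n_paused_steps for m in included)
    per_track_pct = np.array(
        [100.0 * m.n_paused_steps / m.n_steps for m in included if m.n_steps > 0]
    )
    return AnimalSummary(
        animal_id=animal_id,
        group=group,
        n_tracks=len(included),
        mean_speed_um_s=float(track_means.mean()),
        max_speed_um_s=float(track_means.max()),
        pct_time_paused=100.0 * n_paused / n_steps if n_steps else np.nan,
        pct_pausing_endosomes=100.0 * sum(m.has_pause for m in included) / len(included),
        max_step_speed_um_s=float(max(m.max_step_speed_um_s for m in included)),
        pct_time_paused_track_mean=(
            float(per_track_pct.mean()) if per_track_pct.size else np.nan
        ),
        n_axons=n_axons,
        n_steps=n_steps,
    )


def speed_histogram(
    speeds: Sequence[float], bin_width: float = 0.2, n_bins: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal speed-frequency histogram in percent.

    Bins are [k*w, (k+1)*w) from zero. Returns (bin_left_edges, pct);
    percentages sum to 100 for any non-empty input. If ``n_bins`` is
    given the histogram is padded/clipped to that many bins with an
    overflow policy of extending to cover the largest speed (so nothing
    is silently dropped) unless clipping was explicitly requested.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("speed_histogram needs at least one step speed")
    k = np.floor(speeds / bin_width).astype(int)
    k_max = int(k.max())
    nb = k_max + 1 if n_bins is None else max(n_bins, k_max + 1)
    counts = np.bincount(k, minlength=nb).astype(float)
    edges = np.arange(nb) * bin_width
    return edges, 100.0 * counts / speeds.size


def group_histogram(per_animal_pct: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Across-animal mean and SEM of per-animal bin percentages."""
    nb = max(len(p) for p in per_animal_pct)
    mat = np.zeros((len(per_animal_pct), nb))
    for i, p in enumerate(per_animal_pct):
        mat[i, : len(p)] = p
    mean = mat.mean(axis=0)
    sem = (
        mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros(nb)
    )
    return mean, sem


def summarize_cohort(
    cohort,
    eps: float = DEFAULT_EPS_UM,
    *,
    bin_width: float = 0.2,
    with_histograms: bool = True,
    collect_steps: bool = False,
):
    """Quantify a whole cohort.

    Returns (summaries, all_metrics, steps_frame). ``all_metrics`` holds
    the per-track metrics for every input track (included or not), which
    is the audit trail for the filter; ``steps_frame`` is a per-step
    table (pandas) when ``collect_steps`` is True, else None.
    """
    summaries: list[AnimalSummary] = []
    all_metrics: list[TrackMetrics] = []
    step_rows = []
    for animal, group, tracks in cohort.iter_animal_groups():
        dt = cohort.dt_s[animal]
        metrics = [summarize_track(tr, dt, eps) for tr in tracks]
        all_metrics.extend(metrics)
        included_tracks = [
            tr for tr, m in zip(tracks, metrics) if m.included
        ]
        inc_metrics = [m for m in metrics if m.included]
        if not inc_metrics:
            logger.warning("animal %s group %s: no included tracks", animal, group)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = summarize_animal(inc_metrics, animal_id=animal, group=group)
        if with_histograms:
            speeds = np.concatenate(
                [
                    np.hypot(np.diff(tr.x_um), np.diff(tr.y_um)) / dt
                    for tr in included_tracks
                ]
            )
            edges, pct = speed_histogram(speeds, bin_width=bin_width)
            s.hist = pct
            s.hist_bin_width = bin_width
        summaries.append(s)
        if collect_steps:
            for tr in included_tracks:
                step_rows.extend(compute_steps(tr, dt, eps))
    steps_frame = None
    if collect_steps:
        steps_frame = pd.DataFrame(
            [s.__dict__ for s in step_rows],
            columns=[
                "animal_id", "group", "axon_id", "track_id", "step",
                "disp_um", "axial_um", "speed_um_s", "paused",
            ],
        )
    return summaries, all_metrics, steps_frame
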