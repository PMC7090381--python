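"""Core domain types for endosome track analysis.

The unit of observation is a single fluorescent punctum (a signaling
endosome) localized once per acquired frame; an ordered run of such
localizations is a :class:`Track`; all tracks of one imaging session,
grouped by animal and experimental group, form a :class:`Cohort`.

Coordinate convention: in-plane coordinates in micrometres, with the
axial (+x) direction pointing retrogradely, i.e. toward the cell body.
The transverse punctum extent (``width_um``) proxies axon caliber.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "TrackValidationError",
    "TrackTableFormatError",
    "TrackPoint",
    "Track",
    "Cohort",
    "StepRecord",
    "TrackMetrics",
    "AnimalSummary",
    "CaliberEstimate",
]


class TrackTableFormatError(ValueError):
    """A track or summary table does not conform to the documented dialect."""


class TrackValidationError(ValueError):
    """A track violates a structural invariant (ordering, gaps, widths)."""


@dataclass(frozen=True)
class TrackPoint:
    """One localization of one endosome at one frame."""

    frame: int
    t: float  # seconds
    x: float  # axial position, um; +x = retrograde
    y: float  # transverse position, um
    width: Optional[float] = None  # transverse punctum extent, um


@dataclass
class Track:
    """Ordered localizations of one endosome within one axon of one animal.

    Points are stored as parallel numpy arrays for efficiency; the
    ``points`` property materializes :class:`TrackPoint` objects.
    Frames must be consecutive integers: manual tracking in the source
    workflow follows an endosome over consecutive images, so a frame gap
    means two different tracks were conflated and is rejected.
    """

    animal_id: str
    group: str
    axon_id: str
    track_id: str
    frames: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    width_um: np.ndarray  # NaN where not measured

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.width_um is None:
            self.width_um = np.full(self.frames.shape, np.nan)
        self.width_um = np.asarray(self.width_um, dtype=float)
        n = self.frames.size
        if n == 0:
            raise TrackValidationError(f"track {self.key()}: no points")
        for arr, name in (
            (self.t_s, "t_s"),
            (self.x_um, "x_um"),
            (self.y_um, "y_um"),
            (self.width_um, "width_um"),
        ):
            if arr.size != n:
                raise TrackValidationError(
                    f"track {self.key()}: {name} has {arr.size} values for {n} frames"
                )
        if np.any(self.frames < 0):
            raise TrackValidationError(f"track {self.key()}: negative frame index")
        d = np.diff(self.frames)
        if np.any(d <= 0):
            raise TrackValidationError(
                f"track {self.key()}: frames not strictly increasing"
            )
        if np.any(d != 1):
            raise TrackValidationError(
                f"track {self.key()}: gap in frame sequence (frames must be consecutive)"
            )
        if n > 1 and np.any(np.diff(self.t_s) <= 0):
            raise TrackValidationError(
                f"track {self.key()}: timestamps not strictly increasing"
            )
        finite_w = self.width_um[np.isfinite(self.width_um)]
        if np.any(finite_w <= 0):
            raise TrackValidationError(f"track {self.key()}: non-positive width")

    def key(self) -> tuple[str, str, str]:
        return (self.animal_id, self.axon_id, self.track_id)

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(
                frame=int(f),
                t=float(t),
                x=float(x),
                y=float(y),
                width=None if not np.isfinite(w) else float(w),
            )
            for f, t, x, y, w in zip(
                self.frames, self.t_s, self.x_um, self.y_um, self.width_um
            )
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.animal_id == other.animal_id
            and self.group == other.group
            and self.axon_id == other.axon_id
            and self.track_id == other.track_id
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.t_s, other.t_s)
            and np.array_equal(self.x_um, other.x_um)
            and np.array_equal(self.y_um, other.y_um)
            and np.array_equal(self.width_um, other.width_um, equal_nan=True)
        )


@dataclass
class Cohort:
    """All tracks of a study arm, with per-animal frame intervals.

    ``dt_s`` maps animal id to the (per-movie) frame interval in seconds.
    When ``paired`` is False every animal must carry a single group label;
    a paired design (e.g. motor vs sensory axon classes recorded in the
    same animals) sets ``paired=True`` and animals may appear in two
    groups.
    """

    tracks: list[Track]
    dt_s: dict[str, float]
    paired: bool = False

    def __post_init__(self) -> None:
        seen: dict[str, set[str]] = {}
        for tr in self.tracks:
            seen.setdefault(tr.animal_id, set()).add(tr.group)
            if tr.animal_id not in self.dt_s:
                raise TrackValidationError(
                    f"animal {tr.animal_id}: no frame interval (dt_s) recorded"
                )
        if not self.paired:
            for animal, groups in seen.items():
                if len(groups) > 1:
                    raise TrackValidationError(
                        f"animal {animal} appears in multiple groups {sorted(groups)} "
                        "in an unpaired cohort"
                    )

    @property
    def animals(self) -> list[str]:
        return sorted({tr.animal_id for tr in self.tracks})

    @property
    def groups(self) -> list[str]:
        return sorted({tr.group for tr in self.tracks})

    def iter_animal_groups(self) -> Iterator[tuple[str, str, list[Track]]]:
        """Yield (animal_id, group, tracks) units of aggregation, sorted."""
        units: dict[tuple[str, str], list[Track]] = {}
        for tr in self.tracks:
            units.setdefault((tr.animal_id, tr.group), []).append(tr)
        for animal, group in sorted(units):
            yield animal, group, units[(animal, group)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        def order(tracks):
            return sorted(tracks, key=lambda t: (t.animal_id, t.group, t.axon_id, t.track_id))

        return (
            self.paired == other.paired
            and order(self.tracks) == order(other.tracks)
            and set(self.dt_s) == set(other.dt_s)
            and all(
                np.isclose(self.dt_s[a], other.dt_s[a], rtol=0, atol=1e-9)
                for a in self.dt_s
            )
        )


@dataclass(frozen=True)
class StepRecord:
    """One frame-to-frame displacement of one track."""

    animal_id: str
    group: str
    axon_id: str
    track_id: str
    step: int  # index of the step (0-based; step i joins frames i and i+1)
    disp_um: float  # Euclidean in-plane displacement magnitude
    axial_um: float  # signed axial displacement (+ = retrograde)
    speed_um_s: float
    paused: bool


@dataclass
class TrackMetrics:
    """Per-track kinematic summary and inclusion decision."""

    animal_id: str
    group: str
    axon_id: str
    track_id: str
    n_points: int
    n_steps: int
    mean_speed_um_s: float  # over ALL steps, pauses included
    max_step_speed_um_s: float
    n_paused_steps: int
    longest_pause_steps: int  # longest run of consecutive paused steps
    has_pause: bool
    net_axial_um: float
    included: bool = True
    exclusion_reason: Optional[str] = None

    @property
    def longest_pause_images(self) -> int:
        """A pause run of L steps spans L+1 consecutive images."""
        return self.longest_pause_steps + 1 if self.longest_pause_steps > 0 else 0


@dataclass
class AnimalSummary:
    """Per-animal transport statistics: the unit of statistical inference."""

    animal_id: str
    group: str
    n_tracks: int
    mean_speed_um_s: float  # mean over included tracks of per-track mean speeds
    max_speed_um_s: float  # fastest per-track mean speed
    pct_time_paused: float  # pooled: 100 * paused steps / all steps
    pct_pausing_endosomes: float  # 100 * tracks with >=1 pause / tracks
    caliber_um: Optional[float] = None
    # auxiliary metrics (see methods note)
    max_step_speed_um_s: Optional[float] = None
    pct_time_paused_track_mean: Optional[float] = None
    n_axons: Optional[int] = None
    n_steps: Optional[int] = None
    # per-bin speed-frequency percentages (left edges at k * hist_bin_width)
    hist: Optional[np.ndarray] = None
    hist_bin_width: Optional[float] = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnimalSummary):
            return NotImplemented

        def close(a, b):
            if a is None and b is None:
                return True
            if a is None or b is None:
                return False
            return bool(np.isclose(a, b, rtol=0, atol=1e-12, equal_nan=True))

        return (
            self.animal_id == other.animal_id
            and self.group == other.group
            and self.n_tracks == other.n_tracks
            and close(self.mean_speed_um_s, other.mean_speed_um_s)
            and close(self.max_speed_um_s, other.max_speed_um_s)
            and close(self.pct_time_paused, other.pct_time_paused)
            and close(self.pct_pausing_endosomes, other.pct_pausing_endosomes)
            and close(self.caliber_um, other.caliber_um)
        )


@dataclass
class CaliberEstimate:
    """Mean transverse punctum extent of one axon (caliber proxy)."""

    animal_id: str
    axon_id: str
    n_measurements: int
    mean_width_um: float
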