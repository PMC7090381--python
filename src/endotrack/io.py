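"""Reading and writing track tables and per-animal summary tables.

Track-table dialect: plain CSV, UTF-8, one header row, columns

    animal_id, group, axon_id, track_id, frame, t_s, x_um, y_um, width_um

one row per endosome per frame; ``width_um`` may be empty. Coordinates
are micrometres in a per-axon frame with +x = retrograde. Timestamps
must satisfy t_s = frame * dt within 1e-6 s for a per-animal frame
interval dt (a warning is logged otherwise); dt is inferred from the
timestamps on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    AnimalSummary,
    Cohort,
    Track,
    TrackTableFormatError,
    TrackValidationError,
)

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "animal_id",
    "group",
    "axon_id",
    "track_id",
    "frame",
    "t_s",
    "x_um",
    "y_um",
    "width_um",
]

SUMMARY_COLUMNS = [
    "animal_id",
    "group",
    "n_tracks",
    "mean_speed_um_s",
    "max_speed_um_s",
    "pct_time_paused",
    "pct_pausing_endosomes",
    "caliber_um",
]

_T_TOL_S = 1e-6


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrackTableFormatError(
            f"{what} is missing required column(s): {', '.join(missing)}"
        )


def read_track_table(
    path: Union[str, Path], *, paired: bool = False
) -> Cohort:
    """Read a CSV track table into a validated :class:`Cohort`.

    Rows are grouped into tracks by (animal_id, axon_id, track_id) and
    sorted by frame; structural invariants (consecutive frames, strictly
    increasing timestamps, positive widths) are enforced.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str,
                                  "axon_id": str, "track_id": str},
                     float_precision="round_trip")
    _check_columns(df, TRACK_COLUMNS, f"track table {path}")
    tracks: list[Track] = []
    if len(df):
        df = df.sort_values(["animal_id", "axon_id", "track_id", "frame"],
                            kind="mergesort")
        for (animal, axon, track_id), g in df.groupby(
            ["animal_id", "axon_id", "track_id"], sort=True
        ):
            groups = g["group"].unique()
            if len(groups) != 1:
                raise TrackValidationError(
                    f"track ({animal}, {axon}, {track_id}) spans multiple groups"
                )
            tracks.append(
                Track(
                    animal_id=str(animal),
                    group=str(groups[0]),
                    axon_id=str(axon),
                    track_id=str(track_id),
                    frames=g["frame"].to_numpy(),
                    t_s=g["t_s"].to_numpy(float),
                    x_um=g["x_um"].to_numpy(float),
                    y_um=g["y_um"].to_numpy(float),
                    width_um=g["width_um"].to_numpy(float),
                )
            )
    dt_s = _infer_frame_intervals(tracks)
    return Cohort(tracks=tracks, dt_s=dt_s, paired=paired)


def _infer_frame_intervals(tracks: Iterable[Track]) -> dict[str, float]:
    """Per-animal frame interval from timestamps (t_s = frame * dt)."""
    dt_s: dict[str, float] = {}
    by_animal: dict[str, list[Track]] = {}
    for tr in tracks:
        by_animal.setdefault(tr.animal_id, []).append(tr)
    for animal, trs in by_animal.items():
        diffs = np.concatenate(
            [np.diff(tr.t_s) for tr in trs if tr.n_points > 1]
            or [np.array([np.nan])]
        )
        if not np.any(np.isfinite(diffs)):
            raise TrackValidationError(
                f"animal {animal}: frame interval cannot be inferred "
                "(no track has >= 2 points)"
            )
        dt = float(np.median(diffs))
        dt_s[animal] = dt
        for tr in trs:
            expected = tr.frames * dt
            if np.max(np.abs(tr.t_s - expected)) > _T_TOL_S:
                logger.warning(
                    "track %s: t_s deviates from frame * dt (dt=%.6g s) "
                    "by more than %g s", tr.key(), dt, _T_TOL_S,
                )
    return dt_s


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the track-table row layout (sorted)."""
    rows = []
    for tr in sorted(cohort.tracks, key=lambda t: (t.animal_id, t.axon_id, t.track_id)):
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "group": tr.group,
                    "axon_id": tr.axon_id,
                    "track_id": tr.track_id,
                    "frame": tr.frames,
                    "t_s": tr.t_s,
                    "x_um": tr.x_um,
                    "y_um": tr.y_um,
                    "width_um": tr.width_um,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def write_track_table(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort as a CSV track table (deterministic order)."""
    df = cohort_to_frame(cohort)
    df.to_csv(path, index=False, lineterminator="\n")


def summaries_to_frame(summaries: Sequence[AnimalSummary]) -> pd.DataFrame:
    records = []
    for s in sorted(summaries, key=lambda s: (s.group, s.animal_id)):
        records.append(
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "n_tracks": s.n_tracks,
                "mean_speed_um_s": s.mean_speed_um_s,
                "max_speed_um_s": s.max_speed_um_s,
                "pct_time_paused": s.pct_time_paused,
                "pct_pausing_endosomes": s.pct_pausing_endosomes,
                "caliber_um": np.nan if s.caliber_um is None else s.caliber_um,
                "max_step_speed_um_s": (
                    np.nan if s.max_step_speed_um_s is None else s.max_step_speed_um_s
                ),
                "pct_time_paused_track_mean": (
                    np.nan
                    if s.pct_time_paused_track_mean is None
                    else s.pct_time_paused_track_mean
                ),
            }
        )
    cols = SUMMARY_COLUMNS + ["max_step_speed_um_s", "pct_time_paused_track_mean"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame.from_records(records)[cols]


def write_summary_table(
    summaries: Sequence[AnimalSummary], path: Union[str, Path]
) -> None:
    """Write per-animal summaries as CSV (one row per animal x group)."""
    summaries_to_frame(summaries).to_csv(path, index=False, lineterminator="\n")


def read_summary_table(path: Union[str, Path]) -> list[AnimalSummary]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str},
                     float_precision="round_trip")
    _check_columns(df, SUMMARY_COLUMNS, f"summary table {path}")
    out = []
    for _, r in df.iterrows():
        out.append(
            AnimalSummary(
                animal_id=str(r["animal_id"]),
                group=str(r["group"]),
                n_tracks=int(r["n_tracks"]),
                mean_speed_um_s=float(r["mean_speed_um_s"]),
                max_speed_um_s=float(r["max_speed_um_s"]),
                pct_time_paused=float(r["pct_time_paused"]),
                pct_pausing_endosomes=float(r["pct_pausing_endosomes"]),
                caliber_um=(
                    None if pd.isna(r.get("caliber_um")) else float(r["caliber_um"])
                ),
                max_step_speed_um_s=(
                    None
                    if pd.isna(r.get("max_step_speed_um_s"))
                    else float(r["max_step_speed_um_s"])
                ),
                pct_time_paused_track_mean=(
                    None
                    if pd.isna(r.get("pct_time_paused_track_mean"))
                    else float(r["pct_time_paused_track_mean"])
                ),
            )
        )
    return out
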