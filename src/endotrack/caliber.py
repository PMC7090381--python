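"""Axon caliber estimation from the transverse extent of transported puncta.

Caliber is proxied by the distance between the upper and lower margins
of the fluorescent puncta, measured orthogonally to the transport
direction (the ``width_um`` field of the track points). Measurements are
taken along the axon: puncta widths are subsampled to one measurement
per 1-um axial bin to avoid treating repeated sightings of the same
endosome at the same position as independent measurements. At least ten
measurements per axon and three axons per animal are the advisory
minima; fewer triggers a warning, not an error.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .model import CaliberEstimate, Cohort, Track

__all__ = [
    "MIN_MEASUREMENTS_PER_AXON",
    "TARGET_AXONS_PER_ANIMAL",
    "axon_caliber",
    "animal_caliber",
    "axon_width_measurements",
    "cohort_calibers",
]

MIN_MEASUREMENTS_PER_AXON = 10
TARGET_AXONS_PER_ANIMAL = 3
AXIAL_BIN_UM = 1.0


def axon_caliber(
    widths: Sequence[float],
    *,
    animal_id: str = "",
    axon_id: str = "",
) -> CaliberEstimate:
    """Mean punctum width of one axon; warns below ten measurements."""
    widths = np.asarray(widths, dtype=float)
    widths = widths[np.isfinite(widths)]
    if widths.size == 0:
        raise ValueError(f"axon {axon_id!r}: no width measurements")
    if np.any(widths <= 0):
        raise ValueError(f"axon {axon_id!r}: non-positive width measurement")
    if widths.size < MIN_MEASUREMENTS_PER_AXON:
        warnings.warn(
            f"axon {axon_id!r}: only {widths.size} width measurements "
            f"(advisory minimum {MIN_MEASUREMENTS_PER_AXON})",
            stacklevel=2,
        )
    return CaliberEstimate(
        animal_id=animal_id,
        axon_id=axon_id,
        n_measurements=int(widths.size),
        mean_width_um=float(widths.mean()),
    )


def animal_caliber(estimates: Sequence[CaliberEstimate]) -> float:
    """Unweighted mean of per-axon mean widths; warns if not 3 axons."""
    if not estimates:
        raise ValueError("animal_caliber needs at least one axon estimate")
    if len(estimates) != TARGET_AXONS_PER_ANIMAL:
        warnings.warn(
            f"{len(estimates)} axon(s) used for animal caliber "
            f"(target {TARGET_AXONS_PER_ANIMAL})",
            stacklevel=2,
        )
    return float(np.mean([e.mean_width_um for e in estimates]))


def axon_width_measurements(
    tracks: Sequence[Track], bin_um: float = AXIAL_BIN_UM
) -> np.ndarray:
    """Width measurements along one axon, one per distinct axial bin.

    All finite punctum widths of the axon's tracks are pooled; within
    each ``bin_um``-wide axial-position bin the mean width is taken as a
    single measurement.
    """
    xs, ws = [], []
    for tr in tracks:
        ok = np.isfinite(tr.width_um)
        xs.append(tr.x_um[ok])
        ws.append(tr.width_um[ok])
    x = np.concatenate(xs) if xs else np.array([])
    w = np.concatenate(ws) if ws else np.array([])
    if x.size == 0:
        return np.array([])
    bins = np.floor(x / bin_um).astype(int)
    out = []
    for b in np.unique(bins):
        out.append(w[bins == b].mean())
    return np.asarray(out)


def cohort_calibers(
    cohort: Cohort, *, bin_um: float = AXIAL_BIN_UM
) -> tuple[list[CaliberEstimate], dict[tuple[str, str], float]]:
    """Per-axon estimates and per-(animal, group) mean calibers.

    Axons without any width data are skipped. Returns
    (axon_estimates, {(animal_id, group): caliber_um}).
    """
    by_axon: dict[tuple[str, str, str], list[Track]] = {}
    for tr in cohort.tracks:
        by_axon.setdefault((tr.animal_id, tr.group, tr.axon_id), []).append(tr)
    estimates: list[CaliberEstimate] = []
    per_unit: dict[tuple[str, str], list[CaliberEstimate]] = {}
    for (animal, group, axon), trs in sorted(by_axon.items()):
        widths = axon_width_measurements(trs, bin_um=bin_um)
        if widths.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = axon_caliber(widths, animal_id=animal, axon_id=axon)
        estimates.append(est)
        per_unit.setdefault((animal, group), []).append(est)
    animal_means: dict[tuple[str, str], float] = {}
    for unit, ests in per_unit.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            animal_means[unit] = animal_caliber(ests)
    return estimates, animal_means
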