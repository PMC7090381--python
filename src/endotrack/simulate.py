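"""Synthetic cohorts from a two-state run-and-pause motility model.

Each endosome track is a discrete-time hidden Markov chain at frame
resolution with states M (moving) and P (paused) and per-frame
transition probabilities p_MP (move -> pause) and p_PM (pause -> move);
the chain is started from its stationary distribution, whose paused
fraction is pi_P = p_MP / (p_MP + p_PM). A moving step displaces the
endosome axially by v * dt with v drawn from a lognormal moving-speed
distribution (median ``v_med``, log-sd ``sigma_v``); with probability
``q_antero`` the step direction is flipped to anterograde. Paused steps
have zero true displacement. Independent isotropic Gaussian
localization noise ``sigma_loc`` is added to every coordinate, and the
punctum width is drawn per frame around the axon's true caliber.

Between-animal variability enters as lognormal multiplicative factors
on the moving speed, on p_MP and on the axon caliber; in paired designs
the same animal factor applies to all of that animal's groups, so the
within-animal contrast is more precise than the between-animal one —
the property the paired design exploits.

Defaults emulate the intravital imaging workflow the analysis targets:
frame intervals uniform in 2.4-3.2 s, ~50 tracks per animal, geometric
track lengths with minimum 5 points and mean ~10 (so a typical animal
contributes a few hundred frame-to-frame steps), and 5-11 animals per
group. Effect sizes in the presets are synthetic choices made to be
detectable at those group sizes; they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np

from .model import Cohort, Track

__all__ = [
    "GroupParams",
    "SimParams",
    "GroundTruth",
    "simulate_track",
    "simulate_cohort",
    "preset_cohorts",
    "PRESETS",
]


@dataclass(frozen=True)
class GroupParams:
    """Motility and cohort-structure parameters of one group."""

    v_med: float = 1.8  # median moving speed, um/s
    sigma_v: float = 0.35  # lognormal shape of moving speed
    p_mp: float = 0.10  # per-frame move -> pause probability
    p_pm: float = 0.60  # per-frame pause -> move probability
    sigma_loc: float = 0.02  # localization noise sd, um
    q_antero: float = 0.02  # probability a moving step is anterograde
    min_points: int = 5  # minimum track length, frames
    geom_p: float = 0.16  # geometric tail of extra frames (mean extra = 1/p)
    tracks_per_animal: int = 50
    n_animals: int = 8
    n_axons: int = 3
    caliber_um: float = 3.0  # true mean axon caliber
    caliber_axon_cv: float = 0.15  # axon-to-axon caliber CV within animal
    width_frame_cv: float = 0.10  # per-frame width measurement CV

    def validate(self) -> None:
        for name in ("p_mp", "p_pm", "q_antero", "geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.geom_p <= 0.0:
            raise ValueError("geom_p must be > 0")
        if self.v_med <= 0:
            raise ValueError("v_med must be > 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.caliber_um <= 0:
            raise ValueError("caliber_um must be > 0")

    @property
    def pi_paused(self) -> float:
        """Stationary paused fraction of the two-state chain."""
        if self.p_mp == 0.0:
            return 0.0
        return self.p_mp / (self.p_mp + self.p_pm)

    @property
    def mean_moving_speed(self) -> float:
        """Mean of the lognormal moving-speed distribution, um/s."""
        return self.v_med * np.exp(self.sigma_v**2 / 2.0)


@dataclass(frozen=True)
class SimParams:
    """Full specification of a simulated study."""

    groups: dict  # group label -> GroupParams
    paired: bool = False  # same animals contribute to every group
    dt_range: tuple = (2.4, 3.2)  # per-animal frame interval, s
    animal_speed_cv: float = 0.10  # between-animal CV on v_med
    animal_pause_cv: float = 0.15  # between-animal CV on p_mp
    animal_caliber_cv: float = 0.10  # between-animal CV on caliber
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for gp in self.groups.values():
            gp.validate()
        lo, hi = self.dt_range
        if not 0 < lo <= hi:
            raise ValueError("dt_range must be positive with lo <= hi")
        if self.paired:
            ns = {gp.n_animals for gp in self.groups.values()}
            if len(ns) != 1:
                raise ValueError("paired designs need equal n_animals per group")


@dataclass
class GroundTruth:
    """Hidden quantities behind a simulated cohort."""

    # (animal_id, group, axon_id, track_id) -> per-step hidden state array
    # (True = paused)
    states: dict
    pi_paused: dict  # group -> stationary paused fraction
    mean_moving_speed: dict  # group -> true mean moving speed, um/s
    axon_caliber: dict  # (animal_id, group, axon_id) -> true caliber, um


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal factor with unit median and given CV."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(np.exp(rng.normal(0.0, sigma)))


def _simulate_states(n_steps: int, p_mp: float, p_pm: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Hidden state per step (True = paused), stationary start."""
    if n_steps <= 0:
        return np.empty(0, dtype=bool)
    pi_p = p_mp / (p_mp + p_pm) if (p_mp + p_pm) > 0 else 0.0
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=bool)
    states[0] = u[0] < pi_p
    for i in range(1, n_steps):
        if states[i - 1]:
            states[i] = u[i] >= p_pm  # stays paused with prob 1 - p_pm
        else:
            states[i] = u[i] < p_mp
    return states


def simulate_track(
    gp: GroupParams,
    dt: float,
    rng: np.random.Generator,
    *,
    animal_id: str = "a0",
    group: str = "g0",
    axon_id: str = "x0",
    track_id: str = "t0",
    speed_factor: float = 1.0,
    pause_factor: float = 1.0,
    caliber_um: Optional[float] = None,
) -> tuple[Track, np.ndarray]:
    """Simulate one track; returns (Track, hidden paused-state array).

    ``speed_factor`` and ``pause_factor`` are the animal-level
    multiplicative random effects on v_med and p_mp.
    """
    gp.validate()
    p_mp = min(1.0, gp.p_mp * pause_factor)
    n_points = gp.min_points + int(rng.geometric(gp.geom_p)) - 1
    n_steps = n_points - 1
    states = _simulate_states(n_steps, p_mp, gp.p_pm, rng)
    v = gp.v_med * speed_factor * np.exp(rng.normal(0.0, gp.sigma_v, n_steps))
    sign = np.where(rng.random(n_steps) < gp.q_antero, -1.0, 1.0)
    dx = np.where(states, 0.0, sign * v * dt)
    x = np.concatenate(([0.0], np.cumsum(dx)))
    y = np.zeros(n_points)
    if gp.sigma_loc > 0:
        x = x + rng.normal(0.0, gp.sigma_loc, n_points)
        y = y + rng.normal(0.0, gp.sigma_loc, n_points)
    cal = gp.caliber_um if caliber_um is None else caliber_um
    widths = np.maximum(
        cal * (1.0 + gp.width_frame_cv * rng.standard_normal(n_points)), 0.05
    )
    frames = np.arange(n_points)
    track = Track(
        animal_id=animal_id,
        group=group,
        axon_id=axon_id,
        track_id=track_id,
        frames=frames,
        t_s=frames * dt,
        x_um=x,
        y_um=y,
        width_um=widths,
    )
    return track, states


def simulate_cohort(params: SimParams) -> tuple[Cohort, GroundTruth]:
    """Simulate a full multi-group cohort, reproducibly from the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tracks: list[Track] = []
    dt_s: dict[str, float] = {}
    truth = GroundTruth(
        states={},
        pi_paused={g: gp.pi_paused for g, gp in params.groups.items()},
        mean_moving_speed={g: gp.mean_moving_speed for g, gp in params.groups.items()},
        axon_caliber={},
    )
    group_names = list(params.groups)
    if params.paired:
        n_animals = next(iter(params.groups.values())).n_animals
        animal_ids = [f"a{i + 1:02d}" for i in range(n_animals)]
        # shared per-animal factors: the paired design's within-animal
        # correlation comes from here
        factors = {
            a: (
                _lognormal_factor(rng, params.animal_speed_cv),
                _lognormal_factor(rng, params.animal_pause_cv),
                _lognormal_factor(rng, params.animal_caliber_cv),
            )
            for a in animal_ids
        }
        for a in animal_ids:
            dt_s[a] = float(rng.uniform(*params.dt_range))
        for g in group_names:
            gp = params.groups[g]
            for a in animal_ids:
                _simulate_animal(gp, g, a, dt_s[a], factors[a], rng, tracks, truth)
    else:
        for g in group_names:
            gp = params.groups[g]
            for i in range(gp.n_animals):
                a = f"{g}_a{i + 1:02d}"
                dt_s[a] = float(rng.uniform(*params.dt_range))
                factors = (
                    _lognormal_factor(rng, params.animal_speed_cv),
                    _lognormal_factor(rng, params.animal_pause_cv),
                    _lognormal_factor(rng, params.animal_caliber_cv),
                )
                _simulate_animal(gp, g, a, dt_s[a], factors, rng, tracks, truth)
    return Cohort(tracks=tracks, dt_s=dt_s, paired=params.paired), truth


def _simulate_animal(gp, group, animal_id, dt, factors, rng, tracks, truth):
    speed_f, pause_f, caliber_f = factors
    axon_ids = [f"{group}_x{j + 1}" for j in range(gp.n_axons)]
    calibers = {}
    for ax in axon_ids:
        calibers[ax] = gp.caliber_um * caliber_f * _lognormal_factor(
            rng, gp.caliber_axon_cv
        )
        truth.axon_caliber[(animal_id, group, ax)] = calibers[ax]
    for k in range(gp.tracks_per_animal):
        ax = axon_ids[k % len(axon_ids)]
        tid = f"t{k + 1:03d}"
        tr, states = simulate_track(
            gp,
            dt,
            rng,
            animal_id=animal_id,
            group=group,
            axon_id=ax,
            track_id=tid,
            speed_factor=speed_f,
            pause_factor=pause_f,
            caliber_um=calibers[ax],
        )
        tracks.append(tr)
        truth.states[(animal_id, group, ax, tid)] = states


def _mk(name_to_gp: dict, **kw) -> SimParams:
    return SimParams(groups=name_to_gp, **kw)


def _presets() -> dict[str, SimParams]:
    base = GroupParams()
    mutant = replace(base, v_med=base.v_med * 0.75, p_mp=base.p_mp * 2.0)
    return {
        # three identical groups: the null calibration design
        "null": _mk(
            {
                "NTg": replace(base, n_animals=8),
                "grpB": replace(base, n_animals=8),
                "grpC": replace(base, n_animals=8),
            },
            seed=0,
        ),
        # paired motor (ChAT+) vs sensory (ChAT-) axon classes: motor
        # faster and thicker, pausing alike
        "motor_vs_sensory": _mk(
            {
                "ChAT+": replace(base, v_med=2.0, caliber_um=3.0, n_animals=5),
                "ChAT-": replace(base, v_med=1.6, caliber_um=1.5, n_animals=5),
            },
            paired=True,
            seed=0,
        ),
        # control + wildtype-transgene + two mutant groups: mutants
        # slower with doubled pausing entry
        "tdp43_9mo": _mk(
            {
                "NTg": replace(base, n_animals=11),
                "TDP43-WT": replace(base, n_animals=6),
                "TDP43-M337V-hemi": replace(mutant, n_animals=8),
                "TDP43-M337V-homo": replace(mutant, n_animals=8),
            },
            seed=0,
        ),
        # speed-matched groups that differ only in pausing
        "fus_18mo": _mk(
            {
                "Fus-WT": replace(base, n_animals=7),
                "Fus-D14": replace(base, p_mp=base.p_mp * 2.0, n_animals=6),
            },
            seed=0,
        ),
    }


PRESETS = tuple(sorted(_presets()))


def preset_cohorts(name: str, seed: Optional[int] = None) -> SimParams:
    """A documented parameter bundle by name; see ``PRESETS``."""
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(presets))}"
        )
    p = presets[name]
    if seed is not None:
        p = replace(p, seed=seed)
    return p


def params_to_dict(params: SimParams) -> dict:
    """JSON/YAML-serializable form of SimParams (for provenance files)."""
    d = asdict(params)
    d["groups"] = {g: asdict(gp) for g, gp in params.groups.items()}
    d["dt_range"] = list(params.dt_range)
    return d
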