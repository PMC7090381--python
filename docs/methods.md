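# Methods

## Quantification model

`endotrack` analyzes tables of manually or automatically tracked
fluorescent puncta: one row per endosome per frame, with in-plane
coordinates in µm. The axial axis (+x) points retrogradely by
convention; the source imaging literature does not fix units or axes,
so this convention is defined here and enforced throughout.

**Steps and speeds.** A track of *n* consecutive frames yields *n*−1
frame-to-frame steps. Speed is the Euclidean in-plane displacement
magnitude over the frame interval Δt — not the axial component —
because point tracking measures total in-plane motion. Δt is a
per-movie (per-animal) scalar; timestamps must satisfy t = frame·Δt
within 1 µs or a warning is logged. On read, Δt is inferred as the
median timestamp difference per animal.

**Pauses.** A step is paused when its displacement magnitude is below a
tolerance ε. The underlying experimental definition ("same position on
two consecutive images") carries no tolerance; ε is therefore a
required, reported parameter with default **0.1 µm**, the approximate
single-pixel localization granularity of manual tracking at the
acquisition zoom the workflow emulates. A pause run of L steps spans
L+1 consecutive images.

**Track filter.** A track is excluded iff, checked in this order with
the first matching rule reported:
(a) fewer than 5 consecutive frames;
(b) longest pause run spanning more than 10 consecutive images (the
long-pauser rule — in the source workflow these tracks are dropped over
phototoxicity concerns; here the filter, not the optics, is modeled);
(c) solely anterograde, operationalized as: every non-paused step has
negative axial displacement *and* the net axial displacement is
negative. This tolerates paused steps within an otherwise anterograde
track and never fires on a net-stationary one.

**Per-track and per-animal metrics.** Per-track mean speed averages
*all* step speeds, paused steps included (speed across the entire
tracked run, not only while motile). Per animal, over included tracks:
mean speed = mean of per-track means; **maximum speed = the fastest
per-track mean speed** — "fastest endosome", with the endosome as the
speed-carrying unit; the fastest single step is kept as the auxiliary
column `max_step_speed_um_s` since the alternative reading (fastest
single step) cannot be excluded. % time paused is the pooled ratio of
paused steps to all steps ×100; a per-track-percentage-averaged variant
is stored as `pct_time_paused_track_mean`, pooled being primary.
% pausing endosomes is the share of included tracks with ≥1 pause.
Advisory minima — ≥6 tracks from ≥2 axons per animal — produce
warnings, not errors. Speed histograms use bins [k·w, (k+1)·w) from 0
with default w = 0.2 µm/s (the source binning is unpublished); per-bin
values are percentages of that animal's steps, and group curves are
across-animal mean ± SEM.

**Axon caliber.** Caliber is proxied by the transverse punctum extent
(`width_um`). Widths are pooled per axon and subsampled to one
measurement per 1-µm axial bin before averaging, so repeated sightings
of a punctum at the same position do not pseudo-replicate; whether the
original protocol measured one or several endosomes per position is
unknown, making the bin subsampling a design choice. Per-animal caliber
is the unweighted mean of per-axon means; <10 measurements per axon or
≠3 axons per animal warn.

## Statistics

The animal is the unit of inference. Data are assumed normal unless
the D'Agostino–Pearson omnibus test rejects at α = 0.05; the omnibus
test needs n ≥ 8, so smaller groups (most real cohorts here have
n = 5–11) default to the normality assumption rather than an undefined
test. The decision tree is deterministic and the chosen test is
recorded in every result:

| design | normal | non-normal |
|---|---|---|
| 2 groups, paired | paired t | paired t (by design) |
| 2 groups, independent | pooled-variance t | Mann-Whitney U |
| ≥3 groups vs control | one-way ANOVA + Dunnett | Kruskal-Wallis + Dunn |

Pooled-variance t is the default (the classical default of the era's
analysis software), Welch available by flag. Mann-Whitney uses exact
enumeration when both groups have n ≤ 8 (no tie correction there) and
the tie-corrected normal approximation otherwise. Dunnett's two-sided
comparisons come from the multivariate-t distribution
(`scipy.stats.dunnett`, seeded); an independent Monte-Carlo max-|t|
simulation of the same null is kept in the test suite as an oracle.
Dunn's post-hoc z contrasts versus control use pooled mid-ranks with
tie correction; the adjustment over the k−1 control contrasts is
Bonferroni by default (configurable — the original software's choice of
Dunn adjustment is not recoverable). Post-hoc contrasts are reported
unconditionally rather than gated on the omnibus p, matching common
practice in the field's software. All p values are two-tailed; α=0.05.

## Synthetic cohorts

The generator emulates the *statistical structure* of intravital
endosome-transport data, not its optics: no point-spread function,
photobleaching, tracking errors or axon curvature. Passing tests
therefore demonstrate correctness of the quantification and inference
machinery under the stated generative model — they do not validate
tracking accuracy on real movies.

Motility is a two-state (move/pause) discrete-time Markov chain at
frame resolution — the 2.4–3.2 s sampling interval cannot resolve
sub-frame motor switching, so the model deliberately lives at the
observation scale. Chains start from the stationary distribution, whose
paused fraction is π_P = p_MP/(p_MP+p_PM). Moving speeds are lognormal
(strictly positive, right-skewed, single-mode — the observed
per-population speed distributions are bell-shaped, not bimodal).

Defaults (per group, chosen once as field-realistic values):

| parameter | default | meaning |
|---|---|---|
| `v_med` | 1.8 µm/s | median moving speed (fast retrograde transport) |
| `sigma_v` | 0.35 | lognormal shape of moving speed |
| `p_mp` | 0.10 | move→pause per frame |
| `p_pm` | 0.60 | pause→move per frame (mean pause ≈ 1.7 frames ≈ 5 s) |
| `sigma_loc` | 0.02 µm | localization noise sd |
| `q_antero` | 0.02 | probability a moving step is anterograde |
| `min_points`/`geom_p` | 5 / 0.16 | geometric track length, mean ≈ 10 frames |
| `tracks_per_animal` | 50 | matches ~50 endosomes tracked per animal |
| caliber | 3.0 µm (motor-like) | per-frame width CV 0.10, axon CV 0.15 |

With these sizes an animal contributes ≈ 460 frame-to-frame steps —
the order of magnitude real animals produce. Between-animal lognormal
random effects (CV 0.10 on speed, 0.15 on p_MP, 0.10 on caliber) make
the animal, not the track, the dominant variance unit; in paired
designs the same animal factor applies to both groups, which is what
gives the paired t its power advantage.

Presets bundle documented designs: `motor_vs_sensory` (paired, n = 5;
motor v_med 2.0 vs sensory 1.6 µm/s, calibers 3.0 vs 1.5 µm),
`tdp43_9mo` (NTg n = 11, wildtype-transgene n = 6, two mutant groups
n = 8 with v_med ×0.75 and p_MP ×2), `fus_18mo` (n = 7 vs 6, equal
speeds, p_MP ×2 only) and `null` (three identical groups, n = 8).
Preset effect sizes are synthetic choices sized to be detectable at
those group counts; no quantitative per-genotype parameters are
published, so the presets reproduce qualitative patterns, not measured
values.

## Numerical and design notes

- Determinism: one `numpy` Generator seeded from `SimParams.seed`
  drives the whole simulation; the Dunnett computation receives its own
  seeded generator; output CSVs impose fixed row/column order and the
  run log carries no timestamps, so identical config + seed gives
  byte-identical outputs. CSVs round-trip floats exactly
  (`float_precision="round_trip"` on read).
- Degenerate inputs: single-point tracks are valid data but carry no
  steps (excluded as too-short); zero-variance paired differences and
  <2 values per group are errors; empty tables write header-only files.
- Cohorts normally require each animal in exactly one group; a
  `paired` flag relaxes this for within-animal designs (axon classes
  recorded in the same animals).
- Blinding: an option relabels groups through a keyed mapping before
  statistics and unblinds in the report, mirroring genotype-blinded
  tracking.
- Problem sizes: the test suite runs its null-calibration at 2000
  replicates with 8 tracks per animal — the familywise error of the
  animal-level test does not depend on the within-animal track count —
  and the pattern-reproduction checks at 50 replicates at full preset
  size. `scripts/acceptance.py` uses 400 null replicates.
- Known limitations: no sub-frame kinetics, no tracking/linking errors,
  no photobleaching model, straight axons only (y ≈ 0), and the pause
  tolerance ε is a proxy for an undocumented manual-tracking criterion.
  The long-pause filter slightly truncates the pause distribution, so
  the recovered % time paused sits a fraction of a percentage point
  below π_P by construction.
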