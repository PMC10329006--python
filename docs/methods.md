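# Methods

## Scope and data model

The package analyses meiosis-I chromosome dynamics from point tracks: two
spindle poles and, per bivalent, two homolog centroids plus (optionally) two
endpoint markers per homolog, sampled on a regular time grid. All positions
are physical micrometres; time is stored in seconds relative to anaphase
onset (negative before), matching the convention of time-resolved
segregation studies. Tracks come either from the simulator, from the
image-processing pipeline, or from any external tool that writes the track
CSV schema.

The spindle frame is re-derived at every frame from the current pole
positions — the spindle rotates and elongates, so no frozen axis is used and
no temporal smoothing is applied by default. The bivalent center is defined
as the mean of the two homolog centroids (not an intensity-weighted
centroid); this choice is recorded in the metric table's provenance and is
the only sensible option in a point-track data model.

## Metric definitions and conventions

- Orientation uses two angles. The *labeled* angle (0–180°) keeps fixed
  homolog identities — homolog 1 is the homolog nearer pole A at the first
  tracked frame — and detects orientation reversions as crossings above 90°
  persisting at least 3 frames. The *folded* angle min(θ, 180° − θ) is
  label-free and drives threshold classification. This reconciles an
  inclusive orientation threshold in [0°, 90°] with a reversion criterion
  that needs signed identity.
- Threshold comparisons are inclusive (metric ≤ threshold counts as
  correct). Boundary ties are measure-zero on real data; the convention is
  stated here and in the API docs.
- Oscillation is the absolute first difference of the equator distance at
  the native frame interval (10 s by default): a constrained, non-oscillatory
  approach to the plate yields a decaying series, oscillatory motion a
  persistent one.
- Bivalent length is the maximum pairwise distance among the four endpoint
  markers — the outermost extent of the bivalent. With collinear rod-shaped
  homologs this equals inter-homolog distance plus homolog length.
- Undefined angles (coincident homolog centroids) become NaN and are
  excluded from classification denominators.

## Threshold calibration

The three state thresholds are calibrated on a control cohort as *means over
oocytes of per-oocyte maxima*: the maximum folded angle at the onset frame,
and the maximum equator/axis distances over a metaphase window (−100 s to 0
by default; the window length is a package choice since "metaphase" has no
sharp start). Per-oocyte (rather than per-chromosome) maxima were chosen;
the alternative is one flag away in the code and gives slightly larger
thresholds. Published control values for this system are 22.5°, 0.5 µm and
1.6 µm; these are also the defaults used when no control cohort is supplied.

## Fate classification

Fates are called from each homolog's signed equator coordinate
s(t) = (pos − m)·u:

- at the fate-call time t_end (+120 s default): `co_segregating` if both
  homologs share a sign with |s| ≥ d_seg (2 µm); `normal` if signs are
  opposite, both cleared, and neither homolog lagged;
- a homolog is *lagging* when |s| < d_lag (1 µm) at the mid-anaphase
  checkpoint (+60 s) while at least half of all homologs in the oocyte have
  cleared d_seg (so a globally delayed anaphase is not scored as lagging);
- lagging homologs resolve to `lagging_correct` (opposite side at t_end) or
  `lagging_missegregated` (same side, or still near the equator).

d_seg, d_lag, t_check and t_end are package decisions (the original fate
judgments were made by eye from movies); all are exposed in the
configuration. If a homolog's track ends during anaphase — typically inside
the crowded polar chromosome mass — its last post-onset observation is
carried forward, on the grounds that a segregated chromosome does not leave
its spindle half; bivalents with no post-onset observations are reported
`uncallable` and excluded from ploidy. Ploidy is euploid iff no bivalent
co-segregated or mis-segregated, evaluated at t_end.

## Angle–fate association

The mis-segregation indicator is regressed on the folded angle at onset by
logistic maximum likelihood (statsmodels). Significance comes from a seeded
label-permutation test (10,000 permutations by default) on the logistic
*score* statistic Σ θᵢ(yᵢ − ȳ): under the null the labels are exchangeable,
so the test is exact at any sample size, and the score statistic is the
locally most powerful statistic for the slope at zero — permuting it is
equivalent to permuting the slope test while costing one matrix product
instead of thousands of model fits. Complete separation is detected before
fitting and reported as an infinite slope with a flag; the permutation
p-value remains valid in that case. With fewer than two fate categories the
association is reported as undefined rather than fitted.

## Onset detection

Anaphase onset is detected per oocyte from the cohesion-release jump in the
oocyte-median inter-homolog distance: the first increment exceeding
median + k·MAD of all increments (k = 5). On control-like dynamics this is
exact to the frame. Perturbations in which many bivalents co-segregate or
lag mute the median jump and can delay detection by a frame or two; for such
cohorts the manual onset override (`--onset`) is the supported path, which
mirrors how onset is annotated in practice.

## Image-processing pipeline

Spot detection is scale-normalized Laplacian-of-Gaussian filtering with
per-axis sigmas scaled by the voxel spacing (anisotropy must be known;
unknown axial spacing is an error). Peaks are collected per scale with a
minimal 3×3×3 footprint — fine scales resolve near-touching spots that merge
in coarser responses — then deduplicated across scales (strongest response
first, minimum separation half the minimum diameter), and "parent" blobs
whose radius encloses two or more finer detections are discarded as
unresolved unions. Each scale additionally applies a robust noise floor
(15× the MAD of its own response map) so shot noise amplified at fine scales
cannot produce spurious peaks. Positions are refined by an intensity-weighted
centroid in a quarter-diameter window — symmetric around an isolated blob but
short enough not to bleed into a close neighbour. The minimum detection
diameter defaults to 0.8 µm, the scale used for chromosome spotting in this
system.

Poles are located from the tubulin channel by intensity-weighted PCA of
voxel positions above the 99th-percentile intensity (the spindle occupies a
small volume fraction, so a high threshold removes diffuse background
weight), with poles placed at the 2nd/98th weighted percentiles of the
projection onto the principal axis; a near-isotropic distribution raises a
"no spindle axis" error. A/B labels persist by nearest-previous-position
matching.

Linking is greedy mutual-nearest-neighbor per frame under a displacement
budget (1 µm/frame default) with gap closing (2 frames default; the
end-to-end pipeline uses 4 because plate crowding can occlude a chromosome
for several frames). Candidate distances take the minimum of the linearly
predicted and the raw last position, so directed anaphase motion and sudden
direction changes are both tolerated; leftover deadlocks from chained
preferences are resolved by optimal assignment on the admissible remainder.
Homologs are paired into bivalents by minimum-total-distance perfect
matching (networkx general-graph matching) at the earliest frame with
exactly twelve live tracks — early prometaphase, before congression packs
the plate — and bivalents are numbered by distance to pole A. A
manual-edits CSV (track remaps, spot deletions) can be applied after
linking, replacing interactive curation.

## The synthetic cohort generator

The generator is a kinematic phenomenology, not a force model. Per oocyte:
a fixed spindle pose (axis mostly in-plane so rendered stacks fit the 9 µm
axial range), poles at ±L/2 with L = 7 µm, elongating at 0.05 µm/s after
onset. Per bivalent, three coupled states evolve by discrete
Ornstein-Uhlenbeck relaxation: the orientation angle relaxes toward 0 at
rate k_orient once the oocyte's bipolarization time (normal, mean −350 s,
SD 50 s) has passed; the axial plate coordinate and the radial distance
relax at k_congress with additive noise. There is no inertial term, hence
no imposed oscillation — with zero positional noise the congression
increments decay monotonically. A preset fraction of bivalents
("persistently misoriented") never relaxes and wanders around its own high
set-point angle. Homolog and bivalent lengths grow linearly by ΔL (1 µm
split between inter-homolog distance and homolog lengths) over the
stretching window −150 s to −50 s.

At onset, cohesion release adds an instantaneous 0.4 µm jump to the
inter-homolog distance (the signal the onset detector keys on). Each
bivalent's fate is drawn with P(mis-segregate) = logistic(β0 + β1·θ_onset)
from the measured folded angle at the onset frame; mis-segregating bivalents
split between co-segregation and mis-segregating laggards, correct ones
between normal and correctly-resolving laggards. Anaphase kinematics follow
the drawn fate: leaders separate at v_push + v_pull (0.05 µm/s), laggards
hover near the equator until +70 s then move at 0.09 µm/s to their final
side, co-segregating pairs move together to one (random) side. Chromosomes
spread slowly over the polar cup (transverse expansion 0.4%/s), as arriving
chromosomes do.

Fate draws use an RNG stream independent of trajectory noise and a fixed
draw count per bivalent, so raising β1 with the same seed changes fates
monotonically without perturbing a single trajectory — the monotonicity
property is exact, not statistical.

Five presets mirror a kinetochore-perturbation series: `control`;
`knl1_null` (35% persistently misoriented, loose congression, strong
positive β1); `lateral_loss` (delayed but recovered orientation);
`endon_loss` (no stretching, wide plate, no pulling, accurate segregation);
`combined_loss` (additionally no pushing, angle-dependent errors). Relaxation
rates and noise levels are simulator tuning knobs — no quantitative rates
exist to copy — chosen once so that a simulated control cohort calibrates
near the published thresholds (≈0.5 µm congression, ≈1.6 µm compaction,
orientation maxima around 18–22°) and the null preset reproduces the
perturbation phenotypes qualitatively (roughly two-thirds oriented at onset,
about half congressed, 65–85% aneuploidy). The plate layout staggers
azimuths and interleaves radii (0.6–1.4 µm) so neighbouring homolog pairs
never sit closer than ≈0.9 µm — the simulator guarantees the resolvability
that the detection contract assumes.

Rendering draws each homolog as an anisotropic Gaussian blob (object SD
0.25 µm convolved with a PSF of SD 0.35/0.15/0.15 µm in z/y/x) in the
chromatin channel and poles plus an elongated spindle body in the tubulin
channel, on the acquisition grid (30 planes × 0.3 µm, 10 s frames, 0.11 µm
pixels — the lateral pixel size is a typical spinning-disk value, not a
published one, and is configurable). Noise is Poisson with the rate scaled
so the peak signal-to-noise ratio equals the requested value.

### What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes: relaxation
kinetics coupled to bipolarization, non-oscillatory congression, the
stretching ramp, the onset jump, fate-dependent anaphase kinematics, and an
angle-fate logistic link. It does not model forces, chromosome shape,
kinetochore substructure, polar-body extrusion, photobleaching, or optical
aberrations beyond a Gaussian PSF. Passing tests therefore demonstrate that
the pipeline recovers truth under the stated geometry, noise and kinematic
assumptions — not that it is robust to every failure mode of real
microscopy (dense chromatin masses, focus drift, strong background). The
per-timepoint state proportions of real perturbed cohorts are emulated only
qualitatively.

## Problem sizes and numerical choices

Tests and the acceptance script use reduced problem sizes chosen to exercise
every code path at meaningful statistical power: 20-oocyte cohorts for
calibration and proportions, 10–20 oocytes for fate/onset recovery,
2 rendered oocytes × 20 frames at snr 5 for detection metrics, and 100/200
8-oocyte cohorts for slope-sign recovery and type-I error. Geometry oracles
run 1000 random configurations at 1e−9 absolute tolerance. Degenerate
inputs (coincident poles or homologs, blank frames, empty ROIs, zero-length
lines, missing onset jumps) raise typed errors or NaN flags as documented
per function rather than propagating silently.
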