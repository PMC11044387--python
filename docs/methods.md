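# Methods

This note documents the models, conventions and numerical choices behind
`cervikin`, and what the synthetic benchmarks do and do not demonstrate.

## Scope and conventions

Only the lower cervical spine is analyzed: vertebrae C4–C7 and the motion
segments C4-C5, C5-C6, C6-C7. All angles are degrees; extension is positive.
A segment's angle is the rotation of its upper vertebra relative to its
lower one (`theta_upper − theta_lower`), referenced to zero at the first
analysis frame. The C4–C7 *block* angle is defined as the sum of the three
segmental angles, which equals `theta_C4 − theta_C7` identically — additivity
is exact by construction everywhere in the pipeline. Image coordinates are
pixels, origin top-left, y down, frames 0-based; rotations are
counter-clockwise positive in the y-up (viewing) sense. Recordings emulate a
10 frames/s acquisition of 1024 × 1024 frames with the extension half of the
movement covered in 52 frames (≈ 5 s of a 10 s flexion–extension cycle; the
flexion/extension split of the protocol is not fixed, so the frame count is
a parameter). Recordings that start in neutral position instead of full
flexion run through the same code and cover only the second half of
extension; their ROM values are not comparable with full-sweep recordings.

## Synthetic ground-truth kinematics

Each recording is generated from a `MotionProfileSpec`: per-segment total
rotations (must sum to the block total `trom`), contribution peak centers on
the cumulative-rotation axis, Gaussian peak widths, an optional trailing
C4-C5 bump (relative height `trailing_c45_fraction`, default centre
0.97·trom), per-frame noise SD, frame count and seed.

Per-frame increments for segment *i* follow a **baseline + bump** density in
a latent progress coordinate *u* ∈ [0, trom]:

    inc_i(u) ∝ (1 − μ)·base(u) + μ·N(u; c_i, w_i)

where μ (`peak_mass_fraction`, default 0.7; 0.55 in the cohort profiles) is
the fraction of the segment's rotation carried by its bump, and `base` is
either flat (default) or a broad shared "early phase" Gaussian
(`early_phase_center_frac`/`early_phase_width_frac`). The early phase is not
cosmetic: the cumulative-rotation axis is *generated by* the contributions,
so terminal peaks (at 55–88 % of cumulative rotation, as in the normal
pattern) are only geometrically possible if most of the rotation mass
precedes them. Columns are scaled so each segment's increments sum exactly
to its total (conservation to machine precision); the block is the row sum,
so additivity is exact. Because the measured block coordinate is itself the
cumulative row sum, bump centres are recentred by a fixed-point iteration
(inverting the monotone latent→measured map, ≤ 20 iterations) so the
contribution maxima land at the *requested* cumulative-rotation coordinates
within the frame grid resolution. The block consequently advances only
approximately uniformly over frames — faster while a segment is at its
peak, as in real recordings. Frame noise is i.i.d. Gaussian on the segmental
increments; an optional compensated negative dip in C5-C6 emulates the
negative-motion excursions seen in low-motion recordings.

Cohort profiles: `young_profile` uses segment totals (11.1, 7.9, 6.8)°
(tROM 25.8°, the scale of the study cohort's first session), ordered peak
centres at (0.55, 0.72, 0.88)·trom inside the terminal half, widths 1.6°,
trailing fraction 0.3, noise 0.05°/frame. `elderly_profile` uses reduced
totals (9.3, 7.1, 5.9)° (second-session scale), a non-identity permutation
of the centres (breaking the normal order), widths 1.5° and noise
0.15°/frame. `generate_cohort(n, mix, seed)` draws exactly `round(mix·n)`
young-pattern individuals, jitters centres (±0.3°) and totals (±10 %)
per individual without breaking the label's ordering structure, and is
bit-reproducible given the seed.

### Phantom rendering

`render_frames` draws each recording as a lateral-view phantom: four
trapezoidal vertebral bodies on a mildly lordotic arc, each rotated rigidly
about its own centre by its absolute rotation (C7 held fixed), rasterized at
4× supersampling then area-averaged (anti-aliased edges), Gaussian-blurred
(σ = 1.5 px) with additive intensity noise (SD 0.01). The geometry scales
with the image size; tests use 256 px frames to keep runtimes small, the
default is the 1024 px acquisition format. True per-frame poses are returned
alongside the stack. The phantom is deliberately schematic — uniform body
intensity, no soft tissue, no perspective or distortion — it exists to
benchmark pose recovery against known ground truth, not to look like
fluoroscopy.

## Tracking

Each vertebra is annotated once, on frame 0, as a simple polygon. The
template samples the pixels under the contour dilated by 3 px (a uniform
body interior carries no signal; the information is at the edges). Candidate
rigid poses (θ about the contour centroid, plus translation) are scored by
normalized cross-correlation against the reference frame; each frame is
solved by a coarse grid search around the previous pose (±2°, ±8 px; steps
0.5°, 2 px — generous for fluent motion at 10 frames/s) followed by
Nelder–Mead refinement (xatol 0.01). Frames whose best score falls below
`min_score` (0.5) — or whose template has no intensity variance — are
flagged *lost*, logged, and carried (never silently interpolated). Manual
corrections replace a single pose, are logged with old and new values, and
produce a new pose set so downstream kinematics are recomputed.

On default phantoms the tracker recovers vertebral angles with ≈ 0.07–0.13°
mean absolute error and corner positions within ≈ 0.1 px — comfortably below
the 0.3° significance threshold the classifier uses, which is the property
that matters: angular errors of that size cannot create or destroy a
significant peak. This demonstrates correct pose recovery on rendered
phantoms only; equivalence with any particular clinical tracking software
cannot be claimed from phantom recovery.

## SSC curves

Segmental series are smoothed with a Savitzky–Golay filter (window 5,
order 2) whose endpoints are pinned to the raw values, so the net rotation
of the smoothed series equals the raw net exactly and every curve integral
is conserved to machine precision (noiseless; ≈ 0.1° under default noise the
conservation target is the noisy net). The smoothed block is the sum of the
smoothed segments (additivity preserved). The x-axis is the running maximum
of the smoothed block: frames where the block regresses fold back onto their
running-maximum coordinate while their (possibly negative) contributions are
retained. Cumulative segment angles are interpolated piecewise-linearly onto
a uniform grid (0.1° cells); the cell-wise slope is the contribution *rate*
(deg/deg), and the reported curve `y` is the rate times the *local*
per-frame block advance — i.e. degrees of rotation per frame interval, the
scale on which the 0.3° significance rule is defined. Recordings whose net
block extension is below 3° (configurable) are flagged
`insufficient_motion` instead of producing a curve.

ROM summaries offer two methods: `endpoint` (|last − first|) and the default
`extremal` (max − min over the path), because maximal segmental rotation is
often reached away from the movement endpoints; the method used is recorded
in the output. Which method produced any given literature value is generally
unknowable, so both are kept.

## Sequence classification

Peaks are local maxima of the per-segment curve padded with zero
contribution on both sides (no motion outside the movement; bumps at the
window edge still count), with plateaus collapsed to their midpoint.
**Prominence**, not raw height, is compared against the significance
threshold (0.3°) so shoulders on a monotone rise are not counted as peaks.
Classification restricts to the terminal phase — the last 50 % of cumulative
rotation (configurable; the pattern window is the second half of
extension) — and selects each segment's most prominent significant peak
there. The recording is classified `+` iff:

1. all three segments have a significant peak in the terminal phase,
2. the selected peaks are strictly ordered C4-C5 < C5-C6 < C6-C7 in x,
3. no two selected peaks lie within the tie tolerance (0.5° of cumulative
   rotation) — coincident peaks have no defined order and classify `-` with
   reason `tie` rather than guessing, and
4. every C4-C5 local maximum *after* the selected C6-C7 peak has height
   below 0.5× the selected C4-C5 peak's height (the normal small trailing
   peak; "much smaller" is not quantified anywhere authoritative, so the
   0.5 ratio is a package choice recorded in the output). The rule compares
   visible heights and applies to sub-threshold maxima too: it is a relative
   criterion, and a threshold-gated version would break the monotonicity
   property that raising the significance threshold can never turn `-`
   into `+`.

Otherwise `-`, with explicit reason codes
(`no-significant-peak:<segment>`, `order-violation`, `tie`,
`trailing-c45-too-large`, `insufficient-motion`). Classification is
deterministic in the curve and configuration.

## Alignment and eligibility

Cobb angles are signed angles between endplate lines given as
anterior/posterior landmark pairs: C2–C7 alignment between the inferior
endplates of C2 and C7 (the standard convention; the segment-level angles
use the superior endplate of the upper and the inferior endplate of the
lower vertebra). Lordosis is positive, kyphosis negative; magnitude ≤ 90°;
the subject is assumed to face the left of the image (configurable). The
angle is invariant under global rigid transforms and uniform scaling of the
landmarks, and antisymmetric under swapping the two lines. Eligibility:
age in [55, 70], NDI ≤ 4 points (the filter applies to points; the percent
form is carried for reporting), and Kellgren score ≤ 3 in every segment
(grade 4 excludes); reasons are enumerated for exclusions. Kellgren grading
itself is an input, never computed from pixels.

## Statistics

- **ICC(A,k)** (two-way, absolute agreement, average measures) from the
  ANOVA mean squares: `(MSR − MSE) / (MSR + (MSC − MSE)/n)` with rows =
  targets, columns = raters. Zero total variance raises a distinct error.
  Tests verify agreement with pingouin's independent implementation to
  1e-9 on seeded random matrices.
- **Spearman** uses average ranks for ties; the two-sided p-value is exact
  (full enumeration of all n! pairings) for n ≤ 8, a seeded Monte-Carlo
  permutation estimate (99,999 draws, add-one corrected) for 8 < n ≤ 30,
  and asymptotic beyond. Specific correlation p-values printed in the
  literature are not regression targets here: the exact variable pairings
  (timepoint, per-segment pairing of tROM with KS) are ambiguous, so the
  pairing is an explicit argument instead.
- **Test–retest variability** per individual: SD of the two session values
  (`|T1 − T2|/√2`) and CV = SD/mean (zero mean raises).
- **Table summaries** round the mean half-away-from-zero to the printed
  precision (the tables' one-decimal style); bracketed ranges are reproduced
  as column min/max but not asserted — several printed brackets conflict
  with their own columns. Two printed *average* cells conflict with their
  own column entries (study-table T1 C6-C7: printed 5.8 vs column-derived
  6.8; external-table T2 C6-C7: printed 2.6 vs 3.3) and are excluded from
  regression; all other verified column means reproduce exactly at printed
  precision.

## What the synthetic benchmarks show — and don't

Passing tests demonstrate that the pipeline recovers known poses from
rendered phantoms, conserves rotation through the SSC construction, and
classifies constructed consistent/inconsistent patterns perfectly in the
noiseless regime, degrading monotonically with frame noise. They do not
validate the biological finding: the loss of the consistent sequence in
elderly individuals is represented only by the transcribed cohort outcomes
(prevalence 10 % at T1, 0 % at T2) and by synthetic cohorts whose labels are
true by construction. Real fluoroscopy differs from the phantom in contrast,
occlusion, out-of-plane motion and annotation error, so phantom tracking
accuracy is an upper bound on real-data accuracy.

## Problem sizes in tests and the acceptance script

Phantom benchmarks use 256 px frames and 16-frame recordings; classification
rates use 200 recordings per condition at 52 frames; ICC oracle checks use
20 random matrices (3–9 targets × 2–4 raters). These sizes give stable
statistics while keeping the whole suite around half a minute on one CPU.
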