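# cervikin

Quantitative analysis of **cervical spine motion quality** from dynamic
flexion–extension fluoroscopy, for the lower cervical spine (C4–C7).

Quantity of motion — segmental range of motion (sROM) and total C4–C7 range
of motion (tROM) — is notoriously variable between sessions and individuals.
A more stable descriptor of *quality* of motion is the **sequence of
segmental contributions (SSC)** during extension: plotting each segment's
per-frame sagittal rotation against the cumulative rotation of the C4–C7
block, asymptomatic young adults show a characteristic terminal-phase order
of contribution peaks,

```
C4-C5  →  C5-C6  →  C6-C7
```

with peaks below 0.3° of per-frame rotation deemed insignificant, and a
small late C4-C5 peak (much smaller than its main peak) considered normal.
`cervikin` implements the full pipeline needed to measure and classify this
pattern, plus the cohort statistics used to report it:

- **`cervikin.synthetic`** — ground-truth kinematics generator (controllable
  peak structure, totals, noise) and a lateral-view phantom renderer with
  true per-frame vertebral poses, so every downstream stage is testable
  without any recordings.
- **`cervikin.tracking`** — rigid 2-D template tracking of annotated
  vertebral contours across an image stack (normalized cross-correlation,
  coarse grid search + simplex refinement), with lost-frame reporting and
  logged manual corrections.
- **`cervikin.kinematics`** — segmental angle series, cumulative block
  rotation (exactly additive), SSC curves on a uniform cumulative-rotation
  grid (Savitzky–Golay smoothing, running-maximum monotonization, exact
  integral conservation), and endpoint/path-extremal ROM summaries.
- **`cervikin.classification`** — prominence-based peak detection, the
  0.3° significance rule, terminal-phase ordering, tie handling and the
  trailing-C4-C5 rule; cohort prevalence.
- **`cervikin.alignment`** — Cobb angles from endplate landmarks (C2–C7 and
  per segment, lordosis positive) and the study eligibility filter
  (age 55–70, NDI ≤ 4 points, Kellgren score ≤ 3 in every segment).
- **`cervikin.stats`** — ICC(A,k) two-way absolute-agreement average-measures
  reliability from ANOVA mean squares, Spearman rank correlation with exact
  permutation p-values at small n, per-individual test–retest SD and CV, and
  printed-table summaries.
- **`cervikin.datasets`** — packaged CSV transcriptions of the study's
  cohort tables (baseline characteristics, ROM per individual/timepoint,
  external-validation group).

## Worked example

Generate a noiseless recording with the consistent young-adult pattern,
analyze it, and classify the sequence (the `cspine` CLI wraps the library):

```bash
cspine simulate --label young_consistent --seed 3 --noise-sd 0 --out rec
cspine analyze  --angles rec/angles.csv --out analysis
cspine classify --angles rec/angles.csv --out cls.json
```

prints `tROM 25.8 deg` and `+`, and `cls.json` contains

```json
{
 "presence": "+",
 "selected_peaks": {
  "C4-C5": {"x_deg": 13.85, "height_deg": 0.646},
  "C5-C6": {"x_deg": 18.35, "height_deg": 0.557},
  "C6-C7": {"x_deg": 22.25, "height_deg": 0.482}
 }
}
```

i.e. the three segments reach their maximal per-frame contribution (all
above the 0.3° significance threshold) in cranial-to-caudal order along the
cumulative-rotation axis — the normal extension sequence, classified `+`.
The analysis directory holds the SSC curve (CSV + PNG) and the ROM summary:
`sROM = (11.1, 7.9, 6.8)°`, `tROM = 25.8°` (path-extremal method).

The same works from images: `cspine render` draws the recording as a phantom
TIFF stack with contour annotations, and `cspine track` recovers the poses
(mean absolute angular error ≈ 0.07–0.13° at default blur/noise, well below
the 0.3° significance threshold):

```bash
cspine render --recording rec --size 256 --out frames
cspine track  --frames frames/frames.tif --contours frames/contours.json --out poses.csv
cspine analyze --poses poses.csv --out analysis2
```

Cohort tables are reproduced from the packaged fixtures:

```bash
cspine report --table rom
```

recomputes the average rows — tROM mean 25.8° [15.5; 55.8] at T1 and
22.3° [8.1; 53.5] at T2 — and `cspine report --table baseline` the cohort
summary (mean age 61, sequence prevalence 10% at T1, 0% at T2).

## Layout

```
src/cervikin/        library (synthetic, tracking, kinematics,
                     classification, alignment, stats, io, cli, datasets)
src/cervikin/data/   packaged cohort-table CSV fixtures
tests/               pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md      models, conventions, numerical choices, limitations
```
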