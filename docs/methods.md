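# Methods

This note documents the models, conventions and design choices behind
`trochwarp`, what the synthetic phantoms do and do not emulate, and the
numerical details a user re-deriving results will need.

## Coordinate frame and angle conventions

All geometry lives in a canonical body frame: **x̂ lateral** (toward the
measured hip), **ŷ ventral**, **ẑ cranial**; units are mm and degrees. The
measured frame is constructed from two midline landmarks — the centre of the
sacral vertebrae and the centre of the anus — seen on a dorsal frontal
image: the vertical axis is the unit vector along their difference, the
horizontal axis the in-plane orthogonal direction, and the ventral axis
completes the right-handed triad. Angles are therefore invariant to patient
translation and uniform scaling, and equivariant under in-plane tilt (a 5°
tilted patient shifts every AY angle by 5°).

* **AY angle** (plate inclination): unsigned acute angle in [0°, 90°]
  between a direction's frontal-plane projection and the horizontal axis.
  All published values are positive and the manual protocol measures an
  acute angle, so no sign is carried.
* **Frontal trajectory angle**: signed elevation of the frontal projection,
  `atan2(z, |x|)`, negative for a caudomedial course.
* **Transverse trajectory angle**: signed deviation from the frontal plane,
  `atan2(y, |x|)`, negative for a dorsomedial course.

A direction is reconstructed from the two planar angles as the normalised
`(−1, tan τ, tan α)`; the reflection ambiguity of the pair is resolved
toward medial (negative lateral component), the femoral→pelvic reading that
makes abductor frontal angles positive. The reconstruction round-trips
through the two angle operations to < 1e-9°.

## Default warp profiles (constrained reconstruction)

The individual twelve layer means were never published — only summary
anchors: ventral-third mean 51.64°, dorsal-third mean 18.60°,
calibration-layer (6) angle 43.70°, a +2° rise from layer 1 to 2, a total
layer-1 − layer-12 decrease of 33.44°, and the largest inter-layer drop
between layers 8 and 9. The default profile is a *reconstruction* that
satisfies all six anchors exactly, closed by a fixed interpolation rule
(`solve_warp_profile`):

1. dorsal third: arithmetic ramp of slope −0.4°/layer around its mean (the
   profile is described as stable past the transition);
2. layer 1 from layer 12 + total decrease; layer 2 = layer 1 + rise;
3. layers 3–4: arithmetic continuation from layer 2, step solved from the
   ventral-third mean;
4. layer 5 midway between layer 4 and the calibration angle; layers 7–8
   continue the mid-third slope.

The output is frozen as package constants and audited in tests by direct
arithmetic. "Total decrease" is read as the endpoint difference
layer 1 − layer 12 (a thirds-means difference would give 33.04, inconsistent
with the printed 33.44; a regression-slope reading is also rejected for the
same reason). The juvenile default shares the ventral anchors but has a
decrease 8° smaller (dorsal third lifted by 8°), qualitatively matching the
reported smaller pediatric dorsal decline; the exact juvenile numbers are
unpublished and configurable. The pooled profile doubles as the adult
default.

## Synthetic phantoms

A phantom realises exactly what the measurement pipeline consumes:

* a **ruled plate surface** of 12 ventro-dorsal bands over a 36 mm extent
  (12 × 3 mm, typical MRI slice thickness); the trace of band *k* in any
  frontal plane is a straight segment at elevation `warp[k]`, centred on a
  fixed frontal position. Trace lengths peak at layer 6 (30 mm) and taper
  by 3 mm/layer; the taper is steep enough that the maximum-extent
  calibration slice remains identifiable under the default point noise, as
  the labelling protocol presumes;
* an **ellipsoidal trochanter** (semi-axes 11 × 13 × 13.5 mm) for axial
  slicing — nine 3 mm slices, maximal diameter at the equatorial reference
  slice (label 5). Coxa valga shifts the trochanter medially
  (0.25 mm/° above a 130° CCD);
* **landmarks** (sacral centre, anus centre, trochanter tip) and
* **attachment points** from the packaged map (below).

Defaults: adult CCD 130° (juvenile 145°, drawn N(·, 3°) per subject and
thus above the adult distribution), anteversion 15°/30°, point-noise
SD 0.5 mm (no measurement-error model was published; 0.5 mm is sub-voxel
for the emulated acquisitions). Cohorts optionally add per-subject,
per-layer Gaussian warp variation (`warp_sd_deg`, default 0) to model
between-patient biology. Noise is realised at *slicing* time from an RNG
derived from the phantom seed, so phantoms themselves are exact and
everything is bit-reproducible for a fixed (spec, seed); cohort member
seeds derive from the master seed by fixed increment.

**What the phantoms do not emulate:** image intensities, partial-volume and
segmentation error, curved plate traces within a slice, anatomically
realistic muscle paths, or growth over time. Passing planted-recovery tests
therefore shows the *measurement chain* is unbiased and correctly labelled,
not that the protocol is robust to real-image segmentation ambiguity.

## Slicing, calibration and labels

Frontal slices bin the plate extent ventral→dorsal (default 12 bins); each
trace is the in-band plate segment sampled at 25 points and projected onto
the slice-centre plane, so a doubled thickness merges neighbouring bands
into one trace. The calibration slice is the one of maximal longitudinal
extent, measured as the peak-to-peak extent of the trace points projected
onto the trace's own total-least-squares line — identical to polyline arc
length for clean straight traces, but robust to point noise (raw arc length
of a noisy polyline is inflated by the noise zigzag and would randomise the
selection). Axial calibration maximises the outline diameter (largest
pairwise distance). Ties resolve toward the more ventral/cranial slice
(arbitrary but fixed).

Labels: axial reference 5, with `5 − x` cranial and `5 + y` caudal. The
frontal analogue is an extension of the published axial scheme: calibration
at 6, `6 − v` ventral, `6 + d` dorsal, fixed at 6 for every subject. A
stated "five slices ventral and dorsal" reading would give 11 layers while
the summary plots show 12; the 12-layer reading (five ventral, six dorsal)
is adopted.

## AY measurement and statistics

Plate lines are total-least-squares fits (SVD of the centred trace),
oriented to positive lateral component. For a perfectly symmetric V-shaped
trace the fit is the bisecting axis — a documented degenerate case. The
per-layer AY profile is summarised by thirds means over layers 1–4 / 5–8 /
9–12 (their mean equals the 12-layer mean by construction), the calibration
angle, the endpoint total decrease, and a transition detector: the largest
absolute consecutive difference among layers ≥ 2, excluding the ventral
rise so the detector reports the dorsal jump. Missing layers yield partial
summaries with explicit `None` fields.

Group contrast: adult-minus-juvenile mean total decrease with a seeded
patient-level percentile bootstrap (default 1000 replicates). No named test
was published for the decrease, so the bootstrap is supplied as a
transparent, assumption-light interval.

## Trajectory tables and the attachment map

The published mean angles (frontal: ventral/middle/dorsal; transverse:
cranial/middle/caudal; pooled/adult/juvenile columns) are packaged as
constants. The default attachment map is *reverse-engineered*: for each
muscle and region slot, a femoral point near the trochanter and a pelvic
point 80 mm along the direction reconstructed from the two table angles.
Straight-line directions of the map therefore reproduce the tables to
machine precision — the map is a modelling fixture, not anatomy.

Conventions and fallbacks, fixed once:

* the two stratifications share three region slots; `cranial` aliases the
  ventral slot and `caudal` the dorsal slot, so one attachment pair carries
  both planar angles;
* empty cells fall back to the muscle's mean over its available regions in
  the same group column, then to the pooled column (this reproduces the
  published whole-muscle comparison means, e.g. gluteus maximus 58.03°);
* the gluteus maximus' two tabulated fibre fields are averaged per slot;
* muscles absent from the transverse table run parallel to the frontal
  plane (τ = 0);
* triceps coxae is one functional unit (gemelli + obturator internus), as
  tabulated.

The centroid-path method (chord through per-slice cross-section centroids)
is implemented as an independent oracle: it equals the straight-line
direction exactly for straight prismatic bellies and returns the chord for
curved ones, which is how the two classical methods are related.

## Force model

Members: internal band = {gluteus medius, gluteus minimus, vastus
lateralis}; external band = {gluteus maximus, tensor fasciae latae,
iliotibial band}; posterior system = {piriformis, triceps coxae, obturator
externus, quadratus femoris}. Forces are `σ · PCSA · û` along the
straight-line directions; σ and any uniform PCSA rescaling cancel from all
angle outputs. The iliotibial band and the fascial coupling of the other
vasti have no tabulated PCSA and enter as configurable equivalent areas,
default 0.

Regional assembly: ventral and middle regions carry the lateral bands at
their region-specific directions. The dorsal region carries the lateral
bands' *middle*-region resultant unchanged plus the rotators at their
dorsal directions and the periosteal counterforce — the trajectory tables
have no dorsal entries for several lateral-band members, so the model
attributes all dorsal-specific change to the posterior system; zeroing the
posterior weight then reduces the dorsal prediction exactly to the middle
one, a clean ablation.

The periosteal counterforce is `β |R_rot| (sin φ, 0, −cos φ)` with the
lateral tilt opposing the rotators' medial pull. The published account of
the parallelogram is qualitative, so both parameters are free with
documented defaults:

* `β` defaults to the calibration `β* = |R_rot,x| / (|R_rot| sin φ)`, which
  zeroes the lateral component of the posterior resultant — the redirected
  dorsal force is then frontally vertical (elevation 90°, "almost
  vertical"), and the posterior contribution scales linearly with rotator
  weight, making the dorsal prediction strictly monotone in it;
* `φ` = 60° by default. For the redirected resultant to stay cranially
  directed, φ must exceed the rotator resultant's frontal deviation from
  vertical, which ranges up to ≈ 44° across the packaged PCSA sources; a
  small φ (e.g. 15°) with calibrated β flips the posterior resultant
  caudally, partially cancelling the lateral bands and breaking the
  regional ordering, so the steeper default is used. β* is ≈ 0.53 (Lube),
  0.78 (Klein/Horsmann), 0.94 (Brand).

Predicted inclination per region is `90° − elevation(R_region)`, the
perpendicular-alignment principle. Under defaults, every packaged PCSA
source yields ventral > middle > dorsal predicted AY — the direction of the
measured warp — though the absolute predictions (≈ 64/61/54° for Lube) sit
above the measured thirds means (51.6/42.1/18.6°): the model is a
direction-of-effect argument, not a calibrated stress analysis.

PCSA bookkeeping: Brand's printed obturator-externus value (3795 cm²) is a
decimal-point artifact; the table stores it raw and the force model uses
the flagged correction 3.795 cm² by default (configurable). Brand lacks a
quadratus femoris value: the strict group-sum operation raises a
missing-member error, while the force model contributes zero area with a
warning so predictions remain computable for all sources. The grouped
comparison (A = proximally directed muscles, B = external rotators) uses
obturator *externus* as B's fourth member — the only reading consistent
with the printed Lube sums; of the printed ratios only Pierrynowski's
(41.20) reproduces as 100·B/A from its printed sums, so recomputed ratios
are reported alongside the stored printed ones. Literature trajectory
comparison values are stored as reference constants only (with a flagged
suspect entry) and never recomputed.

## Pipeline and reproducibility

`RunConfig` (pydantic-validated) fixes cohort sizes, noise, slice settings,
PCSA source and counterforce parameters; an empty cohort is rejected before
any stage runs. Every run writes the resolved config beside its outputs;
identical config + seed reproduce all tables byte-for-byte. Angles are
serialized with four decimals, dot-decimal, for diff-stability; logging is
timestamped to stderr. Default problem sizes (cohorts of 5 + 5, 25 points
per trace, 1000 bootstrap replicates; 200-rerun Monte-Carlo checks with
n = 20 phantoms in the test suite) keep a full run in seconds while leaving
Monte-Carlo standard errors well below the effects being recovered.

## Known limitations

* The phantom's plate traces are straight within a slice; real traces curve
  and the manual protocol's within-slice averaging is not modelled.
* The per-layer default profile is a constrained reconstruction, not
  published raw data; only its six anchor quantities are evidence-backed.
* The attachment map reproduces published *angles*; moment arms, muscle
  lengths and attachment footprints are schematic.
* The force model is quasi-static, unit-free and linear in PCSA; gait-phase
  loading, hip-joint reaction forces and absolute magnitudes in newtons are
  out of scope.
* Transverse angles of muscles absent from the transverse table default to
  0°, which underestimates their dorso-ventral force components.
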