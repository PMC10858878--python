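# Methods

This note records the model, the parameter choices, and the numerical and
design decisions behind `palsymetry`, at the level of detail a maintainer
or reviewer needs to trust (or challenge) the outputs.

## Input model

The unit of analysis is a landmark clip: per-frame 98-point (x, y)
coordinates in the WFLW numbering plus a frame rate, covering a
neutral → show-teeth → close motion of a few seconds recorded face-on.
Landmark roles are pinned by `LandmarkScheme`: mouth corners 76 (anatomical
right) and 82 (left), outer lip ring 76–87, eye-bottom triples 65–67 /
73–75, nose-bottom arc 55–59, face-width contour pair 6–26. Indices are
0-based, coordinates use the image convention (origin top-left, y down),
and "left/right" are anatomical sides, not image sides. Detection gaps may
be bridged by per-landmark linear interpolation (`interpolate_gaps`), by
default only up to fps/6 consecutive missing frames (~0.17 s); longer
dropouts are an error rather than silently fabricated data.

## Preprocessing

1. **Temporal Gaussian smoothing** of every coordinate series, σ expressed
   in seconds so it is frame-rate independent. Default σ = 0.05 s
   (1.5 frames at 30 fps): enough to damp frame-to-frame localization
   jitter, an order of magnitude below the 0.5 s displacement window it
   must not blur. The kernel is truncated at 4σ with nearest-value boundary
   extension. Smoothing is applied to the raw pixel coordinates (before
   scale or midline correction) so per-frame width division does not
   amplify jitter.
2. **Scale correction**: all coordinates divided by the face width
   (distance between contour landmarks 6 and 26), per frame by default.
3. **Midline frame**: per frame, the right/left eye-bottom centroids and
   the nose-bottom centroid define an orthonormal frame — first axis from
   the right eye centroid toward the left, second axis perpendicular,
   oriented from the nose toward the eyes. Landmarks are re-expressed in
   this frame (origin at the nose centroid). Eye bottoms are used because
   the eye region is largely spared by central palsy and the lower lid is
   less affected by ptosis than the upper; the nose anchor keeps the
   midline centred on the mouth.

The composition is exactly invariant under translation, rotation and
uniform scaling of the raw coordinates (asserted to 1e-9 end to end).
Because smoothing precedes the change of basis, a *time-varying* pose
(head drift) is not perfectly cancelled; with the default σ the residual
effect on the indices is of order 1e-5 and is covered by a regression test
rather than an invariance claim. A fixed-reference-midline variant
(`per_frame_midline=False`, axes from the time-averaged landmarks) exists
for sensitivity analysis.

## The indices

**SMM** is the cosine similarity of the two mouth corners' sliding-window
displacement-magnitude series (window T = round(0.5 s × fps) frames,
stride 1, all N − T windows). Both series are nonnegative, so SMM ∈ [0, 1].
If either corner never moves the denominator vanishes and SMM is returned
as *undefined* (`None`), never coerced to 0: complete palsy with a
motionless corner is outside the index's domain and must be visible as
such to callers. Note the uncentered form also implies a noise floor — two
corners jittering independently with i.i.d. localization error produce a
cosine near E|d|²-type ratios (≈ 0.7–0.8), not 0; observed severe-patient
values around 0.73–0.79 are consistent with that floor, and "SMM ≈ 0"
is not reachable in practice.

**DMS** rasterizes the outer-lip polygon per frame onto a square grid.
The bounding rectangle is axis-aligned in the midline frame and widened to
be symmetric about the midline, so reflection maps grid columns to grid
columns *exactly* (column j ↔ n_cols − 1 − j) and the fold introduces no
resampling error. The width is divided into 200 columns (configurable);
row count follows from squareness. A cell belongs to the mouth region iff
its center lies inside the closed polygon (boundary inclusive, even–odd
rule; membership evaluated with exact geometric predicates via shapely);
cells whose centers fall exactly on the midline belong to neither side.
Per frame the asymmetry is |R ⊕ L′|/(|R| + |L|) with L′ the folded left
set; DMS is the mean over all N frames of the clip — no expression
segmentation is applied, matching the index's definition over the whole
neutral–smile–close recording. Self-intersecting or zero-area contours
raise a geometry error naming the frame; frames are never silently
dropped. At 400 columns the grid ratio agrees with an exact
polygon-clipping area oracle to within 0.01 (tested on random simple
polygons); convergence is O(1/columns).

The outer lip ring (76–87) is used as "the mouth contour": drooping of the
lip margin is the morphology DMS targets. Cell membership by center with
boundary-inclusive ties is one of several defensible discretizations; all
agree in the fine-grid limit.

## Group comparison

Two-sided Mann–Whitney U per index, healthy vs patient. Midranks for ties;
exact enumeration p when the smaller group has ≤ 8 observations and the
pooled data are tie-free, otherwise the normal approximation with tie and
continuity corrections. The choice is recorded in the result's `method`
field, because the packaged cohort table is rounded to two decimals and
therefore tied, forcing the approximate path where the original unrounded
data may have permitted other conventions.

## Classification and evaluation

Unregularized maximum-likelihood logistic regression on the raw (SMM, DMS)
pair — deliberately the simplest usable classifier, so performance is
attributable to the indices. Perfectly separable training data (where the
MLE diverges) are detected exactly (a fitted linear score that perfectly
ranks the classes certifies separability) and refit with a small fixed
ridge (C = 100), flagged on the model object.

Evaluation: leave-one-out cross-validation (one held-out probability per
subject), ROC over the pooled probabilities with thresholds at each unique
probability, trapezoidal AUC, and the Youden-optimal cutoff (max TPR − FPR,
ties broken toward the larger threshold, i.e. higher specificity;
classification rule p ≥ cutoff). The identity AUC = U/(n₁n₂) against the
rank statistic of the probabilities is asserted cross-module on every
dataset tested. Small-sample LOOCV is pessimistic under the null (holding
out a subject shifts the training set away from its class), so
label-permuted AUC distributions centre below 0.5; tests assert the
absence of optimistic bias rather than an exact 0.5 centre.

## The packaged cohort and what it can and cannot reproduce

`data/table1.csv` is the 38-subject reference cohort (20 healthy, 10 mild,
8 severe) with per-subject SMM/DMS as published — rounded to two decimals,
checksum-guarded. On it, the pipeline reproduces the published AUC to
within rounding (0.844 vs 0.847) and the accuracy exactly (81.6%), and
both U tests are significant far below 5%.

The published *operating point* (cutoff 0.61, sensitivity 61.0%,
specificity 100.0%, confusion 11/7/0/20) is **not** recoverable from the
rounded table, and the package reports what it computes rather than the
printed values: one healthy subject whose rounded DMS (0.16) lies inside
the severe-patient range receives a held-out probability ≈ 0.99 under any
solver or scaling choice, so zero false positives would force sensitivity
to 4/18 and the Youden optimum instead lands at cutoff ≈ 0.31 with
confusion 16/2/5/15 (J = 0.64 vs 0.61 at the printed point). Exactly 11
patients — and only that one healthy subject — exceed probability 0.61, so
the printed numbers are consistent with the authors' unrounded per-subject
values, which are not published. The corresponding acceptance test is left
failing with the computed values rather than weakened.

## Synthetic data generator

`generate_subject` builds a fixed, exactly mirror-symmetric 98-landmark
template face (~220 px wide; every left landmark constructed as the exact
reflection of its right counterpart) and animates the mouth with a
raised-cosine neutral → smile → close envelope (1 s up / 1 s hold / 1 s
release inside a 5 s, 30 fps clip by default; corner excursion 18 px).
Palsy is modelled as, on the affected side: excursion scaled by
(1 − movement_asymmetry), onset lagged by 0.3 × asymmetry seconds
(weak *and* delayed movement), and a static droop of the outer-lip half,
tapered from the full `droop_offset` at the corner to zero at the lip
midline so the contour remains simple. Landmark-localization error is
i.i.d. Gaussian jitter (default SD 0.3 px) on every landmark and frame;
optional slow rigid head drift exercises the preprocessing. All randomness
derives from the seed.

`generate_cohort` draws healthy subjects with near-zero asymmetry/droop
(|N(0, 0.02)| and |N(0, 0.3) px| jitter) and palsy subjects from a severity
scalar s ~ U(0.4, 1) mapped to asymmetry 0.85 s and droop 9 s px plus the
same baseline jitter — so severity 0 is distributionally identical to
healthy. These mappings place synthetic severe subjects at SMM ≈ 0.81 and
DMS ≈ 0.26, inside the observed severe-patient ranges.

What the generator does *not* emulate: appearance-driven landmark failure
modes (correlated or expression-dependent localization error, which in real
data inflates healthy DMS to ~0.06), inner/outer lip interaction, 3-D pose
beyond slow drift, and between-subject facial geometry variation. Passing
synthetic tests therefore demonstrates correctness and sensitivity of the
*measurement pipeline*, not clinical performance on video.

## Problem sizes and tolerances in the test suite

Severity-recovery checks use a 5-level severity grid × 50 seeds of 5 s /
30 fps clips, and the end-to-end synthetic cohort uses 20 + 18 subjects —
the cohort geometry of the reference study. Exact-geometry assertions
(similarity invariance, symmetric-face limits) use 1e-9; grid-vs-oracle
agreement 0.01 at 400 columns; the type-I-error check uses a 99% binomial
band around 5% over 1000 null replicates.
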