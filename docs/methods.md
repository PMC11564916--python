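# Methods

`ddacc` compares three prostate radiotherapy strategies on a common footing by
deformable dose accumulation (DDA): the static reference plan (refPlan), a
simulated conventional image-guided workflow with daily translation-only couch
correction (conv-IGRT), and online-adaptive MR-guided radiotherapy with daily
re-planning (OA-MRgRT).  Because clinical image data for such a comparison are
not publicly available, the package ships a synthetic pelvis cohort generator
whose ground-truth deformations make every stage of the pipeline verifiable.

## Coordinate conventions

All volumes live on regular grids with physical spacing in mm, the world
position of the center of voxel (0,0,0) as origin, and an orthonormal
direction matrix (identity for all synthetic data).  Axes are +x right,
+y anterior, +z superior; dorsal is −y.  Displacement fields use the
pull-back convention throughout: a field `u` on grid G warps a volume `v`
into G's frame via `out(x) = v(x + u(x))`.  This convention means dose
mapping needs no field inversion: registering fraction k (moving) to
fraction 1 (fixed) directly yields the field that pulls fraction k's dose
into the accumulation frame.

## Synthetic cohort

**Anatomy.** Each patient is built from smooth parametric shapes with seeded
jitter: an ellipsoidal prostate (CTV, semi-axes ≈ 21×19×19 mm, ≈ 36 cm³)
with a thin urethra (radius 3 mm) along its axis; an ellipsoidal bladder
(≈ 130 cm³ at planning) whose base drapes over the prostate apex; and a
tubular rectum (radius ≈ 11 mm) whose anterior wall forms a 2.5–4.5 mm sheet
lining the dorsal prostate surface, as in real pelvic anatomy.  The PTV is
the CTV expanded by 5 mm, reduced linearly to 3 mm for dorsally directed
expansion.  A T2w-like image assigns organ intensity levels plus a seeded
intra-prostatic Gaussian-blob texture (a zonal-anatomy surrogate) so that
intensity-based registration is well conditioned along every axis.

**Analytic dose model.** Plans are analytic rather than optimizer-based: a
conformal plateau with a logistic penumbra of width `w` (default 2.5 mm)
whose 50 % level sits `b` mm (default 8) outside the PTV, a Gaussian
urethra-sparing dip (default 3.5 % of the plateau; urethral sparing is
protocol-dependent and can be disabled), and a slowly decaying low-dose
bath.  A tuner calibrates each plan to the planning objectives
(CTV D50 % ≥ 60 Gy, D98 % ≥ 57 Gy, OAR Dmax ≤ 61 Gy, rectum V56Gy < 13.5 %,
bladder V56Gy < 18 %): because the model is linear in the plateau, the
plateau that puts the hottest OAR voxel at 61 − 0.15 Gy is found in a single
division — the near-constraint operating point real optimized plans sit at —
and the edge offset / penumbra / dip are then adjusted iteratively until all
objectives hold.  V56 objectives are tuned against planning aims below the
limit (1 percentage point for the reference plan, 2 for daily re-plans — the
online equivalent of a robustness margin against what the course will
accumulate) and, for daily re-plans, as an absolute-volume cap derived from
the planning-time organ volume (the usual cc-style constraint), so that
daily distension cannot dilute the percentage.  Generation fails
loudly, naming the violated objective, if the budget is exhausted.

**Per-fraction variation.** Each fraction composes four component
deformations, every one a diffeomorphism, and composes their pull-back maps
(the composition of fold-free maps is fold-free; sums are not):

* a rigid prostate shift `t = drift·k + N(0, σ²)` per axis (default drift
  0.4 mm/fraction posterior, σ = 2 mm, clipped at 10 mm), carried by a
  kernel that is 1 over the swept CTV volume and decays over
  ~10 mm + |t|, so the CTV moves exactly rigidly;
* bladder filling as a radial scaling about the (anatomically tethered)
  bladder base, calibrated by two Newton steps so the warped volume hits a
  target drawn from the configured range (default 140–230 cm³);
* rectal filling as a radial scaling about the rectum axis (default
  30–70 cm³); and
* a filling-correlated anterior push of the rectum–prostate interface
  (≈ 1.5·(a−1)·r plus noise, clipped to [−2, 2.8] mm) — the component a
  translation-only correction cannot compensate, standing in for gas/stool
  displacing the anterior wall.

Organ terms are attenuated to zero at the CTV surface (prostate rigidity),
with lever-arm saturation keeping strain bounded.  Every composed field is
checked fold-free (min Jacobian determinant > 0.05) with a resample-and-retry
budget.  Fraction 1 carries no variation: the accumulation frame (fraction 1)
then coincides with the reference frame, and the stored reference→fraction
fields double as fraction-1→fraction-k ground truth after numerical
inversion (fixed-point iteration, sub-0.01 mm residual for these smooth
fields).  Magnitudes of the variation are generator configuration chosen at
clinically plausible scales; the defaults deliberately realize the regime in
which adaptive re-planning matters: near-constraint reference plans plus
systematic drift and filling-driven wall motion make the accumulated
conv-IGRT arm exceed the rectum V56 limit in some patients while daily
re-tuning keeps the adaptive arm compliant.

**Arms.** `dose_oa` re-runs the dose tuner on the fraction's own anatomy
(daily re-plan surrogate) scaled to one fraction; `dose_conv` translates the
reference dose by the shift the rigid registration finds between the
reference and daily images.  Adapt-to-position fractions are not modeled as
a separate mode — they are a rigid special case already covered by the conv
machinery.

## Registration

**Rigid (conv-IGRT surrogate).** Translation-only minimization of a
weighted mean-squared intensity difference inside the axis-aligned bounding
box of the CTV dilated by 8 mm: exhaustive coarse search (±12 mm, 3 mm
steps, ties resolved to the smallest shift) followed by per-axis
golden-section refinement to 0.05 mm.  The MSD weight is a smooth window
around the CTV evaluated in the moving frame ("soft-tissue match on the
target"): an unweighted box metric is demonstrably biased by the bright
bladder base, which deforms independently of the prostate.  Rotations are
excluded by contract.

**Deformable (DDA surrogate).** The clinical workflow uses a proprietary
hybrid intensity/structure algorithm; `ddacc` substitutes an open
multi-channel demons scheme with the same contract.  Channels are the
normalized intensity image plus signed-distance transforms (clipped at
±10 mm, weight 4 each) of the CTV, bladder and rectum contours; symmetric
demons forces are fluid-smoothed (σ = 1.5 mm) per iteration and the
accumulated field diffusion-smoothed (σ = 1 mm) over a 3-level pyramid
(≤ 200 iterations per level).  The acceptance surface is recovery on the
phantom's ground truth: warped-contour Dice ≥ 0.95 for CTV, bladder and
rectum, and mean displacement error inside the CTV at or below the 2 mm
voxel size.  Defaults were chosen to meet that contract with margin; they
are configuration, not physics.

## Dose mapping and accumulation

Fraction doses are mapped by direct dose mapping (DDM): trilinear sampling
of the dose at the displaced voxel positions, values clamped at 0,
out-of-field contributions 0, no energy rescaling.  DDM preserves pointwise
dose values and is linear; it does not conserve integral dose under
deformation — a property of the method, not a defect.  Accumulated arms are
voxelwise sums in the fraction-1 frame, evaluated on the fraction-1
structures; the refPlan is evaluated in the reference frame without mapping.

## DVH, objectives and radiobiology

Cumulative DVHs use 0.01 Gy bins; Dq% interpolates linearly between bins
and the boundary is inclusive (D98 % = 57.00 Gy passes); Dmax is the single
hottest voxel, computed voxelwise.  NTCP follows the standard
Lyman-Kutcher-Burman chain: voxelwise EQD2 under the linear-quadratic model
with uniform fractionation (EQD2 = D·(d + α/β)/(2 + α/β), d = D/n), gEUD as
the power mean with volume parameter n (computed with the maximum factored
out for stability at small n), then the logistic
NTCP = 1/(1 + exp(−(gEUD − TD50)/(m·TD50))).  Endpoints: bladder
incontinence G2+ (α/β = 1.5 Gy, TD50 = 108.9 Gy, m = 0.24, n = 0.02) and
rectum late toxicity G2+ (α/β = 3.0 Gy, TD50 = 80.8 Gy, m = 0.15, n = 0.12).
Applying EQD2 voxelwise before the gEUD reduction is the standard ordering;
the scalar-EQD2 notation some sources use is recovered for uniform doses.

## Statistics

Arms are compared pairwise per DVP with the two-sided Wilcoxon signed-rank
test: zero differences dropped, ties midranked, exact null by enumeration of
all 2ⁿ sign assignments for n ≤ 15 (the cohort size of 10 uses the exact
null), tie-corrected normal approximation with continuity correction
otherwise.  Bonferroni correction uses k = 3 (the three arm pairs).  The
effect size is the paired Cohen's d_z = mean(diff)/SD(diff, n−1); the pooled
variant differs and is deliberately not used.  Population DVH summaries are
pointwise means and SDs of the cumulative curves on the union dose range.

## Problem sizes and numerical choices

All synthetic volumes use a single isotropic 2 mm grid (55×59×71 voxels)
— a compromise between clinical image (≈ 1 mm) and dose-grid (3 mm)
resolutions that keeps every oracle computable in closed form — and
heterogeneous-grid inputs are handled by trilinear/nearest resampling.  The
full study conditions (10 patients × 20 fractions) are exercised by the
acceptance suite; examples use reduced courses with the same physics.
Interpolation is trilinear for images and doses, nearest for masks (outputs
strictly binary); dose fills with 0 Gy out of field.  Tie-breaks in the
rigid search are deterministic (smallest-magnitude shift).  Organ-volume
targets are drawn from a 4 % inset of the configured range so the two-step
volume calibration cannot overshoot the interval.  All randomness derives
from one master seed via per-patient/per-fraction seed sequences; cohorts
are bit-reproducible.

## What the phantom does and does not show

Passing tests demonstrate the pipeline's internal correctness (mapping,
accumulation, DVH/NTCP arithmetic, statistics) and its qualitative behaviour
under controlled anatomy: with near-constraint plans and realistic
interfraction motion, translation-only correction accumulates OAR overdose
that daily re-planning avoids, while target coverage is maintained by both.
The phantom does not emulate realistic MRI contrast or noise, intra-fraction
motion, rotations or seminal-vesicle targets, optimizer-specific dose
features (hot spots, beam arrangements), or contouring uncertainty; absolute
clinical DVP values from patient cohorts are outside what synthetic data can
reproduce.  Registration accuracy on phantom images is an upper bound on
real-image performance.

## Known limitations

* The demons surrogate is not the clinical algorithm; only its recovery
  contract is asserted.
* Accumulation carries no uncertainty model; confidence intervals on
  accumulated dose are out of scope.
* Energy/mass-transfer dose mapping is deliberately not implemented (direct
  dose mapping only).
* The urethra-sparing dip makes accumulated CTV D98 insensitive to small
  misalignments (the dip dominates the cold tail); coverage-direction
  comparisons between arms are clearest with sparing disabled.
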