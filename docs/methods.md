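# Methods

## The three angles

All measurements operate on a triangulated femoral surface in millimetres
with a small set of named landmarks (lateral ridge of the greater
trochanter, a shaft station for the base of the lesser trochanter, the
posterior points of the medial and lateral condyles, the epicondyle
midpoint, and an approximate hip-centre hint).

* **Femoral anteversion (FA)** — signed angle between the femoral neck
  axis and the posterior condylar line, projected on the axial view.
  Anteversion is positive, retroversion negative.
* **Neck-shaft angle (NSA)** — angle between the neck axis and the shaft
  axis on the anteroposterior (tabletop) view, in (90°, 180°).
* **Anterior-wall angle (AW)** — signed angle between the shaft axis and
  the line tangential to the anterior wall of a simulated
  greater-trochanter (GT) osteotomy cut, on the sagittal view of an
  ISB-style femoral frame. Positive when the wall leans anteriorly going
  proximally.

## Measurement pipeline

1. **Head centre.** Vertices near the hip-centre hint are reduced to the
   head surface by iterating an algebraic sphere fit with a shrinking
   inlier band (3 → 0.5 mm); the final fit refines the algebraic solution
   with geometric (orthogonal-distance) Levenberg–Marquardt. The hint must
   be within a few mm of the true centre; the fit residual is reported.
2. **Neck axis.** Cutting planes perpendicular to the current axis
   estimate are scanned in 0.5 mm steps over a 20 mm window starting just
   outside the fitted head radius; the minimal-area closed contour
   (selected, among the contours a plane produces, as the one enclosing
   the axis with the nearest centroid) defines the narrowest neck
   section. The axis is re-estimated head-centre → section-centroid until
   the centroid moves < 0.1 mm (≤ 10 iterations), with parabolic
   refinement of the minimal station. A near-constant area profile
   (cylindrical neck) is flagged and resolved to the mid-station. The
   neck axis joins the head centre and the final centroid.
3. **Shaft axis.** The longitudinal direction is the principal axis of
   the vertex cloud, oriented proximally using the epicondyle midpoint.
   Stations are signed distances along it from the centre of mass. The
   axis joins the cross-section centroids at the lesser-trochanter-base
   station and 50 mm further distal. On surface models the canal centre
   is represented by the section centroid, which coincides with the true
   axis for (near-)cylindrical shafts under oblique sectioning.
4. **GT cut.** The cut plane passes through the point 5 mm distal (along
   the shaft axis) to the lateral ridge of the GT and is tilted about the
   anteroposterior axis — dipping medially — until the maximum thickness
   of the resected cap, measured perpendicular to the plane, equals
   10 mm (binary search, 0.1 mm tolerance, tilt limited to 60°). The cap
   is identified as the face-connected component of the sliced surface
   nearest the ridge.
5. **Anterior wall line.** The cut contour is resampled at 0.5 mm;
   boundary samples whose outward normal lies within 60° of the in-plane
   anterior direction form the anterior-wall arc (≥ 5 mm required). A
   weighted total-least-squares line is fitted and translated anteriorly
   to be tangent at the most anterior sample. The RMS deviation from the
   line is reported and a non-flat wall (RMS > 0.2 mm) is flagged, with
   the apex tangent still returned.
6. **Frames and projections.** The tabletop frame uses the scanner axes
   when they are known (supine, symmetric positioning); otherwise it is
   rebuilt from anatomy (proximal = shaft axis, lateral = condylar
   direction orthogonalised, anterior completing the triad via the
   epicondyle-vs-condyle cue, which also determines the side). This keeps
   every measurement invariant under rigid motion of the input. The ISB
   frame takes its proximal axis from the epicondyle midpoint to the head
   centre. FA is projected along the shaft axis by default; whether the
   axial view should instead be the scanner transverse plane is not
   settled, so the alternative projection and the difference are reported
   as diagnostics (`fa_table_view_deg`, `fa_axial_vs_table_deg`).

### Numerical and degenerate-case choices

* The 60° anterior-wall selection cone accommodates walls tilted up to
  ±45° from the shaft axis (a 30° cone would reject any wall beyond 30°
  of tilt, inside the range the measurement must cover); it still
  excludes lateral and posterior contour edges.
* The wall line of a nearly transverse cut runs mediolaterally and can
  lie within a fraction of a degree of the sagittal view normal. Its
  projection remains well conditioned for a flat wall — the line then
  lies in the wall plane, which contains the view axis, so the projected
  direction is independent of the cut obliquity — and the inclination
  guard for this one projection is therefore 0.02° instead of the 1°
  used elsewhere. The inclination is reported per femur
  (`wall_line_inclination_deg`); on noisy surfaces a small inclination
  amplifies wall-fit noise, which is why the wall-flatness RMS is
  surfaced alongside.
* Whether the AW angle is constant along the GT wall is an open
  anatomical question; `MeasureConfig.aw_sweep_offsets_mm` re-runs the
  cut at additional entry offsets and reports the per-level AW angles
  without asserting an answer.
* Angles are reported in degrees (display at 0.1°), lengths in mm.

## Phantoms

Phantoms are unions of analytic primitives so that ground truth is
closed-form: an icosphere head (r = 24 mm); a surface-of-revolution neck
whose radius tapers 16 → 14 → 16 mm with the narrowest circle 30 mm from
the head centre (waist diameter 28 mm); a vertical shaft cylinder
(r = 14 mm); a GT block whose anterior face is an exact plane; and two
condylar bosses whose most-posterior points define the condylar line.
The neck direction is built so the axial projection makes exactly the FA
dial with the condylar line and the AP projection makes exactly the NSA
dial with the shaft axis; the GT anterior face is built against the
closed-form ISB frame so the sagittal-view wall angle equals the AW dial
regardless of the cut obliquity (any line in a plane containing the view
axis projects onto the same image line). Canonical pose: +x anterior,
+y proximal, +z lateral for a right femur; left femora are mirrored with
anatomical landmark labels following the side, making all three angles
side-invariant.

The primitives are concatenated as closed, overlapping solids rather than
boolean-unioned; the surface is edge-manifold watertight and every
cross-section of a primitive is a closed contour. The contour/cap
selection rules above (centroid proximity, face connectivity) are what
make measurement on such multi-component surfaces equivalent to
measurement on a fused surface. The lateral ridge is placed at the
midpoint of the superolateral edge of the GT block top — the literature
gives no quantitative definition of the ridge, so it is a constructed
landmark here. The random seed drives only nuisance features (optional
surface jitter, the ±1 mm hip-hint offset), never the analytic geometry.

What the phantoms do *not* emulate: cortical/trabecular structure, a
hollow medullary canal (the shaft axis is tested via the outer cylinder,
whose centroid locus coincides with the canal axis by construction),
segmentation noise, osteophytes or head collapse, open growth plates, and
anatomical variation beyond the dialled angles. Passing the recovery grid
therefore demonstrates the correctness of the geometry pipeline, not its
robustness to real CT segmentation artefacts.

## Cohort simulation and statistics

The generative model is `FA = 4.330 + 0.744·AW − 4.998·male + ε` with AW
normal within sex (male 14.6 ± 6.6°, 47 % female 20.8 ± 8.2°, 53 % male)
and NSA ~ N(127.3°, 5.4°) independent of FA (the published correlation is
null). Group labels (osteonecrosis vs normal) are assigned independently
of the angles, mirroring the null group differences; retroversion arises
naturally from the normal tails.

Two residual-SD calibrations are provided. The default derives it from
the published pooled FA SD and fit, `10.8·√(1 − 0.507) = 7.58°`. The
closed-form population R² of the generative model under that default is
0.481, because the printed marginals and coefficients imply a total FA SD
of 10.52° rather than 10.8°; `CohortParams.calibrated_to_r_squared(0.507)`
instead solves the residual SD (7.20°) from the systematic-variance
closed form so the population R² matches the published value. The
acceptance script uses the calibrated form; within-sex residual SDs are
not published, so a shared residual SD is an acknowledged approximation.

`simulate_observers` decomposes measurement variance into subject,
observer-bias and session-noise components. Session noise follows from
the intra-observer ICC target (`σ²ₑ = σ²_T(1−ρ)/ρ`); observer biases are
placed deterministically (symmetric ±δ with exact sample variance) so the
large-n ICC(2,1) of session-averaged scores equals the inter-observer
target — with only two observers, randomly drawn biases would make the
target unrecoverable to ±0.01 (single-degree-of-freedom χ² noise), which
would defeat the generator's purpose as a reliability test bed.

The ICC defaults to two-way random effects, absolute agreement, single
measures (the standard model for a two-rater reliability study; one-way
and consistency flavors are available and the ANOVA mean squares are
exposed). Group comparisons default to Welch's t (Student available); the
comparison test behind the published tables is unnamed, so robustness won
the default. Display equations round half-up at one decimal. "More than
10°" prediction error is a strict inequality; under the default
calibration the population fraction is `2(1 − Φ(10/7.58)) ≈ 0.19`, a
closed-form analogue of — not a reproduction of — the 17 % observed in
the original cohort. The rounded display equations deviate from the
full-precision model by up to `0.044·|AW| + 0.03 ≈ 2.0°` over the
measured AW range; predictions use full precision unless rounding is
requested.

Problem sizes used by the checks: marginal calibrations at n = 10⁵;
regression recovery and CI coverage over 500 cohorts of n = 100; ICC
recovery at n = 2000; geometry recovery over a 90-phantom grid
(FA ∈ {−10…38}, AW ∈ {0…42.5}, NSA ∈ {116.6, 127.3, 143.2}) at the
default mesh resolution, with rigid-motion invariance spot-checked on
randomly transformed phantoms.

## Known limitations

* Landmarks are inputs, not detected; the hip-centre hint must be within
  a few mm.
* The "base of the lesser trochanter" is not operationally defined in the
  literature; phantoms emit it as a constructed station and real use
  requires choosing it consistently.
* Per-patient values from any real CT cohort are not reproducible here;
  cohort-level quantities are reproduced through the generative model
  only, and empirical figures tied to the original sample (observed
  large-error count, observed correlations, group p-values) have
  closed-form analogues at best.
* The regression is descriptive: no variable selection, no nonlinear
  terms, and the prediction equations are not meant for retroverted hips.
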