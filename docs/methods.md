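# Methods

## The measurement model

`craniometrics` implements a landmark-anchored craniometric system for
following patients with craniosynostosis (scaphocephaly, trigonocephaly,
anterior plagiocephaly) across surgery: every index is defined relative to
an anatomical coordinate frame so that values from different visits and
scanners are directly comparable.

### Anatomical reference frame

The frame is built from five soft-tissue landmarks:

* **origin** — midpoint of the right and left tragus;
* **Y (anterior)** — unit vector from the tragus midpoint toward the
  midpoint of the right and left lateral canthus;
* **X (lateral)** — unit normal of the midsagittal plane spanned by the
  tragus midpoint, the canthus midpoint and the subnasale, signed so the
  right tragus has positive x;
* **Z (superior)** — `X × Y`.

X is orthogonal to Y by construction (Y lies in the plane X is normal to),
so the triad is exactly orthonormal and right-handed. Construction fails
loudly when a required landmark is missing, when required points coincide
(tolerance 1e-6 cm), or when the three frame-defining points are collinear
(no midsagittal plane). A clinical description of this kind of frame can be
worded several not-quite-consistent ways; the reading used here — the
mid-landmark plane as the midsagittal plane and X as its normal — is the
only one that yields three orthogonal, anatomically sensible axes, and it
is stated prominently because it is a design choice, not a theorem.

### Layered slicing

The supra-basal head — the part of the mesh above the horizontal plane
through the origin (the tragus level; the face/base band below the first
boundary belongs to layer 0) — is divided into **12 equal-thickness
layers** along Z, from the base plane to the topmost vertex. Equal division
is a design choice: the slicing rule is not anatomically canonical, and
equal slices are what makes "averaged over all slices" indices
well-defined. Layer 0 is kept in the stack but flagged excluded; layers
1–11 are analysed. Each layer stores the single closed mesh cross-section
polygon at its mid-height, in frame coordinates. Multiple disjoint contours
in an analysed layer are an error (a head is simply connected there);
negligible satellite loops (< 1e-6 of the main area) are dropped as
numerical debris.

A conservation check accompanies slicing: the midpoint-rule volume
(contour area × thickness summed over all 12 layers) is compared with the
exact enclosed volume above the base plane, computed by the divergence
theorem with the field (0, 0, z) — the base-plane cap then contributes
nothing, so no cap triangulation is needed. Disagreement beyond 5% raises
a warning; on the synthetic fixtures the two agree to ~0.2%.

### Index catalogue

Per analysed slice: length = anteroposterior extent, width = mediolateral
extent, CI_k = 100·width_k/length_k. Reported scalars: cranial length and
width are the maxima over layers 1–11; the cranial index is the
*arithmetic mean* of CI_k, which deliberately differs from
100·max-width/max-length whenever the slice aspect ratio varies with
height (it does in scaphocephaly).

Diagonals A/B are chords through the contour centroid of the
largest-area analysed slice, at ±30° (configurable) from the
anteroposterior axis; A tilts toward the right. The *absolute difference*
|A − B| is the asymmetry quantity reported alongside the raw chords: the
clinically tabulated "diagonal" values (≤ 3.5 cm, 6 cm) are an order of
magnitude below plausible chord lengths, so they can only be the
difference, following the cranial-vault-asymmetry convention. The chord
reference point (area centroid) is a design choice; for non-star-shaped
contours the total intersection length is used and a warning emitted.

Quadrant volumes Q1–Q4 split each analysed contour by the midsagittal
(x = 0) and coronal (y = 0) frame planes: Q1/Q2 anterior right/left, Q3/Q4
posterior right/left; piece area × thickness, summed over layers 1–11, in
ml. The four quadrants partition the analysed volume exactly (up to float
round-off). ASR and PSR are the paired anterior / posterior quadrant
ratios. The default convention is **lower over higher** — a perfect head
scores 1 and asymmetry scores below 1, matching how the values are usually
tabulated — with the reciprocal (higher over lower, ≥ 1, as the ratio is
sometimes described in prose) selectable; the two are exact reciprocals.

Angles are evaluated in the axial (x–y) projection, because they are
defined on an axial view and projection makes them consistent with the
slice geometry. The frontal angle sits at the nasion (glabella selectable)
between the rays to the right and left lateral-orbit landmarks
(exocanthion by default, frontotemporal selectable). The frontoparietal
angles sit at the nasion between the same-side lateral-orbit and parietal
rays, per side; comparisons use the side average, since tabulated values
give a single "right and left" number.

`measure_all` runs the whole chain and returns a record with ~16 scalar
indices plus an 11-row per-slice table (length, width, CI, quadrant
areas) — over 90 named values per subject.

## 2D cephalometrics

Radiograph measures operate on manually placed pixel landmarks plus an
individual scale calibration (two pixel points of known physical
separation). Distances are reported in cm, ratios are calibration-
invariant, angles in degrees. The catalogue is a JSON definition table;
the shipped default carries the eight measures of the emulated radiograph
block. The landmark abbreviations (MO, EU, ECA, ECP, ECS, BA, Tub, Nas)
are bound only by the definition file — their precise anatomical meaning
is not fixed here, and the `Inter-MO`/`Inter-EU` rows default to
angle-kind (their tabulated magnitudes of 120–170 exceed any plausible cm
distance) while `ECA-ECP` stays distance-kind; all kinds are provisional
and overridable.

## Synthetic heads

The generator lofts superellipse cross-sections (exponent 2 = ellipse by
default) with anteroposterior semi-axis `a(z)` and mediolateral semi-axis
`b(z)` over a height `H` (12 layers of thickness `H/12`):

* `a(z) = a_max · (1 − v²)^(γ/2)`, `b(z) = b_max · (1 − v²)^(δ/2)`, where
  `v` rises linearly from 0 at the mid-height of layer 1 to 1 at the apex.
  Independent tapers γ, δ let the mean slice aspect ratio (CI 70) differ
  from the max-extent ratio (12/20 → 60).
* The anterior half of every section is scaled in y by per-side factors
  `s_r`, `s_l`. Each anterior quadrant area is then *exactly* the quarter
  superellipse area times its side factor, so ASR = min(s)/max(s) exactly
  and quadrant volumes are linear in the side scales. When the sides
  differ the contour carries a small vertical step on the midsagittal
  line — the price of exact closed-form quadrants; a smooth blend would
  make the quadrant areas transcendental in the scales.
* Rings are placed at several heights per layer (odd counts, so no ring
  coincides with a layer mid-height and plane–vertex-degenerate sections
  never arise), denser near the apex; caps close the mesh watertight.
* Landmarks are placed by rule so that the landmark-derived frame is the
  generator's own frame, and the angle landmarks sit on rays from the
  nasion at the preset's frontal/frontoparietal angle parameters — the
  pipeline recovers the preset angles exactly. Note that an obtuse
  (~130–140°) angle at the nasion geometrically forces the "parietal" ray
  across the midline; the parietal placements are parametric abstractions
  that realise the angle targets, not measured anatomy.

`analytic_measures` is the closed-form oracle (superellipse quarter-area
via the Gamma-function formula; angles by the vector formula from the
parametric landmark coordinates; only the diagonals use a dense 4096-point
sampling of the exact 2D section — still mesh-free). At the default
resolution (128 contour points) the lofted pipeline agrees with the oracle
to ~0.1% on volumes and exactly on extents and angles; the residual is the
inscribed-polygon area deficit, O(1/n²), which the convergence tests
verify directly.

### Calibration and the frozen exemplars

`calibrate_preset` maps each target index to one preset knob (width → ML
semi-axis; length → AP semi-axis; CI → AP taper, by bracketed
root-finding; Q1/Q2 → side scales; ASR → side-scale ratio; angles → angle
parameters) and sweeps exact or `brentq` one-dimensional updates until all
relative residuals fall below 0.2% (the shipped exemplars are required to
sit within 0.5%). Conflicting targets that share a knob (ASR with Q2 or
diagonal difference) are rejected as infeasible.

The four shipped presets encode the emulated group-mean conditions:

| preset | calibrated to |
|---|---|
| control | symmetric base (17 × 15 cm, CI 88, all ratios 1) |
| scaphocephaly | length 20, width 12, CI 70, frontal 153°, FP 138° |
| trigonocephaly | length 17, width 15, Q1 = Q2 = 400 ml, frontal 130°, FP 130° |
| anterior plagiocephaly | length 17, width 15, Q1 500 ml, ASR 0.8, frontal 140°, FP 134° |

Two tabulated phenotype values are deliberately *not* calibrated. A
scaphocephalic anterior quadrant of 590 ml is jointly infeasible with
20 × 12 cm extents and CI 70 at a plausible vault height (it would need a
≥ 16 cm, nearly untapered vault); the frozen exemplar reports ≈ 338 ml.
The plagiocephalic diagonal difference of 6 cm shares its only knob with
ASR 0.8, which takes precedence; the exemplar's diagonal difference comes
out ≈ 1.3 cm. Heights default to 11 cm (scaphocephaly) and 13.2 cm
(others), chosen once as realistic tragus-to-vertex spans that keep the
calibrated quadrant volumes reachable.

### What the generator does and does not emulate

It reproduces the deterministic geometry of the phenotypes — global
proportions, anterior volume deficit/asymmetry, angle configurations —
with optional smooth seeded surface noise (default off, so the
ground-truth tests are exact). It does **not** model scan noise
statistics, ears/nose/face detail, population shape variation, or infant
growth; passing tests therefore demonstrate correctness of the
measurement machinery on known geometry, not clinical accuracy on real
scans.

## Statistics and quality-of-life scoring

The age-adjusted comparison fits `value = b0 + b1·group + b2·age` by
ordinary least squares through the normal equations, reporting `b1` with
its two-sided p value from the t distribution on n − 3 degrees of freedom
(classical ANCOVA with a single covariate and no interaction — none is
specified for this design). Near-singular designs (condition number
> 1e12, e.g. age constant) raise a collinear-design error. The unadjusted
alternative is a two-tailed two-sample t test, pooled variance by default
with Welch selectable — which variant the emulated analysis used is not
documented, so both are exposed.

Significance tiers use half-open intervals with the boundary falling to
the weaker tier: p < 0.01 highly significant, 0.01 ≤ p < 0.05 significant,
0.05 ≤ p < 0.1 mildly significant, p ≥ 0.1 not significant. The source
wording leaves the boundaries and the 0.05–0.1 band ambiguous; this
resolution is total and monotone, which the property tests assert.

KIDSCREEN-52 category scores are linear sum-score rescalings,
`100·(sum − n)/(4n)` for an n-item category: all-1 → 0, all-5 → 100,
higher = better HRQOL. The instrument is sometimes described as "1–100";
a one-based variant (`1 + 99·(sum − n)/(4n)`) is selectable. Missing
items beyond the completeness threshold (default: all items required)
yield NaN, never imputation. Percentile bands place a score among
user-supplied P10/P25/P50/P75/P90 cuts with lower-edge inclusion. The
shipped `synthetic_norms.csv` is an invented, clearly-labelled
illustration — official norm values are not reproduced here — and the
official Rasch/T-score machinery is out of scope.

## Numerical choices

* Units: cm internally everywhere (1 cm³ = 1 ml); mm input only by
  explicit flag, never auto-detected.
* Tolerances: 1e-9 orthonormality, 1e-6 cm point coincidence, 5% slicing
  volume-conservation warning, 0.2% calibration residual.
* Determinism: identical inputs give bitwise-identical slices and
  measurements; generator randomness (noise only) is fully seeded.
* Test problem sizes: 128-point contours (~5 700 vertices per head),
  0.2 cm voxel oracle, 100-replicate simulation for the covariate-recovery
  check — sizes at which the discretisation error is at least an order of
  magnitude below every asserted tolerance.

## Known limitations

* Landmark placement on real scans is manual and its inter-rater error is
  outside the package's scope; garbage landmarks give garbage frames
  (though degenerate ones are caught).
* The 12-layer equal-thickness rule and the base plane at tragus level are
  conventions; absolute index values are only comparable between datasets
  measured under the same convention.
* The 2D catalogue's landmark semantics are configuration, not anatomy;
  shipped defaults are provisional.
* Only plain sum-score KIDSCREEN scoring is provided.
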