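# Methods

This note records the modelling choices, parameter defaults and known
limitations of the `archform` pipeline, in the spirit of a model-description
appendix.

## Geometric model

**Occlusal frame.** The occlusal plane is the total-least-squares plane
(orthogonal residuals, computed by SVD) through the posterior cusp
landmarks — the three most distal landmarks on each side of the arch.  The
frame's y-axis is the in-plane direction from the midpoint of the two
distal landmarks to the interproximal contact point of the central
incisors; x completes a right-handed frame; the origin is the contact
point's projection onto the plane.  When no contact point is supplied, the
midpoint of the two most anterior landmarks stands in; this shifts the
origin along y only, which width normalization cancels exactly.

**Measurements.** The distal-transverse line is the line parallel to x
through the most distal (minimum-y) point of the measured curve.  When the
two distal ends stop at different y (asymmetric arch), the more distal end
defines the line and the other arm contributes its distal endpoint.  Arch
width is the x-distance between the curve's two meetings with that line;
arch depth is the y-distance from the curve's mid-sagittal (x = 0)
intersection down to it.  Both are computed on a dense sample of the
fitted polynomial, not on raw landmarks, so sampling artifacts do not move
the extrema.

**Tooth segmentation.** The cast is partitioned by concave contour lines:
an interior edge is a barrier when its dihedral angle bends toward the
outward normals by more than 40° (a crease/groove line); vertices with
discrete umbrella concavity above 0.8 mm⁻¹ are barriers too.  Connected
components of the remaining vertex graph are candidate regions; a
component is a crown when it has ≥ 20 vertices, is compact (max distance
from its centroid ≤ 18 mm — crowns are local bumps, tissue patches span
the arch) and has out-of-plane spread > 0.1 mm (flat tissue shelves are
planar).  Edge dihedral angles were chosen over vertex curvature for the
barriers because vertex normals degenerate in narrow grooves; angles are
also invariant to rigid motion and mesh scale.  No height axis enters the
rule, so segmentation commutes with rigid motion.

**Landmarks.** Heights are measured along a cast-intrinsic axis — the
normal of the TLS plane through the crown-component centroids, oriented
away from the soft tissue — so landmark extraction is also rigid-motion
invariant.  Per crown the locally height-maximal vertex is taken (the
buccal-most candidate when several tie within 0.3 mm, measured from the
axis through the centroid of all crown centroids).  Landmarks are ordered
along the arch by angle about their centroid in the plane perpendicular to
the intrinsic axis, cutting the circular sequence at the largest angular
gap (the open lingual side); the walk direction is normalized after
framing by sorting on frame x.

**Soft-tissue layers and LiLo.** The gingival-margin height is the most
apical z of the tooth/tissue boundary contour; the mucosal base is the
lowest soft-tissue z.  Layer heights are evenly spaced strictly between
them: z_i = top − i·(top − bottom)/(n+1), i = 1…n (default n = 10,
configurable), ordered margin-down.  Cross-sections are computed by an
in-package plane/triangle intersector that nudges the plane by 10⁻⁹ mm
when it would pass through vertices and chains crossing segments
deterministically; the longest chain (the buccal arc) is kept.  Smoothness
is the standard deviation of the magnitudes of the first differences of
the contour after uniform arc-length resampling to 200 points, making the
score independent of the original parameterization; ties in the LiLo
selection break toward the more apical layer.

**Polynomial fit.** Degree-6 least squares of y on x with internal
centering/scaling of x for conditioning; coefficients are reported in
frame coordinates and an explicit condition-number guard rejects
near-singular designs.  At least 7 distinct x values are required.

## Normalization and shape vectors

Width normalization maps x to [0, 1] by max–min scaling and divides
y − min y by the same width, preserving the depth/width aspect ratio
exactly.  Min/max are taken over a dense (500-point) sample of the fitted
curve.  A normalized form is summarized by y′ at m = 50 evenly spaced x′
values; Euclidean distance between these vectors is the shape distance
used everywhere downstream.  The feature representation (sampled curves
rather than coefficients or landmarks) is an interpretation choice: it is
the minimal representation that is linear in the curve and independent of
the fitting basis.

## Statistics

**Difference experiment.** Subjects are split 50/50 (floor/ceil when odd)
into S1/S2; the control datasets give both subsets the same data type, the
experimental dataset gives S1 the dental and S2 the dentoalveolar shapes,
labels 0/1 (the positive class is S2's type — the source prints
sensitivities without fixing a polarity, so this is documented here).
Rows are shuffled; the first 80% train, the last 20% test; KNN (k = 5,
Euclidean), Gaussian NB and RBF-SVM (library defaults) are the three
classifiers; 100 repeats.  The 95% CI of accuracy over repeats is the
normal approximation mean ± 1.96·sd/√repeats (a percentile CI is available
via config); whether the original intervals are over repeats or
within-test-set binomial is not stated, and over-repeats matches their
reported tightness.

**Elbow + CuSum.** WSS(k) comes from best-of-10 k-means++ runs for
k = 1…10.  The relative drop d_k = (WSS(k−1) − WSS(k))/WSS(k−1) collapses
by an order of magnitude beyond the true cluster count, so the change
detector works on log d_k: the cumulative sum of mean-adjusted log-drops
peaks at the last k of the high-drop regime, which is returned.  The log
scale matters: with six well-separated clusters the raw drops decline
gradually (0.6 → 0.2) before collapsing (→ 0.01), and a cusum on raw drops
can peak one or two steps early, while the collapse is unambiguous in log
scale.  A flat curve returns k = 1; non-monotone segments are tolerated.

**Anomalies.** AD/AA use the two-sided rule exactly as stated — a distance
outside μ ± 1.96σ of the assigned cluster's member-distance distribution —
including the unusual lower branch: a form closer to a center than any
member is "too typical" and flagged.  For 50-dimensional shape vectors
member distances concentrate at μ ≈ 10σ, so a form exactly at a center is
always flagged by the two-sided rule; a one-sided upper-tail option
(`two_sided=False`) is provided for that reason.  The mismatch threshold
ε defaults to half a subject's worth of association mass (0.5/n_reference).
Multi-round screening refits both cluster models and the association
matrix on the normal-occlusion reference per round (never on the screened
subjects) with fresh seeded initializations; the default is 100 rounds
with threshold rounds/2.  Refit-per-round includes the association matrix,
consistent with the instability rationale for repeating detection at all.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes:

* **Templates.** Arch-shape families are even degree-6 profiles
  y = depth·(1 − a t² − b t⁴ − c t⁶), a + b + c = 1, covering parabolic,
  ovoid, tapered, square and narrow/wide variants.  The default 6 dental
  templates (width 34 mm, aspects 0.64–0.97) and 6 alveolar templates
  (width 42 mm, aspects 0.70–1.04, rounder families — bone contours are
  smoother than cusp lines) are ordered by aspect so that every template
  pair with nonzero association probability keeps the alveolar contour
  buccal of the crown apices; their pairwise normalized-shape distances
  are ≥ 0.27, i.e. ≥ 13× the default per-coordinate noise.
* **Casts.** A cast is a structured parametric surface: a buccal
  soft-tissue skirt (z ∈ [0, 6] mm), a free gingival rim and sulcus groove
  at the margin, and 12 crown bumps (mixed dentition: 2 incisors, canine,
  2 primary molars, 1 first permanent molar per side, ≈ 20k vertices by
  default) ending at the buccal cusp/edge line — lingual anatomy is out of
  scope.  Crown apices sit exactly on the dental template (perturbed per
  tooth by the shape noise, in y); the skirt's horizontal contour at the
  planted LiLo height is exactly the alveolar polynomial plus a constant
  offset (which normalization cancels), while other layers carry seeded
  two-tone sinusoidal corrugation (amplitude ≈ 0.25 mm) on
  constant-corrugation bands around each slicing height, so the planted
  layer is strictly smoothest and the zero-noise round trip is exact to
  machine precision.  Interproximal notches, an embrasure floor (touching
  crowns) and the sulcus groove keep the separating contour concave along
  its whole length — these exist so the cast satisfies the segmentation
  model's assumption that crowns are delimited by concave contour lines,
  as real casts are.
* **Cohorts.** Template pairs are drawn from a 6×6 association table
  (default: mass on |i−j| ≤ 2, exact zeros elsewhere); subject shape
  vectors are template vectors plus i.i.d. Gaussian noise (sd 0.02
  normalized units — the within-cluster variation is *assumed* Gaussian;
  the source gives no distributional description).  Exactly
  round(outlier_rate·n) subjects get a radial shape displacement of
  outlier_magnitude·sd; round(mismatch_rate·n) subjects are redrawn from a
  zero-probability pair.  Cohorts are bit-reproducible per seed.
  `generate_cohort` builds shape-level cohorts by default and full meshes
  on request (`meshes=True`); statistical analyses need only the vectors,
  and convergence checks at n = 10⁴ would gain nothing from 10⁴ meshes.

**What passing synthetic tests does and does not show.** The generator
reproduces the *assumptions* of the method: crowns bounded by concave
contours, a smoothest soft-tissue layer that is a polynomial arch,
Gaussian within-cluster shape variation, and cluster-structured cohorts.
Real casts violate all of these to some degree (scan noise, partially
erupted teeth, non-polynomial arches, unlabelled cluster structure), so
green tests certify the implementation and its calibration, not clinical
performance.  The cohort-scale results on real data (specific accuracies,
cluster shapes, anomaly proportions) depend on the private casts and are
not reproduced here.

## Problem sizes and determinism

Calibration runs use n = 200 subjects × 100 repeats for the classifier
experiments, 20 seeded replicates of 209-subject cohorts for cluster
recovery, n = 2000 draws for the outlier-rule check, and ~10 full meshes
(≈ 20k vertices each) for the geometric end-to-end checks — sizes chosen
to match the study's cohort scale while keeping a full run in minutes on
one CPU.  Every stochastic component takes an explicit seed
(`numpy.random.default_rng`; k-means seeds are derived via
`SeedSequence`), and repeated runs with one seed are bit-identical.

## Known limitations

* Maxillary casts reuse the same frame construction as mandibular ones
  (the source defines the occlusal plane on mandibular teeth only); a
  paired-cast frame can be supplied externally.
* The buccal-only LiLo arc is an interpretation — whether the original
  projection used open or closed contours is unstated.
* Landmark roles (buccal cusp / cusp tip / incisal edge) are assigned by
  arch position, not tooth recognition; FDI numbering is out of scope.
* The segmentation thresholds (40° dihedral, compactness, relief) are
  calibrated for cast-like meshes at mm scale with locally uniform
  triangulation; heavily decimated or soup meshes may need retuning.
* Non-anomalous subjects are labelled category "none" (the source leaves
  open whether they were called "undefined" or "normal").
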