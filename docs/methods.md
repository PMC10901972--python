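# Methods

`aneupoint` implements a morphology-only rupture-risk pipeline for
intracranial aneurysms represented as watertight surface meshes: standardized
cropping of the sac (with or without a parent-vessel sleeve), conversion to
fixed-size point clouds, a hierarchical set-abstraction classifier producing
a softmax risk score, and stratified cross-validated ROC/AUC evaluation.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic studies do and do not demonstrate.

## Synthetic aneurysm geometry (`synthgeom`)

Real cohorts of 3DRA-segmented aneurysm models are replaced by a parametric
surrogate with known ground truth.  Each case is the smooth union of three
implicit solids, extracted by marching cubes (voxel pitch 0.25 mm by
default; grid offset by an irrational fraction of the pitch so planar caps
never coincide with grid planes):

- **Parent vessel** — a tube of radius `vessel_radius` (mm) along a straight
  or circular-arc centerline (`vessel_curvature` in 1/mm), clipped to
  `vessel_length` with planar end caps.
- **Neck tube** — a short cylinder of radius `neck_diameter/2` reaching from
  the vessel interior up to the neck plane, which sits 0.6 mm above the
  vessel surface.  The cylinder makes the minimal cross-section of the
  junction exactly the requested neck diameter (a plateau rather than a
  point), which is what makes the mesh-measured aspect ratio agree with the
  requested one to within ~5–10%.
- **Sac** — an ellipsoid of revolution placed so its section at the neck
  plane has the requested neck diameter and its apex sits `dome_height`
  above that plane; `dome_width` sets the equatorial diameter.  Irregular,
  bleb-carrying sacs are modeled by scaling the ellipsoid level set with a
  low-order lobed field (`bulge_amplitude` ≥ 0, angular frequency
  `irregularity_freq`, phases drawn from the per-case seed); the field
  vanishes at the poles so the neck and apex stay clean.  At
  `bulge_amplitude = 0` the sac is an analytic ellipsoid cap, verified in
  the tests to one voxel.

The smooth union uses a polynomial smooth-minimum with a 0.25 mm blending
width — a fillet comparable to the fillets real segmentations show at the
neck.  Parameter combinations whose sac would pierce the vessel floor or
wall raise a generation error naming the violated constraint; marching-cubes
extractions that graze a grid vertex (rare) are retried at 0.8× pitch,
deterministically.  An optional single side branch (a capsule of
`branch_radius` ≤ 0.5 mm) exists to exercise branch removal.

**Cohorts and labels.**  The established morphological rupture correlates —
aspect ratio (dome height / neck diameter), size ratio (dome height /
parent-vessel diameter) and surface irregularity — carry the class signal.
Each factor has a fixed plausible range (aspect ratio 0.7–2.6, size ratio
0.8–2.8, bulge 0–0.25; necks 2.0–3.2 mm, vessels clamped to 0.9–2.4 mm
radius, lengths 18–24 mm).  A cohort draws class-conditional sub-ranges:
with separation *s*, the unruptured-like class draws from the lower
(1 − *s*/2) fraction of each discriminative range and the ruptured-like
class from the upper.  At *s* = 0 the class distributions are identical
(AUC 0.5 by construction); at *s* = 1 they are disjoint per feature; the
feature-vs-label AUC is monotone in *s* (property-tested over seeds).  This
range-shift mechanism was chosen over a logistic link on a combined score
because it guarantees the per-feature disjointness at full separation that
the end-member checks rely on, while still giving a smoothly tunable,
recoverable signal; class counts are exact and everything is a pure function
of the cohort seed.  `noise_sd` (default 0.03) adds relative jitter to
nuisance parameters only, so the ground-truth shape factors stay exact.
The `features` knob restricts the signal to a subset of factors — the
cut1-vs-dome study uses `features=("size_ratio",)`.

What the generator does **not** emulate: bifurcations and vascular trees,
segmentation noise and imaging artifacts, wall-thickness or hemodynamic
information, and the real (unpublished) morphology distributions of
clinical cohorts.  Passing the synthetic studies therefore shows that the
pipeline recovers a known geometric signal end to end — not that it attains
any particular accuracy on clinical data.

## Mesh preprocessing (`meshproc`)

**Centerline.**  Cross-section centroid marching: planes advance along the
vessel in 0.5 mm steps; each section's maximal inscribed circle (shapely's
pole of inaccessibility) gives the next point and the local radius.  Three
safeguards make this robust on dome-carrying tubes: (1) a warm-up rebuilds
the radius baseline from the first stations, because the seed section near
an end cap can clip the lumen; (2) a station is flagged "contaminated" when
its inscribed radius jumps above 1.12× the running baseline, or drifts
off-axis while the radius grows — flagged stations are extrapolated
straight ahead and afterwards bridged linearly between their clean flanks;
(3) the direction is kept within 40° of the global principal axis (cohort
curvature is gentle; this is not a general tree extractor).  Accuracy
against analytic tubes: straight-axis RMS ≪ 0.1 mm, curved-arc RMS < 5% of
the radius, radii within 5% away from the ends.

**Neck detection.**  The apex is the surface point farthest from the
centerline; planes perpendicular to the base→apex axis are scanned from the
apex down.  The dome equator is the first local area maximum (after 3-point
smoothing of the area profile); the neck is the smallest raw section after
it, taking the station nearest the apex within 2% of the minimum because
the junction is a plateau by construction.  The dome footprint on the
centerline is the arc-length range of the connected excess-vertex component
containing the apex (vertices farther than 1.3× the local radius from the
centerline), so drift artifacts elsewhere cannot widen it.

**Cut1 and dome crops.**  "One vessel diameter" is measured as centerline
arc length from the neck-adjacent station on each side; the parent diameter
is the equivalent-area diameter 2·√(A/π) of a dome-free cross-section,
measured on the inflow side (the choice is recorded here; the convention in
the source data is unstated).  Cuts are half-space slices perpendicular to
the local centerline tangent; the dome configuration is a single planar
incision at the detected neck plane, and a cut1 crop with zero sleeve
degenerates to it.  Openings are capped with planar fans (`cap_openings`
defaults to true) so every stage output is watertight — whether the
reference pipeline capped its cuts before sampling is unknown, and capping
makes area-uniform sampling well defined.

**Branch removal and repair.**  Excess-vertex clusters whose ostium
(boundary ring projected to its best-fit plane) has equivalent diameter
below 2× the threshold are deleted and the notch fan-filled flush;
removal that would disconnect the surface is refused.  The dome's wide
ostium always survives.

**Smoothing** is explicit uniform-weight Laplacian relaxation
(factor 0.5, 3 iterations — the published settings; the reference
software's internal algorithm is unpublished).

**Isotropic remeshing** is a split/collapse/relax scheme written for this
package: edges longer than 4/3 of the 0.15 mm target are midpoint-split
(1-, 2- and 3-edge face patterns, vectorized); edges shorter than 4/5 of
the target are greedily collapsed to their midpoints over an independent
set, subject to the edge link condition *and* a face-collision guard (a
collapse that would duplicate a face across a tetrahedral pocket is
skipped — without this, rare non-manifold fins appear); a tangential
Laplacian step then re-projects vertices onto the input surface via
candidate-triangle search.  Four iterations land the median edge within a
few percent of the target with watertightness preserved; connectivity is
maintained exactly by the edit operations, so no vertex-merging pass is run
afterwards (merging could glue sheets the projection pushed together).

## Point clouds (`cloud`)

Meshes become clouds by area-uniform oversampling (4× by default) followed
by farthest-point sampling to exactly 8,192 points (the published cloud
size; scaled-down studies use 512–1024).  FPS is greedy max-min selection
with ties broken to the lowest index; it matches a from-scratch oracle
exactly and its covering radius beats random subsampling in expectation.
Ball query returns all points within a radius, capped at `max_k`, padded by
repeating the first entry; the serialization contract orders neighbors by
ascending index, while the network layers request nearest-first ordering so
that a truncated neighborhood is a function of the point set alone.  Clouds
are normalized to zero centroid and unit maximum radius before training
(whether the original study normalized is unstated; unit-sphere
conditioning is standard for this architecture family), with the
(centroid, scale) record kept so reports can reference mm coordinates.
Text serialization is one `x y z` line per point at 8 significant digits.

## Classifier (`net`)

A from-scratch NumPy implementation of the hierarchical set-abstraction
architecture with multi-scale grouping: per level, FPS centroids; per
scale, ball-query groups encoded by relative coordinates (the first level
also concatenates the absolute centroid coordinates), a shared per-point
ReLU MLP, and max-pooling; scale features concatenate.  A group-all stage
pools a global feature and a fully connected head with dropout (0.4, head
only) emits two logits; the loss is two-class softmax cross-entropy — the
"binary cross-entropy with softmax normalization" description reconciled as
the standard 2-way softmax CE.  The softmax probability of the ruptured
class is the risk score.

The reference publication names the architecture but not its dimensions;
the default `tiny_config` (two SA levels: 64 centroids at radii 0.15/0.3
with 8/16 neighbors and 16-wide MLPs, then 16 centroids at 0.3/0.6 with
32-wide MLPs; 64-wide global MLP; 32-wide head) is sized for CPU training
on normalized 512–2048-point clouds and is fully overridable.

Because centroid selection and grouping depend only on coordinates, each
cloud's grouping is planned once and cached; training then consists of
dense matrix products.  Gradients are hand-derived and verified against
finite differences for every parameter tensor; the forward pass is exactly
permutation invariant (geometric FPS start point, distance-ordered
truncation).  Float64 is used throughout — the networks are small enough
that precision costs nothing and gradient checks are clean.

## Training (`train`)

`TrainConfig` defaults are the published recipe: batch 20, 200 epochs,
Adam with initial learning rate 2e-5 and weight decay 1e-4 (classic L2),
and a cosine-annealing warm-restarts schedule in closed form.  The restart
parameters are unreported; the defaults are T0 = 10 epochs with cycle
doubling, configurable.  Stratified 5-fold splitting (scikit-learn's
`StratifiedKFold` behind the module surface) keeps class proportions within
one sample per fold.  Per epoch, accuracy/sensitivity/specificity/AUC are
recorded for the train, internal-validation and optional external splits;
an id-level audit asserts that no validation or external sample ever
contributes a gradient.  Bitwise repeatability is promised in
single-threaded deterministic mode; otherwise repeatability is statistical.
No augmentation or class re-weighting is applied (none is described in the
reference recipe).

The scaled-down synthetic studies override epochs and learning rate
(typically 8–25 epochs at 5e-3): a freshly initialized float64 network this
small simply does not move at 2e-5 within a reduced epoch budget, and the
overrides are part of the study scaling, not of the default recipe.

## Evaluation (`evalreport`)

The ROC sweeps thresholds over unique scores with ties stepping
simultaneously, making the trapezoidal AUC exactly the Mann–Whitney
pair-counting statistic (ties = ½) — property-tested against the exhaustive
oracle and cross-checked against scikit-learn.  Confusion metrics use a 0.5
operating threshold by default (the operating point behind the published
confusion matrices is unstated).  Positive class = ruptured throughout.

**Optimal-epoch selection.**  The source criterion ("the most reliable and
robust curve across the training, internal and external sets") is not
operationalized and would let external performance influence model
selection.  The default `guarded` policy maximizes internal-validation AUC
subject to a train/validation gap ≤ 0.15 and never consults the external
set; a `min_of_three` policy (maximize the minimum of the three AUCs) is
available for comparison.  Ties go to the earliest epoch.

Fold aggregation is the unweighted arithmetic mean, reported at two
decimals alongside full precision — the tests verify this reproduces every
Average-row entry of the published five-fold table from its printed
per-fold values.  Mean ROC curves use vertical averaging on a fixed
101-point FPR grid.  Risk reports rank cases by score with a configurable
alert level; per-case scoring failures are reported and skipped.

## Problem sizes of the bundled studies

The acceptance checks and `scripts/acceptance.py` run the pipeline at desk
scale, chosen as the smallest sizes at which each property is comfortably
demonstrated: signal recovery on a 400-case, 1024-point cohort at
separation 0.8 (5-fold, 25 epochs; mean validation AUC ≈ 0.98, far above
the 0.80 bar, with an external cohort at the shifted 55/45 class mix); the
cut1-vs-dome ordering on 36-case cohorts whose label depends only on size
ratio, over several seeds — the normalized dome-only cloud discards the
dome-to-vessel size relation, so the sleeve-carrying cut1 crop wins; a
100-case null cohort at separation 0, scored by the final-epoch
validation AUC because best-epoch selection is upward-biased under pure
noise (AUC 0.5 ± sampling error); and a
50-case geometry sweep for the sleeve-length invariant, with the remeshing
stage verified on a subset because it is the slowest operation.  The
published clinical AUCs (internal 0.85/0.81, external 0.71/0.69 for
cut1/dome) are properties of the original clinical dataset and a GPU-scale
configuration; they are not reproduction targets of the synthetic studies.

## Known limitations

- The centerline tracker assumes a single, gently curved parent vessel;
  bifurcation-rich anatomy is out of scope.
- Neck detection assumes one dominant sac; multiple aneurysms per segment
  are not handled.
- The remesher values robustness over mesh quality; it performs no edge
  flips, so valence regularity is below that of full Botsch–Kobbelt
  implementations.
- Softmax risk scores are not calibrated probabilities; no confidence
  intervals or AUC-difference tests are provided.
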