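# Methods

`vesselmorph` quantifies the morphology of brain blood vessels from a 3D
binary segmentation mask. This note documents the algorithms, the
conventions and tunable parameters, what the synthetic phantoms do and
do not emulate, and the numerical choices made where the design was
genuinely open.

## Pipeline overview

A binary vessel mask (NIfTI, possibly anisotropic voxels) is processed as

1. **thinning** to a one-voxel-wide centerline,
2. **topological classification** of centerline voxels,
3. **radius estimation** from the Euclidean distance transform (EDT),
4. **junction-artifact cleaning** guided by the local radius,
5. **decomposition** into individual vessel segments at bifurcations,
6. **per-segment geometry** (length, chord, tortuosity), and
7. **aggregation** into an 11-feature per-subject summary.

All measurements are in physical units: voxel indices are mapped to
world coordinates through the NIfTI affine, so lengths, radii and
volumes come out in mm regardless of voxel anisotropy (e.g. the
0.47 × 0.47 × 0.8 mm grids typical of time-of-flight angiography).

## Thinning

The centerline is produced by topology-preserving thinning implemented
in `vesselmorph._thinning` (numba-compiled). A voxel may be deleted only
if it is a *simple point* — its removal changes neither the 26-connected
foreground topology nor the 6-connected background topology — and is not
a line endpoint (a voxel with exactly one foreground neighbour).
Simplicity is tested with the classical two-condition characterization
for (26, 6) digital topology: exactly one 26-connected foreground
component in the punctured 3×3×3 neighbourhood, and exactly one
6-connected background component in the 18-neighbourhood touching a face
neighbour.

Deletion order matters for *where* the skeleton ends up, not for its
topology. Two orderings are combined:

* **distance shells**: voxels are eligible for deletion in increasing
  order of their (static) distance to the background, so the ridge of
  the distance transform — the medial axis of a tube — is reached last
  and survives;
* **directional subiterations** within each shell (up/down/north/south/
  east/west, candidates collected per direction and then rechecked
  sequentially), which keeps the peeling symmetric and preserves tube
  tips.

Every deletion is of a point that is simple in the *current* image, so
component counts (26-connected foreground, 6-connected background) are
invariants of the operation, the result is a subset of the input, and
re-thinning a skeleton is the identity. With pure ascending-distance
ordering the line tips retract by roughly one radius; with pure
directional peeling the centerline of an obliquely oriented tube bows
off-axis by 1–2 voxels per pass. The combination exhibits neither
artifact at the scales the test suite probes.

## Point classification and radii

Each skeleton voxel is classified by its number of 26-neighbours within
the skeleton: 0 or 1 → endpoint, 2 → regular, ≥ 3 → bifurcation.

The radius at a centerline voxel is the anisotropic EDT of the mask
sampled at that voxel: the distance, with per-axis spacing, from the
voxel center to the nearest *background voxel center*. No half-voxel
correction is applied; the convention is exact, documented, and the test
oracles (a brute-force nearest-background search) use the same one. The
convention biases absolute radii by up to about half an in-plane voxel
diagonal, which matters below ~3-voxel radii; relative comparisons
between subjects are unaffected.

## Junction cleaning

Thinning real (or rasterized) junctions does not produce a single
bifurcation voxel: the junction blob yields clusters of branch voxels,
short spurs, and sometimes a junction split into two nearby branchings.
Counting these raw artifacts would make `n_bifurcations` a property of
the voxel grid rather than the vasculature, so the default pipeline
cleans the skeleton with rules that are *relative to the local vessel
radius* (from the EDT) and therefore scale-free:

* **spur pruning** — a terminal segment shorter than 2 × the radius at
  its attachment node lies entirely inside the parent vessel's lumen and
  cannot be a resolved branch; it is deleted. An absolute floor in mm
  (`min_spur_length_mm`, default 0) is also available.
* **connector collapse** — a segment joining two bifurcation nodes (or
  looping back onto one) over less than 3 × the local radius is a split
  junction; its voxels are absorbed into the node, merging the cluster.
  Three radii is the extent over which two tubes leaving a common
  junction at ≳ 60° remain merged on the voxel grid.
* **degree resolution** — after merging, a node cluster is only counted
  as a bifurcation if at least three segments attach to it. Degree-2
  clusters ("thick corners") dissolve into a through-path; degree-1
  clusters (terminal blobs) are appended to their segment.

Both factors can be set to 0 to obtain the raw decomposition. On the
phantom suite (below), cleaning changes exact topology recovery from
roughly two-thirds of phantoms to 99–100%.

Endpoints are counted structurally after cleaning: the number of free
segment ends plus isolated voxels.

## Segments and tortuosity

Removing the bifurcation nodes disconnects the skeleton into maximal
simple paths; each path plus its attachment voxel on any adjacent node
is one vessel segment. Per segment:

* `length_mm` — the sum of Euclidean steps between consecutive path
  points in world coordinates. The sum is taken on a lightly smoothed
  polyline (moving average, 5-point window, endpoints pinned), because
  the raw voxel staircase overestimates the arc length of oblique or
  curved vessels by up to ~8%; smoothing leaves collinear paths exactly
  straight, keeps `length ≥ chord`, and brings a digitized semicircle
  within 1.5% of its analytic length. `smooth_window=1` restores the raw
  sum.
* `chord_mm` — the straight-line distance between the segment's two end
  points.
* `tortuosity` — `length_mm / chord_mm`, defined when the chord is
  positive. Closed loops (a cycle with no bifurcation) are one closed
  segment with chord 0 and tortuosity flagged undefined (NaN), never an
  exception.

## The 11-feature summary

`extract_features` aggregates mask and tree into the per-subject vector:
total volume (foreground voxels × |det| of the affine's linear part),
total centerline length, segment/bifurcation/endpoint counts, mean/SD/
max radius over centerline points (bifurcation-node radii included by
default, configurable), mean/SD tortuosity over segments with defined
tortuosity, and mean segment length over segments of positive length.
Degenerate inputs (an empty mask) yield zero counts and NaN-flagged
means. The set has eleven features because eleven is the number of
vessel terms the downstream model comparisons add to a cortical model;
the composition is configurable at the table level by selecting columns.

`VesselFeatureExtractor` wraps the pipeline as a scikit-learn
transformer (a list of masks or NIfTI paths in, a features DataFrame
out), so it composes with sklearn pipelines and parameter search.

## Segmentation overlap

`dice(a, b) = 2|A∩B| / (|A|+|B|)` on identical grids, with the
convention that two empty masks have Dice 1. The grid-identity check
compares shapes and affines.

## Synthetic phantoms

The phantom module rasterizes tubes of known radius around analytic
curves — straight lines, circular arcs, helices, Y-junctions, and random
binary trees — so that every downstream quantity has a closed-form or
recorded truth. A voxel is foreground iff its center lies within the
tube radius of a densely sampled centerline (sample step = min spacing
/ 4, which bounds the surface error by an eighth of a voxel).

Conventions chosen for measurement fidelity:

* free ends of single-tube phantoms are clipped flat by the end planes,
  so a straight tube is a true finite cylinder and the analytic volume
  π r² L applies; arc, helix and tree ends carry spherical caps instead,
  because a flat *oblique* end has a disc-shaped medial axis that
  corrupts thinning near the tip;
* tube axes are offset from the grid center by a fixed sub-voxel vector
  (0.1234, 0.0567, 0.0891) mm; without it the axis sits on a special
  lattice phase and the rasterization error is identical at every grid
  resolution instead of converging;
* the expected volume of a multi-branch phantom is the rasterized union
  (junction overlap counted once), while the π r² Σ L sum is recorded
  separately as `analytic_volume_mm3`.

Random binary trees grow from a trunk by splitting tips: polar angles
off the parent direction drawn from (40°, 55°), sibling azimuths opposed
within ±15°, giving inter-sibling angles ≳ 80° so child tubes detach
within about two radii of the junction. Candidate branches are rejected
unless every sample point stays > 4 × radius away from non-adjacent
branches (for parent and sibling pairs the zone within 4 × radius of the
shared junction is exempt) and the tube stays inside the grid with
margin; the whole tree restarts deterministically (up to 20 times from
the same seed stream) if a split cannot be placed. The default suite
(`random_tree_suite`) draws tube radii uniformly from 1–3 mm on a 128³,
0.5 mm isotropic grid with 3 planned bifurcations, and scales branch
lengths with the radius (minimum 4 r + 3 mm) so the separation rule
remains feasible across the radius range.

What the phantoms emulate: tubular geometry, branching topology, radius
and curvature ranges, anisotropic grids, paired "anatomical" volumes
with controllable contrast and Gaussian noise. What they do not emulate:
MR physics (flow contrast, bias fields, partial-volume profiles),
segmentation errors (holes, breaks, false positives), and realistic
Circle-of-Willis geometry. Passing the phantom suite therefore
demonstrates that the *quantification* is faithful to a known geometry;
it says nothing about segmentation quality on real images.

## Statistical evaluation

`vesselmorph.stats` implements the evaluation protocol over per-subject
tables (one row per subject: age, sex, blood pressures, MMSE, cortical
thickness columns prefixed `thickness_`, and the 11 vessel features).
Nine named Patsy formulas are registered: age as a linear function of
cortex / vessels / both; a dependent variable (diastolic or systolic
blood pressure, MMSE) on age + sex + cortex / vessels / both; and
logistic hypertension classifiers with the same three predictor sets.
Fits go through statsmodels OLS/Logit with listwise deletion; nested
comparisons are computed on identical complete-case rows, enforced
explicitly.

* **Nested ANOVA**: F = ((SSR_reduced − SSR_full)/df_num) /
  (SSR_full/df_den), df_num = number of added parameters, df_den = the
  full model's residual degrees of freedom; p from the F distribution.
  The implementation is SSR-based; the test suite cross-checks it
  against `statsmodels.stats.anova.anova_lm` to 1e-8 and verifies the
  5% type-I error level empirically (1000 null replicates).
* **Cross-validated R²**: subjects are shuffled into k = 10 folds
  (seeded `sklearn.model_selection.KFold`, not stratified); each fold is
  predicted by a model fit on the rest, and one coefficient of
  determination 1 − SS_res/SS_tot is computed over the pooled
  out-of-fold predictions, so every subject is predicted exactly once by
  a model that never saw them.
* **Hypertension rule**: diastolic > 90 mmHg or systolic > 140 mmHg,
  with *strict* inequalities ("above"); the boundary pair (90, 140) is
  labelled negative, and missing blood pressures yield a missing label
  that is dropped listwise downstream.
* **Logistic comparison**: there is no exact F-ANOVA for logistic
  models, so the nested comparison reports an analysis-of-deviance F
  with the same df bookkeeping as the OLS case, plus a likelihood-ratio
  χ² test clearly labelled as an extension. Perfect separation is
  flagged with a warning, not raised.
* **Age subgroups**: older is strictly above 60 years; 60 and below is
  younger.

`simulate_subject_table` generates a synthetic life-span cohort (ages
uniform 18–88) whose noise scales were chosen to land in the regime of
real cohorts of this kind: a vessels-only age model explains ≈ 40% of
variance, cortex-only ≈ 60%, the combined model ≈ 70%, and hypertension
prevalence is ≈ 10%. It exists to exercise the model plumbing at
realistic signal-to-noise, not to make biological claims.

## Problem sizes and numerical choices

Default grids are 128³ voxels at 0.5 mm isotropic — a single phantom
runs through the full pipeline in roughly a second after JIT warm-up, so
the 20-phantom recovery suite and the 1000-replicate null simulation run
in minutes on one CPU. Mask resampling is trilinear with 0-fill outside
the source domain (all inputs are masks or brain-extracted volumes) and
an explicit threshold (default 0.5) when the resampled volume is re-
binarized. Ties in the thinning order are broken lexicographically;
every random component (phantom growth, fold assignment, simulated
cohorts) is driven by an explicit integer seed, and identical inputs
produce bit-identical outputs.

## Known limitations

* Absolute radii inherit the voxel-center EDT convention's bias
  (≈ ±half a voxel diagonal); sub-voxel radius fitting is out of scope.
* Tortuosity of segments shorter than ~10 voxels is dominated by
  digitization and should not be interpreted.
* The junction-cleaning defaults assume roughly tubular vessels; highly
  plate-like structures (which produce medial surfaces) are outside the
  intended domain.
* The statistical module evaluates model structure on tables it is
  given; it does not correct for multiple comparisons across dependent
  variables.
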