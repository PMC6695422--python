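# Methods

## Problem and pipeline

Two cortical networks (call them "reading" and "math") can project through
the same anatomical fascicle — say the superior longitudinal fasciculus —
while occupying distinct parallel sub-bundles ("lanes"). Given a tractogram
with fascicle labels, GWMI masks under the fROIs of each network, and a
co-registered quantitative map, the pipeline answers three questions:

1. **Which streamlines belong to each network?** A streamline is part of an
   fROI's functionally defined white-matter tracts (fWMT) when an endpoint
   lies in the fROI's GWMI mask. Pairwise connections between fROIs are the
   intersections of these sets, summarized by the Dice coefficient
   DC = 2|A∩B| / (|A|+|B|) and compared against an empirical chance level
   (mean DC between network fROIs and out-of-network control ROIs).
2. **Are the two networks' tracts segregated within a fascicle?** After
   resampling to 100 equal-arc-length nodes, (a) each streamline's Euclidean
   distance to its own network's core (per-node mean) tract is compared with
   its distance to the other network's core, and (b) a linear SVM trained on
   node coordinates is tested five nodes toward the posterior end; balanced
   accuracy above the 50% two-class chance level indicates segregation along
   the fascicle's length.
3. **Do the lanes differ in tissue properties?** Scalar maps are sampled by
   trilinear interpolation at every node; tract-average values are compared
   across replicates by paired t-tests, per-node tests use a Bonferroni
   threshold alpha / n_nodes.

## Coordinate conventions

All geometry is RAS+ world millimetres. Voxel indices are 0-based; a world
point belongs to voxel v iff the inverse affine maps it within half a voxel
of v's centre (rounding half away from zero). TRK voxel-offset conventions
are resolved on load (nibabel), so TRK and TCK files of the same geometry
are interchangeable. Labels travel in a CSV sidecar because TCK has no
per-streamline fields.

## The phantom generator

Real subject data for this kind of analysis is not redistributable, so the
package ships a generator that produces the statistical structure the
analysis assumes, with full ground truth:

- A planar circular-arc centreline (default chord ≈ 79 mm along +y, sagitta
  `curvature` = 10 mm toward +z, emulating an arched association fascicle)
  carries the "reading" lane; the "math" lane's centreline is offset by
  `separation_d` (default 8 mm) along +z, matching a superior/inferior lane
  layout. `separation_d = 0` yields perfectly intertwined lanes.
- Each lane holds `n_per_bundle` = 100 streamlines: the centreline plus a
  smooth Gaussian-process offset field (squared-exponential kernel over arc
  length, length scale 1/4 of the tract) whose per-node marginal SD is
  exactly `jitter_sigma` = 2 mm per axis. A GP draw rather than interpolated
  control points keeps that marginal exact everywhere, which the calibration
  tests rely on; i.i.d. per-node jitter would make streamlines unrealistically
  rough and break arc-length resampling.
- Endpoint GWMI masks are voxelized 5 mm spheres at the four lane termini
  (named IFG/SMGr for the reading pair, PCS/SMGm for the math pair), plus a
  7 mm off-bundle control sphere, the radius used for constant-size control
  ROIs in fROI work. Draws whose endpoints miss their designated masks are
  rejected and redrawn, so the guarantee "every non-outlier streamline
  connects to both of its masks" holds exactly while node cross-sections
  stay near-isotropic. (An earlier tapered-jitter design pinned the ends,
  collapsed the along-track node variance, and let the max-margin classifier
  exploit the degenerate direction — rejection avoids that artifact.)
- `n_outliers` = 5 gross outliers are jittered copies of the reading
  centreline displaced 50 mm laterally; they carry the reading lane's
  fascicle label (so 4-SD cleaning has real work) but truth label "outlier".
- The scalar map assigns each voxel whose centre lies within
  2·`jitter_sigma` of a lane's streamline point cloud that lane's baseline
  (defaults: reading 0.95 s, math 1.05 s — plausible 3T white-matter T1
  magnitudes; background 1.50 s), plus N(0, 0.02 s) voxel noise. Assignment
  uses the generated point clouds, not the centrelines, so every sampled
  node lies inside its own lane's region; the residual partial-volume mixing
  at lane borders (a feature real maps share) biases tract means by
  ~0.002 s, well inside the recovery bounds.
- Everything is drawn from one `numpy` generator seeded by `spec.seed`;
  output is bit-identical for a fixed spec.

What the phantom does **not** emulate: anatomy (no realistic fascicle
shapes, crossing fibres, or partial voluming from CSF), subject-to-subject
registration error, tractography biases (seeding density, curvature
thresholds), or multi-compartment qMRI physics. Passing tests therefore
demonstrate correctness of the *analysis machinery* under its stated
statistical assumptions, not performance on real dMRI data.

## Numerical choices

- **Resampling** interpolates linearly along the piecewise-linear path at
  equal arc length; endpoints are copied exactly. Node spacing CV < 1% and
  invariance under midpoint refinement are asserted in tests.
- **Orientation** flips streamlines to agree with an anchor direction
  (default +y ⇒ node 0 anterior), making "five nodes more posterior"
  well-defined; phantoms have no waypoint ROIs, so the full streamline
  extent is resampled.
- **Cleaning** iterates (≤ 5 passes): representative distance = mean node
  distance to the current core; drop streamlines above mean + 4 SD;
  recompute. Ties at the threshold are kept (strict inequality), so a
  zero-variance bundle removes nothing. Representative distance uses
  location only (not length): the 4-SD rule as stated concerns location.
- **Within/between distances**: within-network distances use the
  leave-one-out core. With the plain core each streamline shrinks its own
  bundle mean, biasing between−within by +O(1/n) (~0.03 mm at n = 100) and
  making the intertwined null test significantly "segregated" with certainty.
  LOO restores a calibrated null (sign of the difference ~Binomial(0.5))
  and is indistinguishable from the plain estimator at separation 8 mm.
  `core_tract` itself remains the plain per-node arithmetic mean.
- **Classifier**: SVC with linear kernel, C = 1, no feature scaling (inputs
  are commensurate mm), balanced accuracy (so unequal lane sizes cannot
  inflate scores), lag ≥ 1 enforced, training nodes with i + lag beyond the
  last node are skipped, accuracy attributed to the training node. Points
  classified by libsvm's deterministic rule; duplicated coordinates with
  opposite labels score exactly 50%.
- **Sampling**: trilinear by default (exact at voxel centres, continuous
  across boundaries); nearest-neighbour mode follows the voxel-membership
  rounding convention. Out-of-grid samples are NaN-flagged and excluded
  with a count; > 50% missing is an error.
- **Paired t-tests** flag zero-variance differences explicitly (t = 0 when
  all differences vanish, signed infinity otherwise) instead of silent NaNs.
  Undefined Dice coefficients (no connections at all) are reported missing,
  never as 0, so chance levels are not biased downward.

## Test problem sizes

Simulation-based tests use the generator defaults (120 mm cube, 100
streamlines per lane, 100 nodes) with 3–20 seeds per claim; the
false-positive calibration of the profile comparison runs 200 zero-contrast
comparisons of 8 paired replicates that share one phantom geometry and
redraw the map's voxel noise — the noise field being the only stochastic
element that null concerns. The full suite runs in a couple of minutes on
one CPU.

## Known limitations

- Endpoint-mode intersection with thin real GWMI masks is sensitive to the
  rounding convention; `any_point` mode exists, and mask dilation upstream
  is advisable for single-voxel-thick interfaces.
- "Non-neighbouring" fROI pairs and chance-level pair selection are study
  design choices; `chance_dc` takes an explicit exclusion list rather than
  guessing adjacency.
- The classifier's accuracy depends on bundle curvature through the
  train/test node shift (posterior accuracy drop along arched fascicles is
  reproduced by the phantom); reported accuracies are therefore a property
  of geometry plus scatter, not of scatter alone.
- Replicates stand in for subjects in all group-level statistics; there is
  no hierarchical (mixed-effects) modelling.
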