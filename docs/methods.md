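# Methods

## Data model and geometry

A streamline is an ordered float array of ≥ 2 three-dimensional points in
millimetres; order encodes traversal and is never permuted by any
operation.  All geometry lives in a RAS-like space with superior = +z
("below" means decreasing z), captured by `SpaceConvention` and assumed
atlas-aligned upstream — the package performs no registration.  The brain
center is the unweighted centroid of all streamline points: deterministic,
atlas-free, and translation-equivariant.  Arc-length resampling places
`n_points` samples equally spaced in cumulative polyline arc length with
endpoints preserved exactly; the model default is 15 points per
streamline, a small fixed size typical of point-based streamline
classifiers (configurable everywhere it appears).

## FOV-cut augmentation

A cutting plane is parameterized by tilt θ to the horizontal, azimuth φ,
and depth *d* below the brain center; its unit normal is
(sin θ cos φ, sin θ sin φ, cos θ) and its anchor is center − (0, 0, d).
Sampling is independent and uniform: θ ~ U[0, 30°], φ ~ U[0, 360°),
d ~ U[30, 50] mm — the sampler only states "random within constraints",
so independence and uniformity are the simplest faithful choice.  The
kept half-space is closed (boundary points survive), a deterministic tie
rule.

Cutting keeps, for each streamline, the longest contiguous run of
surviving points, earliest run on ties.  A truncated acquisition cannot
produce a streamline spanning the missing region, so re-entrant
streamlines do not keep both fragments.  Runs shorter than
`min_retained_points = 2` (a single segment being the minimal meaningful
streamline) mean removal.  Outcomes partition the input
(n_unaffected + n_cut + n_removed = n_input), retained points are an
order-preserving subset of the originals with unaltered coordinates, and
labels are preserved — the training signal is precisely that a truncated
streamline keeps its tract identity.  Depth is monotone: a deeper plane
keeps a superset of any shallower plane's points at the same tilt.

Augmentation emits the original plus `n_planes_per_subject = 10` cut
variants per subject with JSON provenance (plane parameters and outcome
counts).  Pre-removal this is n_subjects × n_streamlines × 11 labeled
streamlines; at the reference scale of 70 × 10,000 that is 7.7 million.
Superior/dorsal cutoff simulation is out of scope.

## Local–global context

The neighbor metric is the minimum average direct-flip (MDF) distance on
resampled streamlines — the standard flip-invariant streamline distance in
this literature (the triangle inequality is not guaranteed and not used).
kNN is exact, chunked, and deterministic, with ties broken toward lower
indices; the anchor is excluded from its own neighbor list and instead
contributes an explicit self-pair row, so the context block has
1 + n_local + n_global rows.  Global context is drawn uniformly — without
replacement when the tractogram is large enough, with replacement
otherwise.  During training the global sample is redrawn per anchor every
epoch (fresh stochastic context); at inference a single shared global
sample per tractogram is frozen from `inference_seed`, which makes
prediction deterministic and gives geometrically identical streamlines
identical predictions.

## Network and training

The feature block (context × points × 6) passes through one shared fully
connected layer with ReLU per paired point, then max-pooling over the
context axis (the learned local–global representation, default width 64),
then PointNet-style shared per-point layers (64, 128, 1024) with ReLU,
max-pooling over the point axis, and a fully connected head (512, 256)
with dropout 0.3 and softmax.  No T-Net: absolute streamline position
carries anatomy and must not be normalized away.  The paper family fixes
the architecture but not the widths; the defaults above are the standard
PointNet classification configuration and are fully configurable.

Two structural invariances follow from the pooling and are tested:
the output is invariant to any permutation of context rows, and to a
*consistent* permutation of the point axis (shared per-point transforms +
max-pool carry no point-index information).  Geometry enters through the
per-point anchor–context pairing: permuting context points against anchor
points does change the output.

Forward, backward and Adam are implemented directly on float32 numpy
arrays (gradients spot-checked against central finite differences).
Input coordinates are scaled by a fixed 0.01 at network entry — pure
rescaling of mm to ~unit range for optimization conditioning, with no
centering, so position information is intact.  Training: Adam, lr 0.001,
batch 1024 (auto-reduced with a warning on smaller datasets),
cross-entropy, 20 epochs; a non-finite loss raises a `TrainingError` with
the epoch index; a single-class training set is rejected.  Runs are
bit-reproducible for a fixed seed on a fixed platform (single-threaded
deterministic numpy kernels; BLAS threading may introduce float variation
across platforms).

The estimator (`TractographyParcellator`) follows scikit-learn
conventions: constructor parameters mirror `get_params`/`set_params`,
fitted state lives in trailing-underscore attributes, `fit` accepts lists
of labeled tractogram variants, and `predict`/`predict_proba` operate on
one tractogram at a time because context must come from that tractogram.
Checkpoints are a single `np.savez` file carrying weights plus a JSON
config echo whose SHA-256 is validated on load.

## Synthetic cohorts

The generator emulates the *structure* of a labeled whole-brain
tractogram, not the anatomy of the 73 real atlas tracts: six smooth
bundles (each the arc-length-resampled centerline plus a per-streamline
constant Gaussian offset in the perpendicular plane, sd 2 mm per axis,
and 0.5 mm per-point jitter) spanning a head-sized volume, three of them
descending below the cut zone (two corticospinal-like verticals reaching
z ≈ −78 mm and a cerebellar-like arc), plus rough random-walk "other"
streamlines (step sd 6 mm) filling the bounding box.  Default cohort: 10
subjects × (6 × 100 + 50) = 650 streamlines/subject, seeded per subject
via `SeedSequence` spawn keys so cohorts are fully reproducible and
subjects mutually distinct.  What passing tests on this cohort shows is
that the pipeline's mechanics and the augmentation effect direction are
correct; it says nothing about absolute accuracy on real tractography,
where bundles overlap, curve, and share space with far more heterogeneous
outliers.  Notably the synthetic cohort places half its bundles in the
inferior zone, so planes affect ~30–50 % of streamlines — far above the
~10 % typical of real whole-brain tractograms.

## Evaluation choices

Macro-F1 averages per-class F1 over a caller-supplied tract-class subset;
classes absent from both predictions and truth score 0, so missing
expected tracts penalize the mean (identification completeness).  TIR
uses the ≥ 20-streamline threshold.  ATD is directional subject→atlas
mean closest-point distance after resampling (configurable to symmetric);
empty identified tracts return NaN with a warning and are excluded from
cohort means but counted.  Severity strata (mild/moderate/severe) are
caller-supplied tags — the package does not recompute image-domain QC
scores.  Stratified reports accept per-streamline tags or named index
sets; tag-style strata partition the set, so overall accuracy equals the
size-weighted mean of stratum accuracies.

## Desk-scale problem sizes

`tractofov.experiments` fixes the CPU-scale study conditions used by the
test suite and `scripts/acceptance.py`: a narrow network (repr 32,
backbone 32/64/128, head 64/32), context 10 local + 30 global, batch 128,
and the unchanged 20-epoch Adam protocol.  The separable benchmark is two
straight bundles 40 mm apart (2 × 250 streamlines).  The
truncation-robustness experiment trains on 2 subjects × 260 streamlines
(originals only vs. originals + 4 cut variants each) and scores both
models on a held-out subject cut with one plane, reporting accuracy
separately on cut and unaffected surviving streamlines over 3 seeds.  The
comparison is directional (augmented ≥ plain on cut streamlines, majority
of seeds, with a 0.02 non-inferiority margin on unaffected streamlines);
the magnitude of the gap on real data is not asserted by synthetic
experiments.

## Known limitations

- No registration, no diffusion-image I/O, no tracking: tractograms are
  assumed mm-space and atlas-aligned.
- The VTK/VTP readers cover the ASCII polyline subset this package
  writes; binary VTK variants are not parsed.
- `predict` requires more streamlines than `n_local`; tiny tractograms
  cannot supply a context.
- Per-epoch global resampling and the frozen inference sample are
  documented choices where the reference protocol is silent; likewise the
  15-point resampling and the MDF neighbor metric.
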