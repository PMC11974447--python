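# tractofov

Tractography parcellation that stays robust when the scan's inferior field
of view (FOV) is incomplete.

## The problem

Diffusion-MRI tractography reconstructs white-matter pathways as
*streamlines* — ordered 3-D polylines in mm.  Parcellation assigns every
streamline of a whole-brain tractogram to a named fiber tract (or to an
"other"/outlier class).  Clinical acquisitions frequently miss inferior
slices, so tracts through the brainstem and cerebellum (corticospinal
tract, cortico-ponto-cerebellar pathway, cerebellar peduncles, ...) arrive
truncated, and parcellation methods trained on complete tractograms
misclassify them.

`tractofov` addresses this with two ingredients:

1. **FOV-cut augmentation.**  Training tractograms are synthetically
   truncated by random planes constrained to 30–50 mm below the brain
   center with a tilt of at most 30° to the horizontal.  A point *p*
   survives a plane with superior-oriented unit normal **n** and anchor
   *a* iff **n**·(*p* − *a*) ≥ 0; each streamline is then `unaffected`,
   `cut` (longest contiguous surviving run kept), or `removed`.  With the
   default 10 planes per subject, each training subject contributes 11
   tractogram variants — at the scale of 70 subjects × 10,000 streamlines
   that is 7.7 million labeled streamlines before removal.
2. **A local–global streamline representation.**  Each streamline
   (*anchor*) is classified together with context from its own — possibly
   truncated — tractogram: its *k* = 20 nearest neighbors under the
   minimum average direct-flip (MDF) distance plus 500 randomly sampled
   whole-brain streamlines.  Anchor and context streamlines are resampled
   to 15 points and paired per point into 6-D features
   [*x*ᵃ, *y*ᵃ, *z*ᵃ, *x*ᶜ, *y*ᶜ, *z*ᶜ]; a shared fully connected layer +
   ReLU followed by max-pooling over the context rows yields the
   representation, which feeds a PointNet-style classifier (shared
   per-point layers, max-pool over points, fully connected head, softmax).
   No spatial-transformer (T-Net) is used: absolute position is
   anatomically meaningful.  Training is end to end with Adam
   (lr 0.001), cross-entropy, batch 1024, 20 epochs.

Because context is drawn from the same cut variant as the anchor, a cut
changes the representation even of streamlines the plane never touched —
repeated streamlines across variants are genuinely distinct training
samples.

Evaluation covers label-based metrics (streamline accuracy; macro-F1 over
the tract classes, "other" excluded) and reference-free metrics: **TIR**
(tract identification rate — fraction of expected tracts with ≥ 20
assigned streamlines, averaged over subjects) and **ATD** (atlas-to-tract
distance — mean closest-point distance in mm from an identified tract to
its atlas counterpart).

The package ships a seeded synthetic-cohort generator (smooth bundles
around controlled centerlines, several descending into the inferior cut
zone, plus rough random-walk outliers), so the entire pipeline is testable
without any imaging data.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from tractofov import CohortConfig, FovcaConfig, augment_cohort, generate_cohort, fraction_cut
from tractofov.experiments import fovca_benefit_experiment
from tractofov.synthetic import default_bundle_specs

cfg = CohortConfig(n_subjects=3, bundles=default_bundle_specs(40), n_outliers=20, seed=0)
cohort = generate_cohort(cfg)
variants = augment_cohort(cohort[:2], FovcaConfig(n_planes_per_subject=4, seed=1))
v = variants[1]
print(v.variant, v.provenance["plane"], v.provenance["n_unaffected"],
      v.provenance["n_cut"], v.provenance["n_removed"], round(fraction_cut(v.outcomes), 3))

r = fovca_benefit_experiment(seed=0)
print(r["plain_acc_cut"], r["fovca_acc_cut"])
```

prints (rounded):

```
cut01 {'theta': 21.0, 'phi': 62.8, 'depth': 42.9} 133 86 41 0.488
0.942 1.0
```

The first line is one cut variant of a 260-streamline synthetic subject:
a plane tilted 21.0° at depth 42.9 mm left 133 streamlines unaffected,
truncated 86 and removed 41 (48.8 % affected — the synthetic cohort puts
half its bundles in the inferior zone, far more than a real brain).  The
second line is the point of the package: on the cut streamlines of a
held-out, synthetically truncated subject, a model trained *with* FOV-cut
augmentation reaches accuracy 1.00 where the identically configured model
trained on complete tractograms only reaches 0.94.

The same pipeline is available from the shell:

```bash
tractofov simulate --config cohort.yaml --out sim/
tractofov augment  --in sim/ --out aug/ --n-planes 10 --seed 1
tractofov train    --train aug/ --config train.yaml --out model.ckpt
tractofov parcellate --model model.ckpt --in sim/sub-000.trk \
    --out-labels pred.labels.tsv --out-tracts tracts/
tractofov evaluate --pred pred.labels.tsv --truth sim/sub-000.labels.tsv \
    --other-label 6 --out report.json
```

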