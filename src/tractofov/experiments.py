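"""Desk-scale experiment recipes.

These functions bundle the package's own study conditions for CPU-scale
runs: a small synthetic cohort, a narrow network, and a reduced context.
They exist so that tests, the acceptance script and users exercise the
identical pipeline — generate, augment, train, predict, evaluate — with
problem sizes that complete in minutes on one core.  The package defaults
(wide network, 20 local + 500 global context, batch 1024) remain the
reference protocol for full-size data.
"""

from __future__ import annotations

import numpy as np

from .fovca import CUT, REMOVED, UNAFFECTED, FovcaConfig, augment_cohort
from .model import TractographyParcellator
from .synthetic import BundleSpec, CohortConfig, default_bundle_specs, generate_subject
from .tractogram import LabeledTractogram

__all__ = [
    "desk_model_params",
    "separable_two_bundle_tractogram",
    "fovca_benefit_experiment",
]


def desk_model_params(**overrides) -> dict:
    """Estimator parameters for CPU-scale experiments: a narrow network
    (32 / 32-64-128 / 64-32) and 10 local + 30 global context streamlines;
    the training protocol (20 epochs, Adam, lr 0.001, cross-entropy) is
    unchanged from the reference defaults."""
    params = dict(
        n_points=15,
        n_local=10,
        n_global=30,
        repr_width=32,
        backbone_widths=(32, 64, 128),
        head_widths=(64, 32),
        dropout=0.3,
        epochs=20,
        lr=1e-3,
        batch_size=128,
    )
    params.update(overrides)
    return params


def separable_two_bundle_tractogram(
    seed: int = 0, n_per_bundle: int = 250
) -> LabeledTractogram:
    """Two well-separated straight bundles (40 mm apart, 2 mm spread),
    zero cutting — a sanity benchmark any working classifier must solve."""
    bundles = [
        BundleSpec("bundle_a", np.array([(0.0, 0.0, 0.0), (0.0, 0.0, 60.0)]),
                   n_per_bundle, radial_sd=2.0, along_jitter=0.5),
        BundleSpec("bundle_b", np.array([(40.0, 0.0, 0.0), (40.0, 0.0, 60.0)]),
                   n_per_bundle, radial_sd=2.0, along_jitter=0.5),
    ]
    cfg = CohortConfig(n_subjects=1, bundles=bundles, n_outliers=0, seed=seed)
    return generate_subject(cfg, 0)


def fovca_benefit_experiment(
    seed: int = 0,
    n_train_subjects: int = 2,
    n_streamlines_per_bundle: int = 40,
    n_outliers: int = 20,
    n_planes: int = 4,
    **model_overrides,
) -> dict:
    """Train with and without FOV-cut augmentation; score on a cut subject.

    A held-out subject is synthetically cut with one plane (the evaluation
    protocol for truncation robustness); both models classify the
    surviving streamlines, and accuracy is reported separately for
    streamlines the plane cut and those it left unaffected, plus on the
    original complete tractogram.
    """
    cohort_cfg = CohortConfig(
        n_subjects=n_train_subjects + 1,
        bundles=default_bundle_specs(n_streamlines_per_bundle),
        n_outliers=n_outliers,
        seed=seed,
    )
    subjects = [generate_subject(cohort_cfg, i) for i in range(cohort_cfg.n_subjects)]
    train_subjects, test_subject = subjects[:-1], subjects[-1]

    aug = augment_cohort(
        train_subjects, FovcaConfig(n_planes_per_subject=n_planes, seed=seed + 1)
    )
    params = desk_model_params(**model_overrides)
    plain = TractographyParcellator(random_state=seed, **params).fit(train_subjects)
    fovca_model = TractographyParcellator(random_state=seed, **params).fit(aug)

    test_variant = augment_cohort(
        [test_subject], FovcaConfig(n_planes_per_subject=1, seed=seed + 2)
    )[1]
    cut_t = test_variant.tractogram
    statuses = np.array(
        [o.status for o in test_variant.outcomes if o.status != REMOVED]
    )
    truth = cut_t.labels
    result: dict = {
        "seed": seed,
        "n_train_streamlines_plain": sum(len(t) for t in train_subjects),
        "n_train_streamlines_fovca": sum(len(v.tractogram) for v in aug),
        "test_n_cut": int((statuses == CUT).sum()),
        "test_n_unaffected": int((statuses == UNAFFECTED).sum()),
    }
    for name, est in (("plain", plain), ("fovca", fovca_model)):
        pred = est.predict(cut_t)
        result[f"{name}_acc_cut"] = float((pred == truth)[statuses == CUT].mean())
        result[f"{name}_acc_unaffected"] = float(
            (pred == truth)[statuses == UNAFFECTED].mean()
        )
        result[f"{name}_acc_original"] = float(
            (est.predict(test_subject) == test_subject.labels).mean()
        )
    return result
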