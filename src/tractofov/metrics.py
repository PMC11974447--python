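"""Parcellation evaluation: accuracy, macro-F1, TIR and ATD.

Two families of metrics are provided.  With ground-truth labels available
(synthetically cut data), streamline *accuracy* is measured over all
classes and *macro-F1* is the unweighted mean of per-class F1 over the
tract classes only ("other" excluded by the caller).  Without ground truth
(real clinical data), parcellation quality is judged by the *Tract
Identification Rate* — the fraction of expected tracts with at least 20
assigned streamlines, averaged over subjects — and the *Atlas-to-Tract
Distance* — the mean closest-point distance (mm) from an identified
tract's points to the corresponding atlas tract, averaged over subjects
and tracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import f1_score

from .tractogram import LabeledTractogram, resample_streamline

__all__ = [
    "EvalReport",
    "streamline_accuracy",
    "per_class_f1",
    "macro_f1",
    "tract_identification_rate",
    "cohort_tir",
    "atlas_to_tract_distance",
    "cohort_atd",
    "stratified_report",
]


@dataclass
class EvalReport:
    """Container for the evaluation layer's outputs; fractions in [0, 1],
    distances in mm."""

    accuracy: float | None = None
    macro_f1: float | None = None
    per_class_f1: dict = field(default_factory=dict)
    tir: float | None = None
    atd_mm: float | None = None
    per_tract_atd: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_f1": {str(k): v for k, v in self.per_class_f1.items()},
            "tir": self.tir,
            "atd_mm": self.atd_mm,
            "per_tract_atd": {str(k): v for k, v in self.per_tract_atd.items()},
            "n": self.n,
        }
        if self.strata:
            out["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return out


def _check_aligned(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred/truth length mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def streamline_accuracy(pred, truth) -> float:
    """Overall fraction of correctly classified streamlines, all classes
    (including "other") counted."""
    pred, truth = _check_aligned(pred, truth)
    if len(pred) == 0:
        raise ValueError("empty label arrays")
    return float((pred == truth).mean())


def per_class_f1(pred, truth, classes) -> dict:
    """F1 per class over the given class subset.

    A class absent from both predictions and truth scores 0 so that
    missing expected tracts penalize the macro mean.
    """
    pred, truth = _check_aligned(pred, truth)
    classes = list(classes)
    if not classes:
        raise ValueError("empty class subset")
    scores = f1_score(truth, pred, labels=classes, average=None, zero_division=0.0)
    return {c: float(s) for c, s in zip(classes, scores)}


def macro_f1(pred, truth, tract_classes) -> float:
    """Unweighted mean of per-class F1 over the tract classes.

    The caller controls the subset; for the 74-class atlas scheme this is
    the 73 named tracts, with the "other" class excluded.
    """
    return float(np.mean(list(per_class_f1(pred, truth, tract_classes).values())))


def tract_identification_rate(
    parcellation: dict, expected_tracts, min_streamlines: int = 20
) -> float:
    """Fraction of expected tracts identified in one subject.

    A tract counts as identified when the parcellation assigns it at least
    ``min_streamlines`` streamlines (default 20).
    """
    expected = list(expected_tracts)
    if not expected:
        raise ValueError("expected_tracts must be non-empty")
    hit = sum(len(parcellation.get(tr, ())) >= min_streamlines for tr in expected)
    return hit / len(expected)


def cohort_tir(parcellations, expected_tracts, min_streamlines: int = 20) -> float:
    """TIR averaged across subjects."""
    rates = [
        tract_identification_rate(p, expected_tracts, min_streamlines)
        for p in parcellations
    ]
    return float(np.mean(rates))


def atlas_to_tract_distance(
    subject_tract,
    atlas_tract,
    n_points: int = 15,
    direction: str = "subject_to_atlas",
) -> float:
    """Mean closest-point distance (mm) between an identified tract and
    its atlas counterpart, after resampling every streamline to
    ``n_points``.

    ``direction`` is ``subject_to_atlas`` (default: mean over subject
    points of the distance to the nearest atlas point — not symmetric) or
    ``symmetric`` (mean of both directions).  An empty identified tract
    returns NaN ("not identified"); cohort averaging skips it.
    """
    atlas_tract = list(atlas_tract)
    if not atlas_tract:
        raise ValueError("atlas tract is empty")
    subject_tract = list(subject_tract)
    if not subject_tract:
        warnings.warn("empty identified tract: ATD undefined, returning NaN")
        return float("nan")
    sub = np.concatenate([resample_streamline(s, n_points) for s in subject_tract])
    atl = np.concatenate([resample_streamline(s, n_points) for s in atlas_tract])
    d_sa = cKDTree(atl).query(sub)[0].mean()
    if direction == "subject_to_atlas":
        return float(d_sa)
    if direction == "symmetric":
        d_as = cKDTree(sub).query(atl)[0].mean()
        return float((d_sa + d_as) / 2.0)
    raise ValueError(f"unknown direction {direction!r}")


def cohort_atd(
    subject_parcellations: list[dict],
    atlas: dict,
    tracts,
    n_points: int = 15,
    direction: str = "subject_to_atlas",
) -> tuple[float, dict]:
    """ATD averaged across subjects and tracts.

    ``subject_parcellations`` maps tract name -> list of streamlines per
    subject; ``atlas`` maps tract name -> atlas streamlines.  Returns the
    cohort mean and a per-tract mean dict; unidentified (empty) tracts are
    excluded from the means.
    """
    per_tract: dict = {}
    for tr in tracts:
        vals = []
        for parc in subject_parcellations:
            sub = parc.get(tr, [])
            if not len(sub):
                continue
            vals.append(atlas_to_tract_distance(sub, atlas[tr], n_points, direction))
        if vals:
            per_tract[tr] = float(np.mean(vals))
    if not per_tract:
        return float("nan"), per_tract
    return float(np.mean(list(per_tract.values()))), per_tract


def stratified_report(
    pred, truth, strata=None, tract_classes=None
) -> EvalReport:
    """Whole-set accuracy/macro-F1 plus one sub-report per stratum.

    ``strata`` is either a per-streamline tag sequence (e.g. the
    cut/unaffected status from augmentation, or a severity tag) or a
    mapping of stratum name to streamline indices; empty strata are
    omitted with a warning.  Tag-style stratum sizes sum to the total, so
    the overall accuracy is the size-weighted mean of stratum accuracies.
    """
    pred, truth = _check_aligned(pred, truth)
    if tract_classes is None:
        tract_classes = sorted(np.unique(truth).tolist())
    report = EvalReport(
        accuracy=streamline_accuracy(pred, truth),
        macro_f1=macro_f1(pred, truth, tract_classes),
        per_class_f1=per_class_f1(pred, truth, tract_classes),
        n=len(pred),
    )
    if strata is None:
        return report
    if isinstance(strata, dict):
        groups = {str(k): np.asarray(v, dtype=int) for k, v in strata.items()}
        if any(len(idx) and idx.max() >= len(pred) for idx in groups.values()):
            raise ValueError("strata indices out of range")
    else:
        strata = np.asarray(strata)
        if len(strata) != len(pred):
            raise ValueError("strata misaligned with labels")
        groups = {
            str(tag): np.flatnonzero(strata == tag)
            for tag in dict.fromkeys(strata.tolist())  # first-seen order
        }
    for tag, idx in groups.items():
        if len(idx) == 0:
            warnings.warn(f"empty stratum {tag!r} omitted")
            continue
        report.strata[tag] = EvalReport(
            accuracy=streamline_accuracy(pred[idx], truth[idx]),
            macro_f1=macro_f1(pred[idx], truth[idx], tract_classes),
            per_class_f1=per_class_f1(pred[idx], truth[idx], tract_classes),
            n=len(idx),
        )
    return report
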