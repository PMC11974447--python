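"""FOV-Cut Augmentation: synthetic inferior field-of-view truncation.

Clinical diffusion scans often miss inferior slices, so streamlines through
the brainstem/cerebellum arrive truncated.  This module emulates that
artifact on complete tractograms: it samples random cutting planes
constrained to lie 30-50 mm below the brain center with a tilt of at most
30 degrees to the horizontal, removes everything below each plane, and
tracks per-streamline outcomes (``unaffected`` / ``cut`` / ``removed``).
Applying several planes per subject (default 10, plus the untouched
original) multiplies the labeled training set while preserving every
streamline's tract identity — the training signal for truncation-robust
classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tractogram import LabeledTractogram, as_streamline, brain_center

__all__ = [
    "CutPlane",
    "CutOutcome",
    "FovcaConfig",
    "AugmentedVariant",
    "sample_cut_plane",
    "cut_streamline",
    "cut_tractogram",
    "augment_cohort",
    "pre_removal_count",
    "fraction_cut",
]

UNAFFECTED = "unaffected"
CUT = "cut"
REMOVED = "removed"


@dataclass(frozen=True)
class CutPlane:
    """A cutting plane: tilt (theta, degrees, to the horizontal), tilt
    azimuth (phi, degrees), and depth (mm below the brain center along -z).

    The kept half-space is the closed superior side: a point ``p`` survives
    iff ``normal . (p - anchor) >= 0``.  The normal always points superior
    (positive z component) for tilts under 90 degrees.
    """

    theta: float
    phi: float
    depth: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def normal(self) -> np.ndarray:
        th, ph = math.radians(self.theta), math.radians(self.phi)
        return np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
        )

    @property
    def anchor(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float) + np.array([0.0, 0.0, -self.depth])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.anchor) @ self.normal


@dataclass
class FovcaConfig:
    """Constraints and bookkeeping for plane sampling and cutting."""

    theta_max: float = 30.0
    depth_range: tuple[float, float] = (30.0, 50.0)
    n_planes_per_subject: int = 10
    min_retained_points: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if not (0 <= self.theta_max < 90):
            # theta_max = 0 is the exactly-horizontal-plane limit
            raise ValueError("theta_max must lie in [0, 90) degrees")
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be ordered and positive")
        if self.n_planes_per_subject < 0 or self.min_retained_points < 2:
            raise ValueError("invalid augmentation config")


@dataclass
class CutOutcome:
    """What one cutting plane did to one streamline."""

    status: str
    retained: np.ndarray | None
    original_index: int
    label: int | None = None


def sample_cut_plane(
    center, cfg: FovcaConfig, rng: np.random.Generator
) -> CutPlane:
    """Draw a random constrained plane: theta ~ U[0, theta_max],
    phi ~ U[0, 360), depth ~ U[depth_range]."""
    theta = rng.uniform(0.0, cfg.theta_max)
    phi = rng.uniform(0.0, 360.0)
    depth = rng.uniform(*cfg.depth_range)
    return CutPlane(theta=theta, phi=phi, depth=depth, center=np.asarray(center, float))


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest contiguous True run; earliest on ties."""
    best_start, best_len = 0, 0
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(mask) - start > best_len:
        best_start, best_len = start, len(mask) - start
    return best_start, best_len


def cut_streamline(
    s: np.ndarray,
    plane: CutPlane,
    min_retained_points: int = 2,
    original_index: int = 0,
    label: int | None = None,
) -> CutOutcome:
    """Truncate one streamline at the plane.

    Points exactly on the plane are kept (closed half-space).  A streamline
    crossing the plane more than once keeps only its longest contiguous
    kept run (earliest on ties): a truncated acquisition cannot produce a
    streamline spanning the missing region.  Fewer than
    ``min_retained_points`` surviving points means the streamline is
    removed entirely.
    """
    pts = as_streamline(s)
    kept = plane.signed_distance(pts) >= 0.0
    if kept.all():
        return CutOutcome(UNAFFECTED, pts, original_index, label)
    start, length = _longest_true_run(kept)
    if length < min_retained_points:
        return CutOutcome(REMOVED, None, original_index, label)
    return CutOutcome(CUT, pts[start : start + length], original_index, label)


def cut_tractogram(
    t: LabeledTractogram, plane: CutPlane, cfg: FovcaConfig | None = None
) -> tuple[LabeledTractogram, list[CutOutcome]]:
    """Apply one plane to a whole tractogram.

    Returns the surviving tractogram (unaffected + cut streamlines, input
    order and labels preserved) and one outcome per input streamline.
    """
    if len(t) == 0:
        raise ValueError("cannot cut an empty tractogram")
    min_pts = (cfg or FovcaConfig()).min_retained_points
    outcomes = []
    for i, s in enumerate(t.streamlines):
        lab = int(t.labels[i]) if t.labels is not None else None
        outcomes.append(cut_streamline(s, plane, min_pts, i, lab))
    survivors = [o for o in outcomes if o.status != REMOVED]
    new_labels = (
        np.array([o.label for o in survivors], dtype=int) if t.labels is not None else None
    )
    out = t.with_streamlines([o.retained for o in survivors], new_labels)
    return out, outcomes


@dataclass
class AugmentedVariant:
    """One training tractogram variant plus its cutting provenance."""

    subject_id: str
    variant: str  # "orig" or "cut01".."cutNN"
    tractogram: LabeledTractogram
    provenance: dict
    outcomes: list[CutOutcome] | None = None


def outcome_counts(outcomes: list[CutOutcome]) -> dict:
    return {
        "n_unaffected": sum(o.status == UNAFFECTED for o in outcomes),
        "n_cut": sum(o.status == CUT for o in outcomes),
        "n_removed": sum(o.status == REMOVED for o in outcomes),
    }


def fraction_cut(outcomes: list[CutOutcome]) -> float:
    """Fraction of streamlines touched by the plane (cut or removed)."""
    if not outcomes:
        return 0.0
    return sum(o.status != UNAFFECTED for o in outcomes) / len(outcomes)


def augment_cohort(
    cohort: list[LabeledTractogram], cfg: FovcaConfig
) -> list[AugmentedVariant]:
    """Original + ``n_planes_per_subject`` cut variants for every subject.

    Pre-removal the augmented set holds ``n_streamlines x (n_planes + 1)``
    labeled streamlines per subject; removed streamlines then drop out.
    Plane draws are reproducible from ``cfg.seed`` with an independent
    sub-stream per subject.
    """
    variants: list[AugmentedVariant] = []
    for si, t in enumerate(cohort):
        variants.append(
            AugmentedVariant(
                t.subject_id, "orig", t,
                {"subject": t.subject_id, "plane": None,
                 "n_unaffected": len(t), "n_cut": 0, "n_removed": 0},
            )
        )
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(si,)))
        center = brain_center(t)
        for pi in range(cfg.n_planes_per_subject):
            plane = sample_cut_plane(center, cfg, rng)
            cut_t, outcomes = cut_tractogram(t, plane, cfg)
            prov = {
                "subject": t.subject_id,
                "plane": {"theta": plane.theta, "phi": plane.phi, "depth": plane.depth},
                **outcome_counts(outcomes),
            }
            variants.append(
                AugmentedVariant(t.subject_id, f"cut{pi + 1:02d}", cut_t, prov, outcomes)
            )
    return variants


def pre_removal_count(
    n_subjects: int, n_streamlines_per_subject: int, n_planes_per_subject: int
) -> int:
    """Labeled-streamline count of the augmented set before removal:
    every subject contributes its tractogram once per plane plus the
    original."""
    return n_subjects * n_streamlines_per_subject * (n_planes_per_subject + 1)
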