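"""Seeded generator of labeled whole-brain-like tractograms.

The generator emulates the structure a parcellation model sees in a real
whole-brain tractogram: several smooth bundles (each a noisy tube around a
controlled centerline, some of which descend into the inferior zone that
field-of-view truncation removes) plus a class of rough "other" outlier
streamlines.  It makes no attempt at anatomical realism of the 73 real
atlas tracts — bundle count, geometry and noise are configurable, and every
draw is fully determined by the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tractogram import LabeledTractogram, as_streamline, resample_streamline

__all__ = [
    "BundleSpec",
    "CohortConfig",
    "default_bundle_specs",
    "generate_bundle",
    "generate_subject",
    "generate_cohort",
]


@dataclass
class BundleSpec:
    """One synthetic bundle: a centerline plus Gaussian dispersion.

    ``radial_sd`` is the standard deviation (mm, per perpendicular axis) of
    the constant offset each streamline keeps from the centerline;
    ``along_jitter`` is the per-point isotropic positional noise (mm).
    ``inferior`` flags bundles that descend below z = -30 mm of the brain
    center and are therefore exposed to synthetic FOV cutting.
    """

    name: str
    centerline: np.ndarray
    n_streamlines: int = 100
    radial_sd: float = 2.0
    along_jitter: float = 0.5
    inferior: bool = False

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 control points")
        if self.n_streamlines < 1 or self.radial_sd < 0 or self.along_jitter < 0:
            raise ValueError("invalid bundle spec")


def default_bundle_specs(n_streamlines: int = 100) -> list[BundleSpec]:
    """Six bundles spanning a head-sized volume, three of them inferior.

    Two corticospinal-like near-vertical bundles descend from the vertex to
    z ~ -78 mm, and a cerebellar-like arc sits entirely in the inferior
    zone, so that cut planes 30-50 mm below the brain center always find
    streamlines to truncate; the remaining three bundles (callosal arch,
    arcuate-like arc, longitudinal fasciculus-like) stay superior.
    """
    mk = lambda pts: np.array(pts, dtype=float)
    return [
        BundleSpec("cst_left", mk([(-25, -10, 60), (-22, -12, 20), (-18, -14, -20),
                                   (-14, -14, -55), (-12, -12, -78)]),
                   n_streamlines, inferior=True),
        BundleSpec("cst_right", mk([(25, -10, 60), (22, -12, 20), (18, -14, -20),
                                    (14, -14, -55), (12, -12, -78)]),
                   n_streamlines, inferior=True),
        BundleSpec("cerebellar_arc", mk([(-30, -45, -45), (-15, -60, -60), (0, -65, -68),
                                         (15, -60, -60), (30, -45, -45)]),
                   n_streamlines, inferior=True),
        BundleSpec("callosal_arch", mk([(-45, 10, 25), (-25, 15, 50), (0, 18, 60),
                                        (25, 15, 50), (45, 10, 25)]),
                   n_streamlines),
        BundleSpec("arcuate_left", mk([(-40, 30, 20), (-48, 5, 35), (-45, -25, 30),
                                       (-38, -40, 5)]),
                   n_streamlines),
        BundleSpec("ilf_right", mk([(35, 55, 0), (40, 20, -8), (42, -15, -12),
                                    (38, -50, -5)]),
                   n_streamlines),
    ]


@dataclass
class CohortConfig:
    """Cohort of labeled synthetic subjects; the seed fully determines output."""

    n_subjects: int = 10
    bundles: list[BundleSpec] = field(default_factory=default_bundle_specs)
    n_outliers: int = 50
    seed: int = 0
    points_per_streamline: int = 25

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_outliers < 0:
            raise ValueError("invalid cohort config")
        if not self.bundles:
            raise ValueError("cohort needs at least one bundle")

    @property
    def class_names(self) -> list[str]:
        return [b.name for b in self.bundles] + ["other"]

    @property
    def n_classes(self) -> int:
        return len(self.bundles) + 1

    @property
    def streamlines_per_subject(self) -> int:
        return sum(b.n_streamlines for b in self.bundles) + self.n_outliers


def _perp_basis(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal pair spanning the plane perpendicular to the bundle axis."""
    centered = centerline - centerline.mean(axis=0)
    # dominant direction via PCA; robust to closed/curved centerlines
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def generate_bundle(
    spec: BundleSpec, rng: np.random.Generator, n_points: int = 25
) -> list[np.ndarray]:
    """Draw ``spec.n_streamlines`` noisy copies of the centerline.

    Each streamline is the arc-length-resampled centerline shifted by a
    constant random offset in the perpendicular plane (per-axis Gaussian,
    sd = ``radial_sd``) plus per-point isotropic jitter.  With zero noise
    every streamline equals the resampled centerline exactly.
    """
    center = resample_streamline(as_streamline(spec.centerline), n_points)
    u, v = _perp_basis(center)
    out = []
    for _ in range(spec.n_streamlines):
        a, b = rng.normal(0.0, spec.radial_sd, size=2) if spec.radial_sd > 0 else (0.0, 0.0)
        offset = a * u + b * v
        pts = center + offset
        if spec.along_jitter > 0:
            pts = pts + rng.normal(0.0, spec.along_jitter, size=pts.shape)
        out.append(pts)
    return out


def _generate_outliers(
    n: int, rng: np.random.Generator, bbox_lo: np.ndarray, bbox_hi: np.ndarray,
    n_points: int, step_sd: float = 6.0,
) -> list[np.ndarray]:
    """Rough random-walk streamlines filling the brain bounding box."""
    out = []
    for _ in range(n):
        start = rng.uniform(bbox_lo, bbox_hi)
        steps = rng.normal(0.0, step_sd, size=(n_points - 1, 3))
        pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
        out.append(pts)
    return out


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # distinct, reproducible sub-stream per subject
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def generate_subject(cfg: CohortConfig, subject_index: int) -> LabeledTractogram:
    """One labeled subject: all bundles (label = bundle index) plus outliers.

    The "other" outlier class gets the last label id.  Geometry differs
    across subject indices through per-subject seed sub-streams.
    """
    rng = _subject_rng(cfg.seed, subject_index)
    streamlines: list[np.ndarray] = []
    labels: list[int] = []
    for i, spec in enumerate(cfg.bundles):
        sl = generate_bundle(spec, rng, cfg.points_per_streamline)
        streamlines.extend(sl)
        labels.extend([i] * len(sl))
    ctrl = np.vstack([b.centerline for b in cfg.bundles])
    lo, hi = ctrl.min(axis=0) - 10.0, ctrl.max(axis=0) + 10.0
    outliers = _generate_outliers(cfg.n_outliers, rng, lo, hi, cfg.points_per_streamline)
    streamlines.extend(outliers)
    labels.extend([len(cfg.bundles)] * len(outliers))
    return LabeledTractogram(
        streamlines=streamlines,
        labels=np.asarray(labels, dtype=int),
        class_names=cfg.class_names,
        subject_id=f"sub-{subject_index:03d}",
    )


def generate_cohort(cfg: CohortConfig) -> list[LabeledTractogram]:
    """All subjects of the cohort, reproducible from ``cfg.seed``."""
    return [generate_subject(cfg, i) for i in range(cfg.n_subjects)]
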