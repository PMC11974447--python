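"""Core streamline and tractogram data model.

A *streamline* is an ordered polyline of 3-D points in millimetres tracing
one reconstructed white-matter fiber trajectory; a *tractogram* is the set
of all streamlines of one subject, optionally carrying a per-streamline
integer tract label.  All geometry lives in a RAS-like mm space where the
superior direction is +z ("below" means decreasing z); this convention is
captured by :class:`SpaceConvention` and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpaceConvention",
    "LabeledTractogram",
    "as_streamline",
    "resample_streamline",
    "arc_lengths",
    "brain_center",
]


@dataclass(frozen=True)
class SpaceConvention:
    """Orientation convention for a tractogram: which way is superior, in mm."""

    axis_superior: tuple[float, float, float] = (0.0, 0.0, 1.0)
    units: str = "mm"

    def __post_init__(self) -> None:
        v = np.asarray(self.axis_superior, dtype=float)
        if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0):
            raise ValueError("axis_superior must be a 3-D unit vector")


def as_streamline(points: Iterable) -> np.ndarray:
    """Validate and return a streamline as a float (n, 3) array.

    Raises ``ValueError`` for fewer than 2 points, wrong dimensionality or
    non-finite coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be an (n, 3) array, got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    return pts


@dataclass
class LabeledTractogram:
    """A subject's streamlines with optional per-streamline tract labels.

    ``labels[i]`` is an integer index into ``class_names``; the real atlas
    scheme has 74 entries (73 named tracts plus one "other" class for
    anatomically implausible streamlines), but any scheme size works.
    """

    streamlines: list[np.ndarray]
    labels: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)
    subject_id: str = ""
    space: SpaceConvention = field(default_factory=SpaceConvention)

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.streamlines):
                raise ValueError(
                    f"{len(self.labels)} labels for {len(self.streamlines)} streamlines"
                )
            if self.class_names and len(self.labels) and (
                self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
            ):
                raise ValueError("labels outside [0, n_classes)")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def n_points_total(self) -> int:
        return sum(len(s) for s in self.streamlines)

    def concatenated_points(self) -> np.ndarray:
        if not self.streamlines:
            return np.empty((0, 3))
        return np.concatenate(self.streamlines, axis=0)

    def resampled_array(self, n_points: int) -> np.ndarray:
        """All streamlines resampled to a common point count, as (n, n_points, 3)."""
        return np.stack([resample_streamline(s, n_points) for s in self.streamlines])

    def with_streamlines(
        self, streamlines: Sequence[np.ndarray], labels: np.ndarray | None
    ) -> "LabeledTractogram":
        return replace(self, streamlines=list(streamlines), labels=labels)


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each point of a polyline; starts at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(s: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a streamline to ``n_points`` equally spaced in arc length.

    Endpoints are preserved exactly.  A zero-length (degenerate) streamline
    raises ``ValueError``.
    """
    pts = as_streamline(s)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = arc_lengths(pts)
    total = t[-1]
    if total <= 0.0:
        raise ValueError("cannot resample a zero-length streamline")
    targets = np.linspace(0.0, total, n_points)
    out = np.column_stack([np.interp(targets, t, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def brain_center(t: LabeledTractogram) -> np.ndarray:
    """Unweighted centroid of every point of every streamline.

    Used as the reference for cut-plane depths ("N mm below the center of
    the brain"); deterministic and atlas-free.
    """
    if len(t) == 0:
        raise ValueError("cannot compute the center of an empty tractogram")
    return t.concatenated_points().mean(axis=0)
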