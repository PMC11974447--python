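"""Local-global streamline context construction.

Each streamline (the *anchor*) is classified together with context drawn
from its own — possibly truncated — tractogram: its k nearest neighbor
streamlines under the minimum average direct-flip (MDF) distance, plus a
random sample of whole-brain streamlines.  The context enters the network
as a block of per-point 6-D pairings ``[anchor_point, context_point]``
whose first row pairs the anchor with itself.  Because the context comes
from the same tractogram variant as the anchor, cutting a tractogram
changes the representation even of streamlines the plane never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tractogram import LabeledTractogram

__all__ = [
    "ContextConfig",
    "mdf_distance",
    "mdf_to_all",
    "knn_indices",
    "nearest_neighbors",
    "sample_global",
    "build_context_feature",
    "assemble_blocks",
]


@dataclass
class ContextConfig:
    """Context sizes: 20 local + 500 global streamlines by default, with
    streamlines resampled to ``n_points`` points."""

    n_local: int = 20
    n_global: int = 500
    n_points: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_local < 0 or self.n_global < 0 or self.n_points < 2:
            raise ValueError("invalid context config")

    @property
    def n_context(self) -> int:
        return 1 + self.n_local + self.n_global


def mdf_distance(a, b, n_points: int = 15) -> float:
    """Minimum average direct-flip distance between two streamlines (mm).

    Both streamlines are arc-length resampled to ``n_points``; the distance
    is the mean pointwise Euclidean distance, minimized over reversing one
    streamline.  Symmetric, non-negative and flip-invariant; the triangle
    inequality is not guaranteed.
    """
    from .tractogram import resample_streamline

    pa = resample_streamline(np.asarray(a, float), n_points)
    pb = resample_streamline(np.asarray(b, float), n_points)
    direct = np.linalg.norm(pa - pb, axis=1).mean()
    flipped = np.linalg.norm(pa - pb[::-1], axis=1).mean()
    return float(min(direct, flipped))


def mdf_to_all(X: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """MDF distances from one resampled anchor (P, 3) to all rows of a
    resampled streamline array X (n, P, 3)."""
    direct = np.linalg.norm(X - anchor[None], axis=2).mean(axis=1)
    flipped = np.linalg.norm(X - anchor[None, ::-1], axis=2).mean(axis=1)
    return np.minimum(direct, flipped)


def knn_indices(X: np.ndarray, k: int, chunk: int = 64) -> np.ndarray:
    """Exact k-nearest-neighbor table (n, k) under MDF for all streamlines.

    Chunked exhaustive pairwise evaluation — memory-bounded and fully
    deterministic (ties broken by lower index via stable argsort); no
    approximate index.
    """
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_streamlines={n}")
    out = np.empty((n, k), dtype=int)
    Xf = X[:, ::-1]
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        A = X[lo:hi]
        direct = np.linalg.norm(A[:, None] - X[None], axis=3).mean(axis=2)
        flipped = np.linalg.norm(A[:, None] - Xf[None], axis=3).mean(axis=2)
        d = np.minimum(direct, flipped)
        d[np.arange(hi - lo), np.arange(lo, hi)] = np.inf  # exclude self
        out[lo:hi] = np.argsort(d, axis=1, kind="stable")[:, :k]
    return out


def nearest_neighbors(
    t: LabeledTractogram, anchor_index: int, k: int, n_points: int = 15
) -> list[int]:
    """Indices of the k MDF-nearest streamlines to the anchor (anchor
    excluded, ties to the lower index)."""
    if k >= len(t):
        raise ValueError(f"k={k} must be < n_streamlines={len(t)}")
    if k == 0:
        return []
    X = t.resampled_array(n_points)
    d = mdf_to_all(X, X[anchor_index])
    d[anchor_index] = np.inf
    return list(np.argsort(d, kind="stable")[:k])


def sample_global(
    t_or_n, n_global: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random sample of streamline indices for global context.

    Sampling is without replacement when the tractogram has at least
    ``n_global`` streamlines, with replacement otherwise.
    """
    n = t_or_n if isinstance(t_or_n, (int, np.integer)) else len(t_or_n)
    if n == 0:
        raise ValueError("cannot sample from an empty tractogram")
    return rng.choice(n, size=n_global, replace=n_global > n)


def assemble_blocks(
    X: np.ndarray, anchor_idx: np.ndarray, context_idx: np.ndarray
) -> np.ndarray:
    """Pairwise feature blocks (B, C, P, 6) from a resampled array.

    ``context_idx[b]`` lists the C context streamlines of anchor
    ``anchor_idx[b]``; each output point is the concatenation
    ``[anchor_point, context_point]``.
    """
    anchors = X[anchor_idx]  # (B, P, 3)
    ctx = X[context_idx]  # (B, C, P, 3)
    B, C = context_idx.shape
    tiled = np.broadcast_to(anchors[:, None], (B, C) + anchors.shape[1:])
    return np.concatenate([tiled, ctx], axis=-1)


def build_context_feature(
    t: LabeledTractogram,
    anchor_index: int,
    cfg: ContextConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full context block (1 + n_local + n_global, n_points, 6) for one
    anchor: the anchor self-pair row first, then its nearest neighbors,
    then the random global sample (drawn from ``rng``, or a generator
    seeded with ``cfg.seed``)."""
    if len(t) <= cfg.n_local:
        raise ValueError(
            f"need more than n_local={cfg.n_local} streamlines, got {len(t)}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X = t.resampled_array(cfg.n_points)
    local = nearest_neighbors(t, anchor_index, cfg.n_local, cfg.n_points)
    glob = sample_global(t, cfg.n_global, rng) if cfg.n_global else np.empty(0, int)
    ctx_idx = np.concatenate([[anchor_index], local, glob]).astype(int)
    return assemble_blocks(X, np.array([anchor_index]), ctx_idx[None])[0]
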