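"""End-to-end tractography parcellation estimator.

:class:`TractographyParcellator` is a scikit-learn-style estimator that
classifies every streamline of a tractogram into a tract class.  It trains
the local-global point network end to end on a set of tractogram variants
(typically the originals plus their FOV-cut augmentations), building each
streamline's context from the same variant it belongs to, so truncation
changes the training signal even for streamlines the cut never touched.

Training defaults follow the reference protocol: 20 epochs, Adam with
learning rate 0.001, batch size 1024, cross-entropy loss, 20 local and 500
global context streamlines.  Global context is redrawn every epoch during
training and frozen (one shared sample per tractogram, derived from
``inference_seed``) at prediction time, which makes prediction a pure
function of the model weights and the input tractogram.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .context import assemble_blocks, knn_indices, sample_global
from .fovca import AugmentedVariant
from .nn import Adam, LocalGlobalPointNet, cross_entropy_grad, softmax
from .tractogram import LabeledTractogram

__all__ = [
    "TractographyParcellator",
    "TrainingError",
    "train_parcellator",
    "predict_tractogram",
    "group_parcellation",
    "save_model",
    "load_model",
]


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


def _as_variant_list(data) -> list[LabeledTractogram]:
    if isinstance(data, LabeledTractogram):
        return [data]
    out = []
    for item in data:
        if isinstance(item, AugmentedVariant):
            out.append(item.tractogram)
        elif isinstance(item, LabeledTractogram):
            out.append(item)
        else:
            raise TypeError(f"cannot interpret {type(item)} as a training tractogram")
    return out


class TractographyParcellator(BaseEstimator, ClassifierMixin):
    """Streamline classifier with a learned local-global representation.

    Parameters
    ----------
    n_points : points per streamline after arc-length resampling.
    n_local, n_global : context sizes (nearest neighbors / random
        whole-brain sample).
    repr_width, backbone_widths, head_widths, dropout : network shape.
    epochs, lr, batch_size : optimization protocol (Adam, cross-entropy).
    random_state : seed controlling initialization, shuffling, dropout and
        per-epoch global sampling.
    inference_seed : seed of the frozen global sample used by ``predict``.

    Fitted attributes (trailing underscore): ``net_``, ``classes_``,
    ``class_names_``, ``history_``.
    """

    def __init__(
        self,
        n_points: int = 15,
        n_local: int = 20,
        n_global: int = 500,
        repr_width: int = 64,
        backbone_widths: tuple[int, ...] = (64, 128, 1024),
        head_widths: tuple[int, ...] = (512, 256),
        dropout: float = 0.3,
        epochs: int = 20,
        lr: float = 1e-3,
        batch_size: int = 1024,
        random_state: int = 0,
        inference_seed: int = 0,
    ):
        self.n_points = n_points
        self.n_local = n_local
        self.n_global = n_global
        self.repr_width = repr_width
        self.backbone_widths = backbone_widths
        self.head_widths = head_widths
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state
        self.inference_seed = inference_seed

    # ------------------------------------------------------------------
    def _prepare_variant(self, t: LabeledTractogram) -> dict:
        if t.labels is None:
            raise ValueError("training tractograms need labels")
        if len(t) <= self.n_local:
            raise ValueError(
                f"variant with {len(t)} streamlines cannot provide "
                f"n_local={self.n_local} neighbors"
            )
        X = t.resampled_array(self.n_points).astype(np.float32)
        return {
            "X": X,
            "knn": knn_indices(X, self.n_local) if self.n_local else
                   np.empty((len(t), 0), dtype=int),
            "y": np.asarray(t.labels, dtype=int),
            "n": len(t),
        }

    def fit(self, tractograms, y=None, validation=None):
        """Train on labeled tractogram variants (originals and/or cuts).

        ``tractograms`` may be a single :class:`LabeledTractogram`, a list
        of them, or a list of :class:`AugmentedVariant`.  ``validation``
        (same forms) adds a per-epoch validation accuracy to the history.
        """
        variants = [self._prepare_variant(t) for t in _as_variant_list(tractograms)]
        all_labels = np.concatenate([v["y"] for v in variants])
        classes = np.unique(all_labels)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        n_classes = int(all_labels.max()) + 1

        rng = np.random.default_rng(self.random_state)
        self.net_ = LocalGlobalPointNet(
            n_classes=n_classes,
            repr_width=self.repr_width,
            backbone_widths=tuple(self.backbone_widths),
            head_widths=tuple(self.head_widths),
            dropout=self.dropout,
            rng=rng,
        )
        opt = Adam(self.net_.params, lr=self.lr)
        self.classes_ = np.arange(n_classes)
        self.class_names_ = None
        for t in _as_variant_list(tractograms):
            if t.class_names:
                self.class_names_ = list(t.class_names)
                break

        n_total = sum(v["n"] for v in variants)
        batch_size = self.batch_size
        if batch_size > n_total:
            warnings.warn(
                f"batch_size {batch_size} exceeds the {n_total}-streamline "
                f"training set; reducing to {n_total}"
            )
            batch_size = n_total
        var_of = np.concatenate(
            [np.full(v["n"], i, dtype=int) for i, v in enumerate(variants)]
        )
        row_of = np.concatenate([np.arange(v["n"]) for v in variants])

        val_variants = (
            [self._prepare_variant(t) for t in _as_variant_list(validation)]
            if validation is not None else None
        )

        self.history_ = {"train_loss": [], "train_acc": [], "val_acc": []}
        for epoch in range(self.epochs):
            glob = [self._epoch_globals(v, rng) for v in variants]
            order = rng.permutation(n_total)
            losses, correct = [], 0
            for lo in range(0, n_total, batch_size):
                sel = order[lo : lo + batch_size]
                blocks, yb = self._gather(variants, glob, var_of[sel], row_of[sel])
                logits = self.net_.forward(blocks, training=True, rng=rng)
                loss, dlogits = cross_entropy_grad(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                grads = self.net_.backward(dlogits)
                opt.step(self.net_.params, grads)
                losses.append(loss * len(sel))
                correct += int((logits.argmax(axis=1) == yb).sum())
            self.history_["train_loss"].append(sum(losses) / n_total)
            self.history_["train_acc"].append(correct / n_total)
            if val_variants is not None:
                self.history_["val_acc"].append(self._eval_variants(val_variants))
        return self

    def _epoch_globals(self, v: dict, rng: np.random.Generator) -> np.ndarray:
        """Fresh per-anchor global sample, redrawn every epoch."""
        n, g = v["n"], self.n_global
        if g == 0:
            return np.empty((n, 0), dtype=int)
        if g > n:  # with replacement
            return rng.integers(0, n, size=(n, g))
        return np.argsort(rng.random((n, n)), axis=1, kind="stable")[:, :g]

    def _gather(self, variants, glob, var_sel, row_sel):
        blocks, ys = [], []
        for vi in np.unique(var_sel):
            rows = row_sel[var_sel == vi]
            v = variants[vi]
            ctx = np.concatenate([rows[:, None], v["knn"][rows], glob[vi][rows]], axis=1)
            blocks.append(assemble_blocks(v["X"], rows, ctx))
            ys.append(v["y"][rows])
        return np.concatenate(blocks), np.concatenate(ys)

    def _eval_variants(self, variants: list[dict]) -> float:
        correct = total = 0
        for v in variants:
            proba = self._variant_proba(v)
            correct += int((proba.argmax(axis=1) == v["y"]).sum())
            total += v["n"]
        return correct / total

    # ------------------------------------------------------------------
    def _variant_proba(self, v: dict, chunk: int = 256) -> np.ndarray:
        """Class probabilities for every streamline of a prepared variant.

        The global context is a single shared sample per tractogram drawn
        from ``inference_seed``, making prediction deterministic and
        identical for geometrically identical streamlines.
        """
        rng = np.random.default_rng(self.inference_seed)
        n = v["n"]
        shared = (
            sample_global(n, self.n_global, rng) if self.n_global
            else np.empty(0, dtype=int)
        )
        out = np.empty((n, self.net_.n_classes))
        for lo in range(0, n, chunk):
            rows = np.arange(lo, min(lo + chunk, n))
            ctx = np.concatenate(
                [rows[:, None], v["knn"][rows],
                 np.broadcast_to(shared, (len(rows), len(shared)))], axis=1
            )
            blocks = assemble_blocks(v["X"], rows, ctx)
            out[rows] = softmax(self.net_.forward(blocks, training=False))
        return out

    def predict_proba(self, t: LabeledTractogram) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise ValueError("estimator is not fitted")
        if len(t) <= self.n_local:
            raise ValueError(
                f"tractogram with {len(t)} streamlines cannot provide "
                f"n_local={self.n_local} neighbors"
            )
        X = t.resampled_array(self.n_points).astype(np.float32)
        v = {
            "X": X,
            "knn": knn_indices(X, self.n_local) if self.n_local
                   else np.empty((len(t), 0), dtype=int),
            "y": None,
            "n": len(t),
        }
        return self._variant_proba(v)

    def predict(self, t: LabeledTractogram) -> np.ndarray:
        """Per-streamline class labels for one tractogram."""
        return self.predict_proba(t).argmax(axis=1)

    def score(self, t: LabeledTractogram, y=None) -> float:
        truth = np.asarray(y if y is not None else t.labels)
        return float((self.predict(t) == truth).mean())


# ---------------------------------------------------------------------------
# functional wrappers

def train_parcellator(train_set, val_set=None, **params) -> TractographyParcellator:
    """Fit a :class:`TractographyParcellator` on tractogram variants."""
    est = TractographyParcellator(**params)
    return est.fit(train_set, validation=val_set)


def predict_tractogram(model: TractographyParcellator, t: LabeledTractogram):
    """Labels and class probabilities for every streamline of ``t``."""
    proba = model.predict_proba(t)
    return proba.argmax(axis=1), proba


def group_parcellation(labels, t: LabeledTractogram, class_names=None) -> dict:
    """Partition streamline indices by predicted class.

    Every class of the scheme gets a (possibly empty) group; the "other"
    class is retained as its own group.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(t):
        raise ValueError("labels misaligned with tractogram")
    names = class_names or t.class_names
    n_classes = max(len(names), int(labels.max()) + 1 if len(labels) else 0)
    if not names:
        names = [f"class_{i}" for i in range(n_classes)]
    elif len(names) < n_classes:
        names = list(names) + [f"class_{i}" for i in range(len(names), n_classes)]
    groups: dict[str, list[int]] = {name: [] for name in names}
    for i, lab in enumerate(labels):
        groups[names[lab]].append(i)
    return groups


# ---------------------------------------------------------------------------
# checkpointing

def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def save_model(model: TractographyParcellator, path) -> None:
    """Serialize weights plus a config echo (validated on load) to one file."""
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.get_params().items()}
    meta = {
        "config": cfg,
        "config_sha256": _config_digest(cfg),
        "n_classes": int(model.net_.n_classes),
        "class_names": model.class_names_,
        "history": model.history_,
    }
    arrays = {f"param::{k}": v for k, v in model.net_.params.items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_model(path) -> TractographyParcellator:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    cfg = meta["config"]
    if _config_digest(cfg) != meta["config_sha256"]:
        raise ValueError("checkpoint config hash mismatch")
    cfg = {k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.items()}
    model = TractographyParcellator(**cfg)
    model.net_ = LocalGlobalPointNet(
        n_classes=meta["n_classes"],
        repr_width=model.repr_width,
        backbone_widths=tuple(model.backbone_widths),
        head_widths=tuple(model.head_widths),
        dropout=model.dropout,
    )
    for k in model.net_.params:
        model.net_.params[k] = params[k]
    model.classes_ = np.arange(meta["n_classes"])
    model.class_names_ = meta["class_names"]
    model.history_ = meta["history"]
    return model
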