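"""A point-based streamline classifier in plain numpy.

Architecture: a local-global representation learning module (one shared
fully connected layer with ReLU applied to every 6-D paired point, followed
by max-pooling over the context streamlines) replaces the first layer of a
PointNet-style classifier: shared per-point layers, global max-pooling over
points, and a fully connected head with dropout and softmax.  No input
spatial transformer (T-Net) is used anywhere — absolute streamline position
is anatomically meaningful and must be preserved.

Forward, backward and the Adam optimizer are implemented directly on
float32 arrays; training is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LocalGlobalPointNet", "Adam", "softmax", "cross_entropy_grad"]


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean())
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(np.float32)


class LocalGlobalPointNet:
    """Shared-MLP + max-pool network over context feature blocks.

    Input: blocks of shape (batch, n_context, n_points, 6).  The context
    axis is pooled first (local-global representation), then the point
    axis (global feature), so the output is invariant to any permutation
    of the context rows but not of the point order, which carries the
    streamline's geometry.
    """

    def __init__(
        self,
        n_classes: int,
        repr_width: int = 64,
        backbone_widths: tuple[int, ...] = (64, 128, 1024),
        head_widths: tuple[int, ...] = (512, 256),
        dropout: float = 0.3,
        input_scale: float = 0.01,
        rng: np.random.Generator | None = None,
    ):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        rng = rng or np.random.default_rng(0)
        self.n_classes = n_classes
        # fixed rescaling of mm coordinates to ~unit range for conditioning;
        # no centering, so absolute position information is preserved
        self.input_scale = float(input_scale)
        self.repr_width = repr_width
        self.backbone_widths = tuple(backbone_widths)
        self.head_widths = tuple(head_widths)
        self.dropout = float(dropout)
        self.params: dict[str, np.ndarray] = {}
        self._add("repr", 6, repr_width, rng)
        w_in = repr_width
        for i, w in enumerate(self.backbone_widths):
            self._add(f"bb{i}", w_in, w, rng)
            w_in = w
        for i, w in enumerate(self.head_widths):
            self._add(f"head{i}", w_in, w, rng)
            w_in = w
        self._add("out", w_in, n_classes, rng)
        self._cache: dict = {}

    def _add(self, name: str, fan_in: int, fan_out: int, rng) -> None:
        self.params[f"{name}.W"] = _he(rng, fan_in, fan_out)
        self.params[f"{name}.b"] = np.zeros(fan_out, dtype=np.float32)

    # ------------------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        chunk: int = 128,
    ) -> np.ndarray:
        """Logits (batch, n_classes) for feature blocks (B, C, P, 6)."""
        x = np.ascontiguousarray(x, dtype=np.float32) * np.float32(self.input_scale)
        if x.ndim != 4 or x.shape[-1] != 6:
            raise ValueError(f"expected (B, C, P, 6) feature blocks, got {x.shape}")
        B, C, P, _ = x.shape
        cache: dict = {"x": x, "training": training}

        # representation module: shared FC + ReLU per paired point, max over context
        W, b = self.params["repr.W"], self.params["repr.b"]
        rep = np.empty((B, P, self.repr_width), dtype=np.float32)
        arg = np.empty((B, P, self.repr_width), dtype=np.int32)
        for lo in range(0, B, chunk):
            hi = min(lo + chunk, B)
            a = np.maximum(x[lo:hi] @ W + b, 0.0)  # (b, C, P, r)
            arg[lo:hi] = a.argmax(axis=1)
            rep[lo:hi] = np.take_along_axis(a, arg[lo:hi][:, None], axis=1)[:, 0]
        cache["arg"] = arg
        cache["rep"] = rep

        # backbone: shared per-point layers, then max over points
        h = rep
        cache["bb_in"] = []
        cache["bb_mask"] = []
        for i in range(len(self.backbone_widths)):
            W, b = self.params[f"bb{i}.W"], self.params[f"bb{i}.b"]
            cache["bb_in"].append(h)
            z = h @ W + b
            h = np.maximum(z, 0.0)
            cache["bb_mask"].append(z > 0)
        cache["argp"] = h.argmax(axis=1)  # (B, w_last)
        g = np.take_along_axis(h, cache["argp"][:, None], axis=1)[:, 0]

        # head: fully connected with dropout
        cache["head_in"] = []
        cache["head_mask"] = []
        cache["drop_mask"] = []
        for i in range(len(self.head_widths)):
            W, b = self.params[f"head{i}.W"], self.params[f"head{i}.b"]
            cache["head_in"].append(g)
            z = g @ W + b
            cache["head_mask"].append(z > 0)
            g = np.maximum(z, 0.0)
            if training and self.dropout > 0:
                if rng is None:
                    raise ValueError("training forward pass needs an rng for dropout")
                m = (rng.random(g.shape) >= self.dropout).astype(np.float32)
                m /= np.float32(1.0 - self.dropout)
                g = g * m
                cache["drop_mask"].append(m)
            else:
                cache["drop_mask"].append(None)
        cache["out_in"] = g
        self._cache = cache
        return g @ self.params["out.W"] + self.params["out.b"]

    def predict_proba(self, x: np.ndarray, chunk: int = 128) -> np.ndarray:
        return softmax(self.forward(x, training=False, chunk=chunk))

    # ------------------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients for every parameter given d(loss)/d(logits)."""
        c = self._cache
        grads: dict[str, np.ndarray] = {}
        g = c["out_in"]
        grads["out.W"] = g.T @ dlogits
        grads["out.b"] = dlogits.sum(axis=0)
        d = dlogits @ self.params["out.W"].T

        for i in reversed(range(len(self.head_widths))):
            if c["drop_mask"][i] is not None:
                d = d * c["drop_mask"][i]
            d = d * c["head_mask"][i]
            grads[f"head{i}.W"] = c["head_in"][i].T @ d
            grads[f"head{i}.b"] = d.sum(axis=0)
            d = d @ self.params[f"head{i}.W"].T

        # unpool over points
        B, P, _ = c["rep"].shape
        h_last = np.zeros((B, P, self.backbone_widths[-1]), dtype=np.float32)
        np.put_along_axis(h_last, c["argp"][:, None], d[:, None], axis=1)
        d = h_last
        for i in reversed(range(len(self.backbone_widths))):
            d = d * c["bb_mask"][i]
            inp = c["bb_in"][i]
            grads[f"bb{i}.W"] = inp.reshape(-1, inp.shape[-1]).T @ d.reshape(-1, d.shape[-1])
            grads[f"bb{i}.b"] = d.sum(axis=(0, 1))
            d = d @ self.params[f"bb{i}.W"].T

        # unpool over context into the shared repr layer; the gradient is
        # nonzero only at each channel's argmax context row, where the ReLU
        # is active iff the pooled value is positive
        dval = d * (c["rep"] > 0)
        x_perm = c["x"].transpose(0, 2, 1, 3)  # (B, P, C, 6)
        xg = np.take_along_axis(x_perm, c["arg"][:, :, :, None], axis=2)  # (B, P, r, 6)
        grads["repr.W"] = np.einsum("bprj,bpr->jr", xg, dval, optimize=True).astype(np.float32)
        grads["repr.b"] = dval.sum(axis=(0, 1))
        return grads

    def num_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= np.float32(self.lr) * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + np.float32(self.eps)
            )
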