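"""Minimal fully-connected regressor with analytic gradients.

A small multi-layer perceptron (ReLU hidden layers, linear output)
trained by Adam on a per-sample-weighted squared-error loss, with
inverted dropout and L2 weight decay. Written directly in numpy so that
the exact Jacobian of the output with respect to the input is available
in closed form — the gradient-based gene scoring downstream needs it —
and so that every source of randomness (init, batching, dropout) hangs
off one Generator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["MLP"]


class MLP:
    """MLP with ``dims = (in, hidden..., out)`` and relu or tanh hiddens."""

    def __init__(
        self,
        dims: Sequence[int],
        rng: np.random.Generator,
        activation: str = "tanh",
    ):
        if activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.dims = tuple(int(d) for d in dims)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        gain = 2.0 if activation == "relu" else 1.0
        for fan_in, fan_out in zip(self.dims[:-1], self.dims[1:]):
            scale = np.sqrt(gain / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    def _act(self, pre: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return np.maximum(pre, 0.0)
        return np.tanh(pre)

    def _act_grad(self, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return (pre > 0).astype(float)
        return 1.0 - post**2

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(
        self,
        X: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
        cache: bool = False,
    ):
        """Forward pass; dropout (inverted) applies after each hidden unit."""
        acts = [X]  # layer inputs (post-dropout)
        pres: list[np.ndarray] = []
        masks: list[np.ndarray | None] = []
        h = X
        for i in range(self.n_layers):
            pre = h @ self.W[i] + self.b[i]
            h = pre
            if i < self.n_layers - 1:
                pres.append(pre)
                h = self._act(pre)
                if dropout > 0.0:
                    if rng is None:
                        raise ValueError("dropout requires an rng")
                    mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
        if cache:
            return h, acts, pres, masks
        return h

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def loss_and_grads(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        sample_weight: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Weighted MSE ``mean_i w_i |pred_i - y_i|^2`` and its parameter grads."""
        n = X.shape[0]
        out, acts, pres, masks = self.forward(X, dropout=dropout, rng=rng, cache=True)
        resid = out - Y
        loss = float(np.mean(sample_weight * np.sum(resid**2, axis=1)))
        # d loss / d out
        delta = 2.0 * resid * sample_weight[:, None] / n
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        for i in range(self.n_layers - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                pre = pres[i - 1]
                delta = delta * self._act_grad(pre, self._act(pre))
        return loss, gW, gb

    def adam_step(
        self,
        gW: list[np.ndarray],
        gb: list[np.ndarray],
        lr: float,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        params = self.W + self.b
        grads = [g + weight_decay * w for g, w in zip(gW, self.W)] + gb
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def input_jacobian(self, X: np.ndarray) -> np.ndarray:
        """Exact d out / d in per sample: shape (n, out_dim, in_dim).

        The Jacobian at x is the product of the weight matrices with the
        activation derivatives interleaved along the path.
        """
        n = X.shape[0]
        h = X
        # J holds d h / d x, shape (n, width, in_dim)
        J = np.broadcast_to(
            np.eye(self.dims[0]), (n, self.dims[0], self.dims[0])
        ).copy()
        for i in range(self.n_layers):
            J = np.einsum("ho,nhi->noi", self.W[i], J)
            pre = h @ self.W[i] + self.b[i]
            if i < self.n_layers - 1:
                post = self._act(pre)
                J = J * self._act_grad(pre, post)[:, :, None]
                h = post
        return J

    def get_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = w.copy()
            out[f"b{i}"] = b.copy()
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for i in range(self.n_layers):
            self.W[i] = np.asarray(params[f"W{i}"], dtype=float).copy()
            self.b[i] = np.asarray(params[f"b{i}"], dtype=float).copy()
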