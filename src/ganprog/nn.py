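"""Minimal dense networks with hand-written backprop.

The WGAN-GP critic needs second-order terms (the gradient penalty is a
function of the critic's input gradient), so the module provides both the
usual reverse-mode parameter gradients and an analytic parameter gradient
of the penalty.  Leaky-ReLU derivative masks are treated as constants when
differentiating the input gradient; this is exact almost everywhere because
the second derivative of a piecewise-linear activation vanishes off the
kinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DenseNet", "Adam", "leaky_relu"]


def leaky_relu(a: np.ndarray, slope: float) -> np.ndarray:
    return np.where(a > 0, a, slope * a)


def _mask(a: np.ndarray, slope: float) -> np.ndarray:
    # subgradient 1 at the kink
    return np.where(a > 0, 1.0, slope)


@dataclass
class ForwardCache:
    """Per-layer activations retained for backprop."""

    inputs: list[np.ndarray] = field(default_factory=list)   # h_0 .. h_{L-1}
    masks: list[np.ndarray | None] = field(default_factory=list)  # phi'(a_l) or None
    output: np.ndarray | None = None


class DenseNet:
    """Fully connected net, leaky-ReLU hidden layers.

    Parameters
    ----------
    sizes
        Layer widths including input and output, e.g. ``(100, 250, 250, 1208)``.
    leaky_slope
        Negative-side slope of the leaky ReLU.
    output_activation
        ``"leaky"`` applies the leaky ReLU to the output layer too (the
        generator), ``"linear"`` leaves it affine (the critic).
    init
        ``("uniform", half_range)`` for U[-r, r] or ``("glorot", None)``.
    """

    def __init__(
        self,
        sizes: tuple[int, ...],
        *,
        leaky_slope: float = 0.2,
        output_activation: str = "leaky",
        init: tuple[str, float | None] = ("glorot", None),
        rng: np.random.Generator | None = None,
    ) -> None:
        if len(sizes) < 2 or any(s <= 0 for s in sizes):
            raise ValueError(f"invalid layer sizes {sizes!r}")
        if output_activation not in ("leaky", "linear"):
            raise ValueError(f"unknown output activation {output_activation!r}")
        rng = rng if rng is not None else np.random.default_rng()
        self.sizes = tuple(int(s) for s in sizes)
        self.leaky_slope = float(leaky_slope)
        self.output_activation = output_activation
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        kind, arg = init
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            if kind == "uniform":
                r = float(arg)  # type: ignore[arg-type]
            elif kind == "glorot":
                r = float(np.sqrt(6.0 / (fan_in + fan_out)))
            else:
                raise ValueError(f"unknown init {kind!r}")
            self.weights.append(rng.uniform(-r, r, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def get_parameters(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights] + [b.copy() for b in self.biases]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        L = self.n_layers
        if len(params) != 2 * L:
            raise ValueError("parameter list length mismatch")
        for i in range(L):
            if params[i].shape != self.weights[i].shape:
                raise ValueError("weight shape mismatch")
            self.weights[i] = params[i].copy()
            self.biases[i] = params[L + i].copy()

    def copy(self) -> "DenseNet":
        clone = DenseNet(
            self.sizes,
            leaky_slope=self.leaky_slope,
            output_activation=self.output_activation,
            init=("uniform", 0.0),
        )
        clone.set_parameters(self.get_parameters())
        return clone

    # -- forward / backward -------------------------------------------------

    def _activated(self, layer: int) -> bool:
        return layer < self.n_layers - 1 or self.output_activation == "leaky"

    def forward(self, x: np.ndarray, cache: bool = False):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        c = ForwardCache() if cache else None
        h = x
        for l in range(self.n_layers):
            a = h @ self.weights[l] + self.biases[l]
            if self._activated(l):
                m = _mask(a, self.leaky_slope)
                out = a * m  # leaky relu via its own mask
            else:
                m, out = None, a
            if c is not None:
                c.inputs.append(h)
                c.masks.append(m)
            h = out
        if c is not None:
            c.output = h
            return h, c
        return h

    def backprop(self, cache: ForwardCache, upstream: np.ndarray):
        """Reverse pass.

        Returns ``(weight_grads, bias_grads, input_grad)`` for the scalar loss
        whose gradient w.r.t. the network output is ``upstream``.
        """
        gw = [None] * self.n_layers
        gb = [None] * self.n_layers
        d = upstream
        for l in range(self.n_layers - 1, -1, -1):
            if cache.masks[l] is not None:
                d = d * cache.masks[l]
            gw[l] = cache.inputs[l].T @ d
            gb[l] = d.sum(axis=0)
            d = d @ self.weights[l].T
        return gw, gb, d

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(output)/d(input) rows for a scalar-output net, one per sample."""
        if self.sizes[-1] != 1:
            raise ValueError("input_gradient requires a scalar output")
        y, cache = self.forward(x, cache=True)
        _, _, g = self.backprop(cache, np.ones_like(y))
        return g

    # -- gradient penalty ---------------------------------------------------

    def gradient_penalty(self, xhat: np.ndarray):
        """WGAN-GP penalty mean((||grad_x D(xhat)|| - 1)^2) and its parameter grads.

        The derivative through the activation masks is zero almost everywhere,
        so the masks recorded on the forward pass are held fixed; the penalty
        is then multilinear in the weights and its gradient has a closed form.
        Bias gradients vanish for the same reason.
        """
        if self.sizes[-1] != 1:
            raise ValueError("gradient penalty requires a scalar-output critic")
        xhat = np.atleast_2d(np.asarray(xhat, dtype=float))
        B = xhat.shape[0]
        y, cache = self.forward(xhat, cache=True)

        # downstream vectors d_l = dL(output)/d(pre-mask input of layer l),
        # collected so g = d_1 @ W_1^T
        d = np.ones_like(y)
        d_list: list[np.ndarray] = [None] * self.n_layers  # type: ignore[list-item]
        for l in range(self.n_layers - 1, -1, -1):
            if cache.masks[l] is not None:
                d = d * cache.masks[l]
            d_list[l] = d
            d = d @ self.weights[l].T
        g = d  # (B, n_in): per-sample input gradient

        norms = np.sqrt((g * g).sum(axis=1))
        penalty = float(np.mean((norms - 1.0) ** 2))

        safe = np.maximum(norms, 1e-12)
        u = (2.0 / B) * ((norms - 1.0) / safe)[:, None] * g  # dP/dg

        gw = []
        f = u
        for l in range(self.n_layers):
            gw.append(f.T @ d_list[l])
            if l < self.n_layers - 1:
                f = f @ self.weights[l]
                if cache.masks[l] is not None:
                    f = f * cache.masks[l]
        gb = [np.zeros_like(b) for b in self.biases]
        return penalty, gw, gb


class Adam:
    """Adam optimizer over a DenseNet's (weights, biases)."""

    def __init__(self, net: DenseNet, lr: float = 1e-4, beta1: float = 0.5,
                 beta2: float = 0.9, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.weights + net.biases]
        self.v = [np.zeros_like(p) for p in net.weights + net.biases]

    def step(self, weight_grads: list[np.ndarray], bias_grads: list[np.ndarray]) -> None:
        self.t += 1
        grads = list(weight_grads) + list(bias_grads)
        params = self.net.weights + self.net.biases
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
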