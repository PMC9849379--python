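"""NumPy building blocks for complex-valued (and real-valued) CNNs.

All layers operate on ndarrays that are either ``complex128`` or
``float64``; the same code path serves the complex-valued network and the
real-valued baseline CNN (``np.conj`` is the identity on real arrays).

Gradient convention for complex parameters: a parameter w = u + iv is
treated as the real pair (u, v) and gradients are stored as the complex
number dL/du + i dL/dv.  For the C-linear maps used here (convolution,
dense product) this gives the compact rules

    grad_w = G * conj(x),      grad_x = conj(w) * G,

where G is the incoming gradient in the same convention.  These follow from
expanding z = w x into real and imaginary parts and are exercised by the
finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "Linear",
    "SplitReLU",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "Readout",
    "softmax",
    "cross_entropy",
]


class Layer:
    """Minimal layer protocol: params/grads dicts + forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


def _init(shape, fan_in: int, rng: np.random.Generator, complex_weights: bool):
    std = np.sqrt(1.0 / fan_in)
    if complex_weights:
        return (
            rng.normal(0, std / np.sqrt(2), shape)
            + 1j * rng.normal(0, std / np.sqrt(2), shape)
        )
    return rng.normal(0, std, shape)


class Conv2d(Layer):
    """2-D cross-correlation with 'same' zero padding.

    With complex weights A + iB and complex input R + iI the output is the
    complex product combination (A*R - B*I) + i(A*I + B*R), realised
    directly by complex matrix multiplication over im2col patches.
    """

    is_conv = True

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        complex_weights: bool = True,
    ) -> None:
        super().__init__()
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        self.params["W"] = _init(
            (out_channels, in_channels, self.k, self.k), fan_in, rng, complex_weights
        )
        dtype = complex if complex_weights else float
        self.params["b"] = np.zeros(out_channels, dtype)
        self.zero_grad()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), (2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        W = self.params["W"]
        if W.shape[2] > h + 2 * self.pad or W.shape[2] > w + 2 * self.pad:
            raise ValueError("kernel larger than padded input")
        self._cols = self._im2col(x)
        wmat = W.reshape(W.shape[0], -1)
        out = self._cols @ wmat.T + self.params["b"]
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out_c = grad.shape[1]
        gmat = grad.transpose(0, 2, 3, 1).reshape(-1, out_c)
        W = self.params["W"]
        wmat = W.reshape(out_c, -1)
        self.grads["W"] += (gmat.T @ np.conj(self._cols)).reshape(W.shape)
        self.grads["b"] += gmat.sum(axis=0)
        gcols = gmat @ np.conj(wmat)  # (n*h*w, c*k*k)
        gcols = gcols.reshape(n, h, w, c, self.k, self.k)
        p = self.pad
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gcols.dtype)
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, p : p + h, p : p + w]


class Linear(Layer):
    """Dense complex (or real) affine map y = x W^T + b."""

    is_conv = False

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        complex_weights: bool = True,
    ) -> None:
        super().__init__()
        self.params["W"] = _init(
            (out_features, in_features), in_features, rng, complex_weights
        )
        dtype = complex if complex_weights else float
        self.params["b"] = np.zeros(out_features, dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.params["W"].shape[1]:
            raise ValueError(
                f"width mismatch: input {x.shape[1]}, "
                f"layer expects {self.params['W'].shape[1]}"
            )
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += grad.T @ np.conj(self._x)
        self.grads["b"] += grad.sum(axis=0)
        return grad @ np.conj(self.params["W"])


class SplitReLU(Layer):
    """ReLU applied to real and imaginary feature maps separately."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if np.iscomplexobj(x):
            self._mask_re = x.real > 0
            self._mask_im = x.imag > 0
            return np.maximum(x.real, 0) + 1j * np.maximum(x.imag, 0)
        self._mask_re = x > 0
        self._mask_im = None
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask_im is None:
            return grad * self._mask_re
        return grad.real * self._mask_re + 1j * (grad.imag * self._mask_im)


class BatchNorm(Layer):
    """Complex batch normalisation.

    Default ``mode="per_part"``: real and imaginary parts are standardised
    independently per channel (batch mean 0, variance 1 in train mode) and
    given an independent learned affine per part; gradients are exact.

    ``mode="whiten"``: the 2x2 real/imaginary covariance per channel is
    whitened by its inverse principal square root before the per-part
    affine.  The backward pass treats the batch statistics as constants (a
    documented approximation; the default mode has exact gradients).

    For real inputs this reduces to ordinary batch normalisation.
    """

    def __init__(
        self,
        n_channels: int,
        complex_weights: bool = True,
        mode: str = "per_part",
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> None:
        super().__init__()
        if mode not in ("per_part", "whiten"):
            raise ValueError(f"unknown batchnorm mode {mode!r}")
        self.mode = mode
        self.momentum = momentum
        self.eps = eps
        self.complex = complex_weights
        dtype = complex if complex_weights else float
        self.params["gamma"] = np.ones(n_channels, dtype)
        if complex_weights:
            self.params["gamma"] += 1j  # unit gain on both parts
        self.params["beta"] = np.zeros(n_channels, dtype)
        self.running_mean = np.zeros(n_channels, dtype)
        self.running_var_re = np.ones(n_channels)
        self.running_var_im = np.ones(n_channels)
        self.running_cov = np.zeros(n_channels)
        self.zero_grad()

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v if ndim == 2 else v[:, None, None]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = self._axes(x)
        if train and x.shape[0] < 2:
            raise ValueError("batch normalisation needs batch size >= 2 in train mode")
        if train:
            mean = x.mean(axis=axes)
            xr = x.real - self._expand(mean.real if self.complex else mean, x.ndim)
            var_re = (xr**2).mean(axis=axes)
            if self.complex:
                xi = x.imag - self._expand(mean.imag, x.ndim)
                var_im = (xi**2).mean(axis=axes)
                cov = (xr * xi).mean(axis=axes)
            else:
                xi, var_im, cov = None, None, np.zeros_like(var_re)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var_re = (1 - m) * self.running_var_re + m * var_re
            if self.complex:
                self.running_var_im = (1 - m) * self.running_var_im + m * var_im
                self.running_cov = (1 - m) * self.running_cov + m * cov
        else:
            mean = self.running_mean
            var_re = self.running_var_re
            var_im = self.running_var_im if self.complex else None
            cov = self.running_cov
            xr = x.real - self._expand(mean.real if self.complex else mean, x.ndim)
            xi = x.imag - self._expand(mean.imag, x.ndim) if self.complex else None

        if not self.complex:
            std = np.sqrt(var_re + self.eps)
            xhat = xr / self._expand(std, x.ndim)
            self._cache = (xhat, std, axes, x.shape, train)
            return self._expand(self.params["gamma"], x.ndim) * xhat + self._expand(
                self.params["beta"], x.ndim
            )

        if self.mode == "per_part":
            std_re = np.sqrt(var_re + self.eps)
            std_im = np.sqrt(var_im + self.eps)
            xhat = xr / self._expand(std_re, x.ndim) + 1j * (
                xi / self._expand(std_im, x.ndim)
            )
            self._cache = (xhat, std_re, std_im, axes, x.shape, train)
        else:
            # inverse principal square root of [[vr, c], [c, vi]]
            det = (var_re + self.eps) * (var_im + self.eps) - cov**2
            s = np.sqrt(det)
            t = np.sqrt(var_re + var_im + 2 * self.eps + 2 * s)
            w11 = (var_im + self.eps + s) / (s * t)
            w22 = (var_re + self.eps + s) / (s * t)
            w12 = -cov / (s * t)
            e = lambda v: self._expand(v, x.ndim)
            xhat = (e(w11) * xr + e(w12) * xi) + 1j * (e(w12) * xr + e(w22) * xi)
            self._cache = (xhat, w11, w12, w22, axes, x.shape, train)
        gamma, beta = self.params["gamma"], self.params["beta"]
        e = lambda v: self._expand(v, x.ndim)
        return (
            e(gamma.real) * xhat.real
            + e(beta.real)
            + 1j * (e(gamma.imag) * xhat.imag + e(beta.imag))
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if not self.complex:
            xhat, std, axes, shape, train = self._cache
            self.grads["gamma"] += (grad * xhat).sum(axis=axes)
            self.grads["beta"] += grad.sum(axis=axes)
            g = grad * self._expand(self.params["gamma"], grad.ndim)
            if not train:
                return g / self._expand(std, grad.ndim)
            n = grad.size // grad.shape[1] if grad.ndim == 4 else grad.shape[0]
            return (
                g
                - self._expand(g.mean(axis=axes), grad.ndim)
                - xhat * self._expand((g * xhat).mean(axis=axes), grad.ndim)
            ) / self._expand(std, grad.ndim)

        e = lambda v: self._expand(v, grad.ndim)
        if self.mode == "per_part":
            xhat, std_re, std_im, axes, shape, train = self._cache
            self.grads["gamma"] += (grad.real * xhat.real).sum(axis=axes) + 1j * (
                grad.imag * xhat.imag
            ).sum(axis=axes)
            self.grads["beta"] += grad.real.sum(axis=axes) + 1j * grad.imag.sum(
                axis=axes
            )
            gamma = self.params["gamma"]
            gr = grad.real * e(gamma.real)
            gi = grad.imag * e(gamma.imag)
            if not train:
                return gr / e(std_re) + 1j * (gi / e(std_im))
            out_re = (
                gr - e(gr.mean(axis=axes)) - xhat.real * e((gr * xhat.real).mean(axes))
            ) / e(std_re)
            out_im = (
                gi - e(gi.mean(axis=axes)) - xhat.imag * e((gi * xhat.imag).mean(axes))
            ) / e(std_im)
            return out_re + 1j * out_im

        xhat, w11, w12, w22, axes, shape, train = self._cache
        self.grads["gamma"] += (grad.real * xhat.real).sum(axis=axes) + 1j * (
            grad.imag * xhat.imag
        ).sum(axis=axes)
        self.grads["beta"] += grad.real.sum(axis=axes) + 1j * grad.imag.sum(axis=axes)
        gamma = self.params["gamma"]
        gr = grad.real * e(gamma.real)
        gi = grad.imag * e(gamma.imag)
        # statistics treated as constants: transpose of the whitening matrix
        out_re = e(w11) * gr + e(w12) * gi
        out_im = e(w12) * gr + e(w22) * gi
        return out_re + 1j * out_im


class Dropout(Layer):
    """Dropout zeroing real and imaginary parts together (one mask)."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Readout(Layer):
    """Map the final complex activations to real class logits.

    Modes: ``"modulus"`` (|z|, phase-invariant), ``"real"`` (Re z).  Real
    networks use ``"real"`` which is then the identity.
    """

    def __init__(self, mode: str = "modulus", eps: float = 1e-12) -> None:
        super().__init__()
        if mode not in ("modulus", "real"):
            raise ValueError(f"unknown readout mode {mode!r}")
        self.mode = mode
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        if self.mode == "real":
            return x.real if np.iscomplexobj(x) else x
        return np.abs(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.mode == "real":
            if np.iscomplexobj(self._x):
                return grad.astype(complex)
            return grad
        if not np.iscomplexobj(self._x):
            return grad * np.sign(self._x)
        mod = np.abs(self._x)
        safe = np.maximum(mod, self.eps)
        return grad * (self._x.real / safe) + 1j * (grad * (self._x.imag / safe))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    loss = -np.log(np.maximum(probs[np.arange(n), targets], 1e-300)).mean()
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n
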