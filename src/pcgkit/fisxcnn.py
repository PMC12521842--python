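"""Sugeno fuzzy inference fused with a 1-D separable-convolution network.

Two cooperating models:

* a five-layer first-order Sugeno fuzzy inference system (FIS) over a
  handful of selected features.  Layer 1 computes membership degrees
  (Gaussian / triangular / generalized-bell), layer 2 the rule firing
  strengths (product T-norm over the rule's memberships times an
  optional rule weight), layer 3 normalizes them to sum to one, layer 4
  weights each rule's linear consequent ``w . x + e`` by its normalized
  firing, and layer 5 sums -- the firing-strength-weighted mean that
  centroid defuzzification reduces to for a Sugeno system.  Training is
  *hybrid*: consequent parameters are solved globally by linear least
  squares with the premises frozen, then premise centers/widths take a
  gradient step on the squared error.

* a small Xception-style 1-D CNN over filter-bank envelope segments of
  the denoised recording: conv(32, k=5) -> batchnorm -> ReLU ->
  maxpool(2) -> depthwise-separable conv(64, k=3) -> batchnorm -> ReLU
  -> maxpool(2) -> global average pool -> concat(FIS risk score) ->
  dense -> dropout -> softmax(5), trained with categorical
  cross-entropy and Adam.  All layers are implemented here with
  explicit backward passes; the gradients are validated against finite
  differences in the test suite.

The FIS contributes a scalar *fuzzy risk score* in [0, 1] (trained on
normal-vs-disease) that is concatenated to the CNN's pooled features
before the dense layer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# membership functions


@dataclass
class MembershipFn:
    """One fuzzy membership function.

    ``gaussian``: params (m, sigma) -- ``exp(-(x-m)^2 / (2 sigma^2))``.
    ``triangular``: params (w, r, e) with w < r < e -- linear ramps.
    ``bell``: params (u, v, m) -- ``1 / (1 + |(x-m)/u|^(2v))``.
    """

    kind: str
    params: tuple

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if self.params[1] <= 0:
                raise ValueError("gaussian width must be positive")
        elif self.kind == "triangular":
            w, r, e = self.params
            if not (w < r < e):
                raise ValueError("triangular needs w < r < e")
        elif self.kind == "bell":
            if self.params[0] <= 0:
                raise ValueError("bell width must be positive")
        else:
            raise ValueError(f"unknown membership kind {self.kind!r}")


def membership(fn: MembershipFn, x) -> np.ndarray:
    """Evaluate a membership function; output in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if fn.kind == "gaussian":
        m, s = fn.params
        return np.exp(-((x - m) ** 2) / (2.0 * s**2))
    if fn.kind == "triangular":
        w, r, e = fn.params
        up = (x - w) / (r - w)
        down = (e - x) / (e - r)
        return np.clip(np.minimum(up, down), 0.0, 1.0)
    u, v, m = fn.params
    return 1.0 / (1.0 + np.abs((x - m) / u) ** (2.0 * v))


# ---------------------------------------------------------------------------
# Sugeno FIS


class SugenoFIS:
    """First-order Sugeno fuzzy system with hybrid learning.

    Parameters
    ----------
    mfs_per_input : int
        Gaussian membership functions per input; the rule base is the
        full grid, so with k inputs there are ``mfs_per_input ** k``
        rules (k is capped at 6 to keep the rule base tractable).
    epochs, lr : training budget and premise-gradient step size.

    Attributes (after ``fit``): ``centers_``, ``sigmas_`` of shape
    (k, mfs_per_input); ``consequents_`` of shape (R, k+1) holding each
    rule's linear coefficients and bias; ``loss_curve_``.
    """

    def __init__(self, mfs_per_input: int = 2, epochs: int = 50,
                 lr: float = 0.05, rule_weights: np.ndarray | None = None):
        self.mfs_per_input = mfs_per_input
        self.epochs = epochs
        self.lr = lr
        self.rule_weights = rule_weights

    # -- forward machinery -------------------------------------------------

    def _memberships(self, X: np.ndarray) -> np.ndarray:
        # (n, k, m)
        diff = X[:, :, None] - self.centers_[None, :, :]
        return np.exp(-(diff**2) / (2.0 * self.sigmas_[None, :, :] ** 2))

    def _firing(self, M: np.ndarray) -> np.ndarray:
        # (n, R): product over inputs of the rule's chosen memberships
        n = M.shape[0]
        p = np.ones((n, self.rules_.shape[0]))
        for j in range(self.n_inputs_):
            p *= M[:, j, self.rules_[:, j]]
        return p * self.rule_weights_[None, :]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        """Full five-layer pass; returns outputs and the layer trace."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        M = self._memberships(X)                      # layer 1
        p = self._firing(M)                           # layer 2
        total = p.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("no rule coverage for at least one input")
        pbar = p / total                              # layer 3
        ones = np.ones((X.shape[0], 1))
        Xa = np.concatenate([X, ones], axis=1)        # (n, k+1)
        f = Xa @ self.consequents_.T                  # (n, R) rule outputs
        weighted = pbar * f                           # layer 4
        g = weighted.sum(axis=1)                      # layer 5
        trace = {"memberships": M, "firing": p, "normalized": pbar,
                 "rule_outputs": f, "weighted": weighted, "output": g}
        return g, trace

    def predict(self, X) -> np.ndarray:
        return self.forward(X)[0]

    # -- training ----------------------------------------------------------

    def _init_premises(self, X: np.ndarray) -> None:
        k, m = self.n_inputs_, self.mfs_per_input
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        self.centers_ = np.linspace(0, 1, m)[None, :] * span[:, None] + lo[:, None]
        self.sigmas_ = np.full((k, m), 1.0) * (span / max(1.5 * (m - 1), 1.0))[:, None]
        self.rules_ = np.array(list(itertools.product(range(m), repeat=k)),
                               dtype=int)
        R = self.rules_.shape[0]
        self.rule_weights_ = (np.ones(R) if self.rule_weights is None
                              else np.asarray(self.rule_weights, dtype=float))
        self.consequents_ = np.zeros((R, k + 1))

    def _solve_consequents(self, X: np.ndarray, y: np.ndarray) -> None:
        """Least-squares step: globally optimal consequents for the
        current premises (cannot increase the training loss)."""
        M = self._memberships(X)
        p = self._firing(M)
        pbar = p / p.sum(axis=1, keepdims=True)
        Xa = np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)
        # design: n x (R*(k+1)), block r = pbar[:, r, None] * Xa
        A = (pbar[:, :, None] * Xa[:, None, :]).reshape(X.shape[0], -1)
        sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            logger.debug("rank-deficient consequent system (rank %d < %d); "
                         "minimum-norm solution used", rank, A.shape[1])
        self.consequents_ = sol.reshape(self.rules_.shape[0], -1)

    def premise_gradients(self, X: np.ndarray, y: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Analytic d(mean squared error)/d(centers, sigmas)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        M = self._memberships(X)
        p = self._firing(M)
        total = p.sum(axis=1, keepdims=True)
        pbar = p / total
        Xa = np.concatenate([X, np.ones((n, 1))], axis=1)
        f = Xa @ self.consequents_.T
        g = (pbar * f).sum(axis=1)
        dg = 2.0 * (g - y) / n                               # (n,)
        # dL/dp_r = dg * (f_r - g) / total
        dp = dg[:, None] * (f - g[:, None]) / total          # (n, R)
        # route to memberships: p_r = w_r * prod_j M[:, j, rule[r, j]]
        dM = np.zeros_like(M)
        for j in range(self.n_inputs_):
            mj = M[:, j, self.rules_[:, j]]                  # (n, R)
            contrib = dp * p / np.maximum(mj, 1e-300)
            np.add.at(dM[:, j, :], (slice(None), self.rules_[:, j]), 0)
            for m in range(self.mfs_per_input):
                sel = self.rules_[:, j] == m
                dM[:, j, m] += contrib[:, sel].sum(axis=1)
        diff = X[:, :, None] - self.centers_[None, :, :]
        s2 = self.sigmas_[None, :, :] ** 2
        d_centers = (dM * M * diff / s2).sum(axis=0)
        d_sigmas = (dM * M * diff**2 / (s2 * self.sigmas_[None, :, :])).sum(axis=0)
        return d_centers, d_sigmas

    def fit(self, X, y) -> "SugenoFIS":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self.n_inputs_ = X.shape[1]
        if self.n_inputs_ > 6:
            raise ValueError("more than 6 FIS inputs would explode the rule "
                             "base; select features first")
        self._init_premises(X)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            self._solve_consequents(X, y)
            g, _ = self.forward(X)
            self.loss_curve_.append(float(np.mean((g - y) ** 2)))
            dc, ds = self.premise_gradients(X, y)
            self.centers_ -= self.lr * dc
            self.sigmas_ -= self.lr * ds
            np.clip(self.sigmas_, 1e-3 * np.ptp(X, axis=0).max() + 1e-12,
                    None, out=self.sigmas_)
        self._solve_consequents(X, y)
        g, _ = self.forward(X)
        self.loss_curve_.append(float(np.mean((g - y) ** 2)))
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"mfs_per_input": self.mfs_per_input, "epochs": self.epochs,
                "lr": self.lr, "rule_weights": self.rule_weights}

    def set_params(self, **params) -> "SugenoFIS":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def fis_forward(model: SugenoFIS, x: np.ndarray) -> tuple[float, dict]:
    """Single-sample forward pass exposing all five layers."""
    g, trace = model.forward(np.atleast_2d(x))
    return float(g[0]), trace


def fis_train_hybrid(X, y, mfs_per_input: int = 2, epochs: int = 50,
                     lr: float = 0.05) -> SugenoFIS:
    return SugenoFIS(mfs_per_input=mfs_per_input, epochs=epochs, lr=lr).fit(X, y)


def fuzzy_risk_score(fis: SugenoFIS, x: np.ndarray) -> np.ndarray:
    """Clipped-to-[0, 1] FIS output; 0 reads as normal, 1 as disease."""
    return np.clip(fis.predict(np.atleast_2d(x)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# activations / losses / softmax


def activation(kind: str, x, params: dict | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Closed-form activation functions used by the network."""
    x = np.asarray(x, dtype=float)
    params = params or {}
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "tanh":
        return np.tanh(x)
    if kind == "relu":
        return np.maximum(0.0, x)
    if kind == "leaky_relu":
        m = params.get("m", 0.01)
        return np.where(x > 0, x, m * x)
    if kind == "prelu":
        u = params.get("u", 0.25)
        return np.where(x > 0, x, u * x)
    if kind == "noisy_relu":
        if rng is None:
            rng = np.random.default_rng(params.get("seed", 0))
        sigma = params.get("sigma", 0.1)
        return np.maximum(0.0, x + rng.normal(0.0, sigma, size=x.shape))
    raise ValueError(f"unknown activation {kind!r}")


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-shifted)."""
    z = np.asarray(logits, dtype=float)
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def loss(kind: str, predicted, target, margin: float = 1.0) -> float:
    """Training losses: categorical cross-entropy, mean Euclidean error,
    or binary hinge with targets in {0, 1}."""
    w = np.asarray(predicted, dtype=float)
    j = np.asarray(target, dtype=float)
    if kind == "cross_entropy":
        if w.shape != j.shape:
            raise ValueError("prediction/target shape mismatch")
        return float(-np.sum(j * np.log(np.maximum(w, 1e-12))))
    if kind == "euclidean":
        if w.shape != j.shape:
            raise ValueError("prediction/target shape mismatch")
        return float(np.sum((w - j) ** 2) / (2.0 * w.size))
    if kind == "hinge":
        # target in {0,1} mapped to {-1,+1}; w holds raw scores
        return float(np.sum(np.maximum(0.0, margin - (2.0 * j - 1.0) * w)))
    raise ValueError(f"unknown loss {kind!r}")


# ---------------------------------------------------------------------------
# network layers (explicit forward/backward)


class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}


class _Conv1d(_Layer):
    """Same-padded 1-D convolution, weight (O, C, K)."""

    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k))
        self.k = k
        self.params = {"W": rng.normal(0, scale, (c_out, c_in, k)),
                       "b": np.zeros(c_out)}

    def forward(self, x, train):
        K = self.k
        pl, pr = (K - 1) // 2, K // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._xp = xp
        L = x.shape[2]
        W, b = self.params["W"], self.params["b"]
        y = np.zeros((x.shape[0], W.shape[0], L))
        for t in range(K):
            y += np.einsum("oc,ncl->nol", W[:, :, t], xp[:, :, t:t + L],
                           optimize=True)
        return y + b[None, :, None]

    def backward(self, gy):
        K = self.k
        W = self.params["W"]
        L = gy.shape[2]
        xp = self._xp
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for t in range(K):
            dW[:, :, t] = np.einsum("nol,ncl->oc", gy, xp[:, :, t:t + L],
                                    optimize=True)
            dxp[:, :, t:t + L] += np.einsum("oc,nol->ncl", W[:, :, t], gy,
                                            optimize=True)
        self.grads = {"W": dW, "b": gy.sum(axis=(0, 2))}
        pl = (K - 1) // 2
        return dxp[:, :, pl:pl + L]


class _DepthwiseConv1d(_Layer):
    """Per-channel same-padded convolution, weight (C, K)."""

    def __init__(self, c, k, rng):
        super().__init__()
        self.k = k
        self.params = {"W": rng.normal(0, np.sqrt(2.0 / k), (c, k)),
                       "b": np.zeros(c)}

    def forward(self, x, train):
        K = self.k
        pl, pr = (K - 1) // 2, K // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._xp = xp
        L = x.shape[2]
        W, b = self.params["W"], self.params["b"]
        y = np.zeros_like(x)
        for t in range(K):
            y += W[None, :, t, None] * xp[:, :, t:t + L]
        return y + b[None, :, None]

    def backward(self, gy):
        K, W = self.k, self.params["W"]
        L = gy.shape[2]
        xp = self._xp
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for t in range(K):
            dW[:, t] = np.sum(gy * xp[:, :, t:t + L], axis=(0, 2))
            dxp[:, :, t:t + L] += W[None, :, t, None] * gy
        self.grads = {"W": dW, "b": gy.sum(axis=(0, 2))}
        pl = (K - 1) // 2
        return dxp[:, :, pl:pl + L]


class _PointwiseConv1d(_Layer):
    """1x1 convolution mixing channels, weight (O, C)."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.params = {"W": rng.normal(0, np.sqrt(2.0 / c_in), (c_out, c_in)),
                       "b": np.zeros(c_out)}

    def forward(self, x, train):
        self._x = x
        return (np.einsum("oc,ncl->nol", self.params["W"], x, optimize=True)
                + self.params["b"][None, :, None])

    def backward(self, gy):
        self.grads = {"W": np.einsum("nol,ncl->oc", gy, self._x, optimize=True),
                      "b": gy.sum(axis=(0, 2))}
        return np.einsum("oc,nol->ncl", self.params["W"], gy, optimize=True)


class _BatchNorm1d(_Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.momentum, self.eps = momentum, eps
        self.run_mean, self.run_var = np.zeros(c), np.ones(c)

    def forward(self, x, train):
        if train:
            m = x.mean(axis=(0, 2))
            v = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * m
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * v
        else:
            m, v = self.run_mean, self.run_var
        self._std = np.sqrt(v + self.eps)
        self._xhat = (x - m[None, :, None]) / self._std[None, :, None]
        return (self.params["gamma"][None, :, None] * self._xhat
                + self.params["beta"][None, :, None])

    def backward(self, gy):
        xhat, std = self._xhat, self._std
        N = gy.shape[0] * gy.shape[2]
        g = self.params["gamma"]
        self.grads = {"gamma": np.sum(gy * xhat, axis=(0, 2)),
                      "beta": gy.sum(axis=(0, 2))}
        dxhat = gy * g[None, :, None]
        sum_d = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (dxhat - sum_d / N - xhat * sum_dx / N) / std[None, :, None]


class _ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return gy * self._mask


class _MaxPool2(_Layer):
    def forward(self, x, train):
        n, c, L = x.shape
        L2 = L - (L % 2)
        xr = x[:, :, :L2].reshape(n, c, L2 // 2, 2)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, gy):
        n, c, Lh = gy.shape
        dx = np.zeros(self._shape)
        dxr = dx[:, :, :Lh * 2].reshape(n, c, Lh, 2)
        np.put_along_axis(dxr, self._arg[..., None], gy[..., None], axis=3)
        return dx


class _GlobalAvgPool(_Layer):
    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._L, axis=2) / self._L


class _Dense(_Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        self.params = {"W": rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out)),
                       "b": np.zeros(d_out)}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads = {"W": self._x.T @ gy, "b": gy.sum(axis=0)}
        return gy @ self.params["W"].T


class _Dropout(_Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


# ---------------------------------------------------------------------------
# the XCNN model


class XCNNModel:
    """conv(32,5) -> BN -> ReLU -> pool -> sepconv(64,3) -> BN -> ReLU ->
    pool -> GAP -> [concat risk] -> dropout -> dense(n_classes) -> softmax.

    Dropout regularizes the input of the final (output) layer; at
    inference it is disabled."""

    def __init__(self, c_in: int = 1, n_classes: int = 5, dropout: float = 0.5,
                 use_risk: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.use_risk = use_risk
        self.n_classes = n_classes
        self.conv_stack = [
            _Conv1d(c_in, 32, 5, rng), _BatchNorm1d(32), _ReLU(), _MaxPool2(),
            _DepthwiseConv1d(32, 3, rng), _PointwiseConv1d(32, 64, rng),
            _BatchNorm1d(64), _ReLU(), _MaxPool2(), _GlobalAvgPool(),
        ]
        self.dense = _Dense(64 + (1 if use_risk else 0), n_classes, rng)
        self.dropout = _Dropout(dropout, np.random.default_rng(seed + 1))
        self.layers = self.conv_stack + [self.dense, self.dropout]

    # -- plumbing ----------------------------------------------------------

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield f"{li}.{name}", layer, name, arr

    def forward(self, x: np.ndarray, risk: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        """Class probabilities for input (n, C, L); risk is (n,)."""
        h = np.asarray(x, dtype=float)
        for layer in self.conv_stack:
            h = layer.forward(h, train)
        if self.use_risk:
            if risk is None:
                raise ValueError("model was built with risk fusion enabled")
            h = np.concatenate([h, np.asarray(risk, float)[:, None]], axis=1)
        h = self.dropout.forward(h, train)
        logits = self.dense.forward(h, train)
        return softmax(logits, axis=1)

    def loss_and_grads(self, x, y_onehot, risk=None, train: bool = True
                       ) -> tuple[float, np.ndarray]:
        """Mean cross-entropy and parameter gradients (stored per layer)."""
        probs = self.forward(x, risk, train=train)
        n = x.shape[0]
        value = float(-np.sum(y_onehot * np.log(np.maximum(probs, 1e-12))) / n)
        glogits = (probs - y_onehot) / n
        g = self.dense.backward(glogits)
        g = self.dropout.backward(g)
        if self.use_risk:
            g = g[:, :-1]
        for layer in reversed(self.conv_stack):
            g = layer.backward(g)
        return value, probs


class _Adam:
    def __init__(self, model: XCNNModel, lr: float = 1e-3, b1=0.9, b2=0.999,
                 eps=1e-8):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, b1, b2, eps
        self.m = {k: np.zeros_like(a) for k, _, _, a in model.parameters()}
        self.v = {k: np.zeros_like(a) for k, _, _, a in model.parameters()}
        self.t = 0

    def step(self):
        self.t += 1
        for key, layer, name, arr in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def xcnn_train(segments: np.ndarray, labels: np.ndarray,
               risk: np.ndarray | None = None, n_classes: int = 5,
               epochs: int = 30, lr: float = 1e-3, batch_size: int = 32,
               dropout: float = 0.5, seed: int = 0,
               classes: np.ndarray | None = None) -> XCNNModel:
    """Train the separable-convolution classifier with Adam.

    ``segments`` is (n, C, L); ``risk`` the per-sample fuzzy score (or
    None to disable fusion).  Aborts on NaN loss.  The fitted model
    carries ``classes_``, ``loss_curve_`` and ``train_accuracy_``.
    """
    x = np.asarray(segments, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite values in training segments")
    if risk is not None and not np.all(np.isfinite(np.asarray(risk, float))):
        raise FloatingPointError("non-finite values in risk scores")
    cls = np.unique(y) if classes is None else np.asarray(classes)
    if np.unique(y).size < cls.size:
        logger.warning("only %d of %d classes present in training data",
                       np.unique(y).size, cls.size)
    y_idx = np.searchsorted(cls, y)
    onehot = np.eye(cls.size)[y_idx]
    model = XCNNModel(c_in=x.shape[1], n_classes=cls.size, dropout=dropout,
                      use_risk=risk is not None, seed=seed)
    opt = _Adam(model, lr=lr)
    rng = np.random.default_rng(seed + 7)
    n = x.shape[0]
    curve = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            sel = order[start:start + batch_size]
            r = None if risk is None else np.asarray(risk, float)[sel]
            value, _ = model.loss_and_grads(x[sel], onehot[sel], r, train=True)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"NaN/Inf training loss at epoch {len(curve)}")
            opt.step()
            ep_loss += value * sel.size
        curve.append(ep_loss / n)
    model.classes_ = cls
    model.loss_curve_ = curve
    pred = xcnn_predict(model, x, risk)[1]
    model.train_accuracy_ = float(np.mean(pred == y))
    return model


def xcnn_state(model: XCNNModel) -> dict:
    """Serializable state: all parameters, BN running stats, and the
    architecture metadata needed to rebuild the model."""
    state = {"meta_c_in": np.array(model.conv_stack[0].params["W"].shape[1]),
             "meta_n_classes": np.array(model.n_classes),
             "meta_use_risk": np.array(int(model.use_risk)),
             "meta_dropout": np.array(model.dropout.p),
             "classes": np.asarray(getattr(model, "classes_", []))}
    for key, layer, name, arr in model.parameters():
        state[f"param_{key}"] = arr
    for li, layer in enumerate(model.layers):
        if isinstance(layer, _BatchNorm1d):
            state[f"bn_{li}_mean"] = layer.run_mean
            state[f"bn_{li}_var"] = layer.run_var
    return state


def xcnn_from_state(state: dict) -> XCNNModel:
    model = XCNNModel(c_in=int(state["meta_c_in"]),
                      n_classes=int(state["meta_n_classes"]),
                      dropout=float(state["meta_dropout"]),
                      use_risk=bool(int(state["meta_use_risk"])))
    for key, layer, name, arr in model.parameters():
        arr[...] = state[f"param_{key}"]
    for li, layer in enumerate(model.layers):
        if isinstance(layer, _BatchNorm1d):
            layer.run_mean = np.asarray(state[f"bn_{li}_mean"])
            layer.run_var = np.asarray(state[f"bn_{li}_var"])
    if state["classes"].size:
        model.classes_ = state["classes"]
    return model


def xcnn_predict(model: XCNNModel, segments: np.ndarray,
                 risk: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class probabilities and argmax labels (dropout off)."""
    probs = model.forward(np.asarray(segments, float), risk, train=False)
    labels = model.classes_[np.argmax(probs, axis=1)]
    return probs, labels
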