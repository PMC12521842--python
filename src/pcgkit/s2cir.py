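"""Margin-based cardiac impact scoring (soft-margin hyperplane fit).

A linear soft-margin separator ``sign(s . x + v)`` is fitted by solving

    min_(s, v, xi)  1/2 ||s||^2 + C * sum(xi)
    s.t.            y_i (s . x_i + v) >= 1 - xi_i,   xi_i >= 0

The optimal objective value is the *impact rate*: small when the classes
separate with a wide margin, growing with every margin violation.  The
per-feature impact score ``|s_j| * sd(X_j)`` ranks features by how much
a one-standard-deviation move along them shifts the decision value;
multi-class problems aggregate one-vs-rest fits by the maximum.

The solver is a deterministic two-variable coordinate ascent on the dual
(maximal-violating-pair selection), so repeated fits are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ImpactModel:
    """Fitted soft-margin hyperplane with its slack and objective."""

    s: np.ndarray
    v: float
    xi: np.ndarray
    C: float
    impact_rate: float
    feature_impacts: np.ndarray | None = None

    @property
    def margin(self) -> float:
        """Geometric margin width ``2 / ||s||``."""
        norm = np.linalg.norm(self.s)
        if norm == 0:
            raise ValueError("degenerate geometry: zero weight vector")
        return 2.0 / norm


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-8,
         max_iter: int = 200_000) -> tuple[np.ndarray, float]:
    """Maximal-violating-pair SMO on the dual; returns (alpha, bias)."""
    n = y.size
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    g = -np.ones(n)                      # gradient of 1/2 a'Qa - e'a
    for _ in range(max_iter):
        yg = -y * g
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < C)) | ((y > 0) & (alpha > 0))
        if not up.any() or not low.any():
            break
        i = int(np.where(up)[0][np.argmax(yg[up])])
        j = int(np.where(low)[0][np.argmin(yg[low])])
        gmax, gmin = yg[i], yg[j]
        if gmax - gmin < tol:
            break
        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] != y[j]:
            quad = max(Q[i, i] + Q[j, j] + 2 * Q[i, j], 1e-12)
            delta = (-g[i] - g[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0 and aj < 0:
                ai, aj = diff, 0.0
            elif diff <= 0 and ai < 0:
                ai, aj = 0.0, -diff
            if diff > 0 and ai > C:
                ai, aj = C, C - diff
            elif diff <= 0 and aj > C:
                ai, aj = C + diff, C
        else:
            quad = max(Q[i, i] + Q[j, j] - 2 * Q[i, j], 1e-12)
            delta = (g[i] - g[j]) / quad
            tot = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if tot > C:
                if ai > C:
                    ai, aj = C, tot - C
            elif aj < 0:
                ai, aj = tot, 0.0
            if tot > C:
                if aj > C:
                    ai, aj = tot - C, C
            elif ai < 0:
                ai, aj = 0.0, tot
        alpha[i], alpha[j] = ai, aj
        g += Q[:, i] * (ai - ai_old) + Q[:, j] * (aj - aj_old)
    # bias from the final violating-pair bracket / free support vectors
    yg = -y * g
    free = (alpha > 1e-10) & (alpha < C - 1e-10)
    if free.any():
        b = float(np.mean(yg[free]))
    else:
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y < 0) & (alpha < C)) | ((y > 0) & (alpha > 0))
        hi = yg[up].max() if up.any() else 0.0
        lo = yg[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b


def fit_hyperplane(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> ImpactModel:
    """Fit the soft-margin hyperplane (linear kernel).

    ``y`` must hold exactly two labels (mapped to -1/+1; an explicit
    ±1 coding is kept as-is).  Slack values are recomputed exactly from
    the solution, so the KKT feasibility ``y(s.x+v) >= 1 - xi`` holds to
    rounding error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if C <= 0:
        raise ValueError("C must be positive")
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError("need exactly two classes")
    if set(labels) == {-1, 1}:
        yy = y.astype(float)
    else:
        yy = np.where(y == labels[1], 1.0, -1.0)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate geometry: all feature rows identical")
    K = X @ X.T
    alpha, b = _smo(K, yy, C)
    s = (alpha * yy) @ X
    # given s, the objective is piecewise linear in the bias, so the exact
    # optimum sits at a hinge breakpoint; scan them plus the SMO estimate
    margins = X @ s
    candidates = np.append(yy - margins, b)
    hinge_tot = np.maximum(0.0, 1.0 - yy[None, :] *
                           (margins[None, :] + candidates[:, None])).sum(axis=1)
    b = float(candidates[np.argmin(hinge_tot)])
    xi = np.maximum(0.0, 1.0 - yy * (margins + b))
    obj = 0.5 * float(s @ s) + C * float(np.sum(xi))
    return ImpactModel(s=s, v=b, xi=xi, C=C, impact_rate=obj)


def impact_rate(model: ImpactModel) -> float:
    """The fitted objective ``1/2 ||s||^2 + C sum(xi)`` (>= 0)."""
    if model.s is None:
        raise ValueError("model is not fitted")
    return model.impact_rate


def feature_impacts(X: np.ndarray, y: np.ndarray, C: float = 1.0
                    ) -> list[tuple[int, float]]:
    """Rank features by scale-corrected hyperplane weight.

    For each one-vs-rest binary problem the score of feature j is
    ``|s_j| * sd(X_j)``; multi-class scores take the maximum over the
    per-class fits.  Returns ``(feature_index, score)`` pairs in
    descending score order, distance ties broken by column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("need at least two features to rank")
    classes = np.unique(y)
    sd = np.std(X, axis=0)
    scores = np.zeros(X.shape[1])
    if classes.size == 2:
        model = fit_hyperplane(X, y, C)
        scores = np.abs(model.s) * sd
    else:
        for c in classes:
            yy = np.where(y == c, 1.0, -1.0)
            model = fit_hyperplane(X, yy, C)
            scores = np.maximum(scores, np.abs(model.s) * sd)
    order = np.argsort(-scores, kind="stable")
    return [(int(j), float(scores[j])) for j in order]


class ImpactHyperplane:
    """Estimator wrapper: binary soft-margin classifier + feature scores.

    Attributes (after ``fit``): ``coef_``, ``intercept_``, ``slack_``,
    ``impact_rate_``, ``feature_impacts_`` (unranked per-column scores),
    ``classes_``.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y) -> "ImpactHyperplane":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        model = fit_hyperplane(X, y, self.C)
        self.model_ = model
        self.coef_ = model.s
        self.intercept_ = model.v
        self.slack_ = model.xi
        self.impact_rate_ = model.impact_rate
        self.feature_impacts_ = np.abs(model.s) * np.std(X, axis=0)
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        pos = self.decision_function(X) >= 0
        if set(self.classes_) == {-1, 1}:
            return np.where(pos, 1, -1)
        return np.where(pos, self.classes_[1], self.classes_[0])

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C}

    def set_params(self, **params) -> "ImpactHyperplane":
        for k, v in params.items():
            if k != "C":
                raise ValueError(f"unknown parameter {k!r}")
            self.C = v
        return self
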