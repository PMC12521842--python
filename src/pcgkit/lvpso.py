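"""Linear-vectored particle swarm optimization for feature selection.

Particles move in ``[0, 1]^d``; each position is a soft feature-weight
vector whose fitness is the held-out error of a small learning vector
quantization (LVQ1) classifier trained on the weighted features, with
per-feature information gain folded into its distance.  Two rules give
the variant its name:

* the per-step acceleration coefficients ``e1, e2 ~ U(0, 2)`` are binned
  into low / medium / high classes, and
* the inertia weight is chosen from the pair of classes -- both low
  accelerations select the high inertia 0.9 (push the global search),
  both high select the low inertia 0.4 (refine locally), every mixed
  combination selects the midpoint 0.65.

The final global-best weights are thresholded into a binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: inertia anchor values: low / medium / high
INERTIA_LOW, INERTIA_MID, INERTIA_HIGH = 0.4, 0.65, 0.9

#: per-dimension velocity clamp
V_CLAMP = 0.5


def info_gain(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Per-feature mutual information (bits) with the class label.

    Each feature is binned into ``n_bins`` equal-width bins over its own
    range (hence invariant to affine rescaling), and the discrete mutual
    information with the label is computed.  Constant features get 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, yc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("label is constant; information gain undefined")
    n, d = X.shape
    gains = np.zeros(d)
    for j in range(d):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi <= lo:
            continue
        b = np.minimum(((col - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        joint = np.zeros((n_bins, classes.size))
        np.add.at(joint, (b, yc), 1.0)
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        gains[j] = np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz]))
    return np.maximum(gains, 0.0)


# ---------------------------------------------------------------------------
# LVQ1 with gain-weighted distance


@dataclass
class LVQCodebook:
    z: np.ndarray            # (n_classes, d) prototypes
    classes: np.ndarray
    alpha: float
    gains: np.ndarray

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if np.any(self.gains < 0):
            raise ValueError("gains must be non-negative")


def lvq_train(X: np.ndarray, y: np.ndarray, gains: np.ndarray,
              alpha: float = 0.3, epochs: int = 10,
              seed: int = 0) -> LVQCodebook:
    """Train an LVQ1 codebook (one prototype per class).

    The winning prototype under the gain-weighted squared distance
    ``sum_j G_j (x_j - z_j)^2`` is pulled toward a same-class sample
    (``z += a (x - z)``) and pushed away from a wrong-class one.  The
    learning rate decays linearly to zero over the epoch budget.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    protos = np.stack([X[y == c].mean(axis=0) for c in classes])
    rng = np.random.default_rng(seed)
    g = np.asarray(gains, dtype=float)
    n = X.shape[0]
    for ep in range(epochs):
        a = alpha * (1.0 - ep / epochs)
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            dist = ((protos - x) ** 2 * g).sum(axis=1)
            win = int(np.argmin(dist))
            if classes[win] == y[i]:
                protos[win] += a * (x - protos[win])
            else:
                protos[win] -= a * (x - protos[win])
    return LVQCodebook(z=protos, classes=classes, alpha=alpha, gains=g)


def lvq_predict(book: LVQCodebook, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    d = ((X[:, None, :] - book.z[None, :, :]) ** 2 * book.gains).sum(axis=2)
    return book.classes[np.argmin(d, axis=1)]


def lvq_fitness(X: np.ndarray, y: np.ndarray, weights: np.ndarray,
                gains: np.ndarray | None = None, alpha: float = 0.3,
                epochs: int = 10, n_folds: int = 3,
                seed: int = 0) -> float:
    """Held-out LVQ error of the weight-masked feature matrix, in [0, 1].

    Features are multiplied by ``weights`` (a particle position) and the
    error is averaged over a seeded stratified ``n_folds``-fold split
    (every row is scored exactly once while held out), which keeps the
    fitness estimate's variance low enough for the swarm to resolve the
    contribution of individual features.
    """
    X = np.asarray(X, dtype=float) * np.asarray(weights, dtype=float)
    y = np.asarray(y)
    if gains is None:
        gains = np.ones(X.shape[1])
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        if idx.size < n_folds:
            raise ValueError("a class would be absent from a training split")
        idx = idx[rng.permutation(idx.size)]
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    wrong = 0
    for f in folds:
        te = np.array(f, dtype=int)
        tr = np.setdiff1d(np.arange(y.size), te)
        book = lvq_train(X[tr], y[tr], gains, alpha=alpha, epochs=epochs,
                         seed=seed)
        wrong += int(np.sum(lvq_predict(book, X[te]) != y[te]))
    return wrong / y.size


# ---------------------------------------------------------------------------
# PSO with acceleration classing


def classify_accel(e: float) -> str:
    """Bin an acceleration coefficient in [0, 2] into L / M / H.

    The printed class intervals ([0, 0.8], [0.9, 1.2], [1.3, 2]) leave
    gaps which are closed at their midpoints, 0.85 and 1.25.
    """
    if not (0.0 <= e <= 2.0):
        raise ValueError(f"acceleration coefficient {e} outside [0, 2]")
    if e < 0.85:
        return "L"
    if e < 1.25:
        return "M"
    return "H"


def select_inertia(class1: str, class2: str) -> float:
    """Inertia weight from the two acceleration classes.

    Both low -> 0.9 (strengthen global search when the pulls are weak),
    both high -> 0.4 (refine locally when the pulls are strong), any
    other combination -> the midpoint 0.65.
    """
    for c in (class1, class2):
        if c not in ("L", "M", "H"):
            raise ValueError(f"invalid acceleration class {c!r}")
    if class1 == class2 == "L":
        return INERTIA_HIGH
    if class1 == class2 == "H":
        return INERTIA_LOW
    return INERTIA_MID


@dataclass
class Particle:
    x: np.ndarray
    v: np.ndarray
    pbest: np.ndarray
    pbest_fit: float


@dataclass
class Swarm:
    particles: list[Particle]
    gbest: np.ndarray
    gbest_fit: float
    history: list[float] = field(default_factory=list)


def init_swarm(n_particles: int, d: int, fitness, rng: np.random.Generator,
               informed: list[np.ndarray] | None = None) -> Swarm:
    """Random swarm, optionally warm-started with informed positions
    (e.g. the all-features baseline) replacing the first particles."""
    particles = []
    gbest, gbest_fit = None, np.inf
    informed = list(informed or [])
    for i in range(n_particles):
        x = informed[i] if i < len(informed) else rng.random(d)
        v = (rng.random(d) - 0.5) * 0.2
        f = fitness(x)
        particles.append(Particle(x=x, v=v, pbest=x.copy(), pbest_fit=f))
        if f < gbest_fit:
            gbest, gbest_fit = x.copy(), f
    return Swarm(particles=particles, gbest=gbest, gbest_fit=gbest_fit,
                 history=[gbest_fit])


def pso_step(swarm: Swarm, fitness, rng: np.random.Generator) -> Swarm:
    """One synchronous update of every particle.

    Per particle: draw ``e1, e2 ~ U(0, 2)``, derive the inertia from
    their classes, form per-dimension accelerations
    ``phi_i = e_i * U(0, 1)``, update
    ``v <- w v + phi1 (pbest - x) + phi2 (gbest - x)`` (clamped to
    +-0.5), and ``x <- clip(x + v, 0, 1)``; then refresh the personal
    and global bests.  The global-best history is non-increasing by
    construction.
    """
    if not swarm.particles:
        raise ValueError("empty swarm")
    d = swarm.gbest.size
    for p in swarm.particles:
        e1, e2 = rng.uniform(0, 2, size=2)
        w = select_inertia(classify_accel(e1), classify_accel(e2))
        phi1 = e1 * rng.random(d)
        phi2 = e2 * rng.random(d)
        p.v = w * p.v + phi1 * (p.pbest - p.x) + phi2 * (swarm.gbest - p.x)
        p.v = np.clip(p.v, -V_CLAMP, V_CLAMP)
        p.x = np.clip(p.x + p.v, 0.0, 1.0)
        f = fitness(p.x)
        if f < p.pbest_fit:
            p.pbest, p.pbest_fit = p.x.copy(), f
        if f < swarm.gbest_fit:
            swarm.gbest, swarm.gbest_fit = p.x.copy(), f
    swarm.history.append(swarm.gbest_fit)
    return swarm


@dataclass
class SelectionReport:
    mask: np.ndarray
    weights: np.ndarray
    history: list[float]
    seed: int


class LVPSOSelector:
    """Feature selector: PSO over soft masks scored by LVQ error.

    Parameters mirror the swarm configuration.  After ``fit``:
    ``mask_`` (boolean, at least one feature), ``weights_`` (the
    global-best position), ``history_`` (per-iteration best fitness),
    ``support_`` alias of ``mask_``.
    """

    def __init__(self, n_particles: int = 15, n_iter: int = 25,
                 threshold: float = 0.5, lvq_epochs: int = 10,
                 n_bins: int = 10, seed: int = 0):
        self.n_particles = n_particles
        self.n_iter = n_iter
        self.threshold = threshold
        self.lvq_epochs = lvq_epochs
        self.n_bins = n_bins
        self.seed = seed

    def fit(self, X, y) -> "LVPSOSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        d = X.shape[1]
        if d < 2:
            # nothing to search over
            self.mask_ = np.ones(d, dtype=bool)
            self.weights_ = np.ones(d)
            self.history_ = []
            self.support_ = self.mask_
            return self
        # standardize so weight magnitudes are comparable across features
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        gains = info_gain(Xs, y, self.n_bins)
        rng = np.random.default_rng(self.seed)

        def fitness(w):
            return lvq_fitness(Xs, y, w, gains=gains,
                               epochs=self.lvq_epochs, seed=self.seed)

        informed = [np.ones(d),
                    0.5 + 0.5 * gains / (gains.max() + 1e-12)]
        swarm = init_swarm(self.n_particles, d, fitness, rng,
                           informed=informed)
        for _ in range(self.n_iter):
            pso_step(swarm, fitness, rng)
        mask = swarm.gbest > self.threshold
        if not mask.any():
            mask[int(np.argmax(swarm.gbest))] = True
        self.mask_ = mask
        self.weights_ = swarm.gbest
        self.history_ = list(swarm.history)
        self.support_ = mask
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.mask_]

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        return self.mask_

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_particles", "n_iter", "threshold", "lvq_epochs",
                 "n_bins", "seed")}

    def set_params(self, **params) -> "LVPSOSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def select_features(X: np.ndarray, y: np.ndarray, n_particles: int = 15,
                    n_iter: int = 25, threshold: float = 0.5, seed: int = 0
                    ) -> tuple[np.ndarray, SelectionReport]:
    """Functional front end over :class:`LVPSOSelector`."""
    sel = LVPSOSelector(n_particles=n_particles, n_iter=n_iter,
                        threshold=threshold, seed=seed).fit(X, y)
    return sel.mask_, SelectionReport(mask=sel.mask_, weights=sel.weights_,
                                      history=sel.history_, seed=seed)
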