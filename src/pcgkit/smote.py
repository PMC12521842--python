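"""Synthetic minority oversampling (SMOTE) for the feature table.

Minority-class rows are augmented with points drawn uniformly on the line
segments joining each minority sample to one of its k nearest same-class
neighbours (Euclidean metric): ``x_new = x + alpha * (x_nn - x)`` with
``alpha ~ U(0, 1)``.  Interpolating rather than duplicating keeps the
synthetic points inside the convex hull of the minority class while still
widening its empirical support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureTable


@dataclass
class SmoteConfig:
    k: int = 5
    target: str | dict[str, int] = "match-majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


class SMOTEResampler:
    """Oversample minority classes by segment interpolation.

    Parameters
    ----------
    k : int
        Number of nearest same-class neighbours to interpolate toward.
        Must be smaller than every oversampled class's size.
    target : "match-majority" or dict
        Per-class output counts; the default grows every non-majority
        class to the majority count.
    seed : int
        Seed for neighbour choice and interpolation coefficients.

    Attributes
    ----------
    sample_indices_ : ndarray
        For each output row, the index of the original row it derives
        from (its base point, for synthetic rows).
    synthetic_ : ndarray of bool
        Flags the generated rows; originals are always preserved first.
    """

    def __init__(self, k: int = 5, target="match-majority", seed: int = 0):
        self.k = k
        self.target = target
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes to oversample")
        majority = counts.max()
        if self.target == "match-majority":
            targets = {c: majority for c in classes}
        else:
            targets = {c: int(self.target.get(c, n))
                       for c, n in zip(classes, counts)}
        rng = np.random.default_rng(self.seed)
        out_X = [X]
        out_y = [y]
        base_idx = [np.arange(X.shape[0])]
        flags = [np.zeros(X.shape[0], dtype=bool)]
        for c, n in zip(classes, counts):
            n_new = targets[c] - n
            if n_new <= 0:
                continue
            if n <= self.k:
                raise ValueError(
                    f"class {c!r} has {n} samples; need more than k={self.k}")
            idx = np.where(y == c)[0]
            Xc = X[idx]
            # k nearest same-class neighbours, distance ties broken by
            # row index (stable sort), self excluded
            d = cdist(Xc, Xc)
            np.fill_diagonal(d, np.inf)
            nn = np.argsort(d, axis=1, kind="stable")[:, : self.k]
            base = rng.integers(0, n, size=n_new)
            pick = rng.integers(0, self.k, size=n_new)
            alpha = rng.random(n_new)
            neigh = nn[base, pick]
            synth = Xc[base] + alpha[:, None] * (Xc[neigh] - Xc[base])
            out_X.append(synth)
            out_y.append(np.full(n_new, c, dtype=y.dtype))
            base_idx.append(idx[base])
            flags.append(np.ones(n_new, dtype=bool))
        self.sample_indices_ = np.concatenate(base_idx)
        self.synthetic_ = np.concatenate(flags)
        return np.vstack(out_X), np.concatenate(out_y)

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "target": self.target, "seed": self.seed}

    def set_params(self, **params) -> "SMOTEResampler":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def smote_oversample(table: FeatureTable, cfg: SmoteConfig | None = None
                     ) -> FeatureTable:
    """Oversample a labelled feature table; adds a ``synthetic`` flag."""
    cfg = cfg or SmoteConfig()
    rs = SMOTEResampler(k=cfg.k, target=cfg.target, seed=cfg.seed)
    X, y = rs.fit_resample(table.X, table.y)
    n_new = X.shape[0] - table.X.shape[0]
    ids = list(table.record_ids) + [f"synthetic-{i:05d}" for i in range(n_new)]
    out = FeatureTable(X=X, feature_names=list(table.feature_names),
                       y=y, record_ids=ids)
    out.synthetic = rs.synthetic_
    return out
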