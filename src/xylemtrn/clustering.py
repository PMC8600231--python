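"""Fuzzy c-means soft clustering of standardized expression profiles.

Classic Bezdek alternating optimization: with fuzzifier m > 1, memberships
u_ik and centers v_k minimize sum_ik u_ik^m ||x_i - v_k||^2 subject to
row-stochastic u.  The objective is non-increasing across iterations and the
memberships of every profile sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class FuzzyCMeansResult:
    memberships: np.ndarray  # (n, c), rows sum to 1
    centers: np.ndarray  # (c, d)
    objective: list[float]  # per-iteration objective values
    n_iter: int

    @property
    def hard_labels(self) -> np.ndarray:
        """Argmax membership per profile; ties broken by lowest cluster index."""
        return np.argmax(self.memberships, axis=1)


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FuzzyCMeansResult:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"profiles must be a 2-D array, got shape {X.shape}")
    n, d = X.shape
    if c < 2:
        raise ValidationError(f"need at least 2 clusters, got c={c}")
    if n < c:
        raise ValidationError(f"need at least c={c} profiles, got {n}")
    if m <= 1.0:
        raise ValidationError(f"fuzzifier m must exceed 1, got {m}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("profiles contain non-finite values")

    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)

    objective: list[float] = []
    exponent = 1.0 / (m - 1.0)
    for it in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        objective.append(float((um * d2).sum()))
        inv = d2 ** (-exponent)
        new_u = inv / inv.sum(axis=1, keepdims=True)
        shift = float(np.abs(new_u - u).max())
        u = new_u
        if shift < tol:
            break
    um = u**m
    centers = (um.T @ X) / um.sum(axis=0)[:, None]
    return FuzzyCMeansResult(memberships=u, centers=centers, objective=objective, n_iter=it)
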