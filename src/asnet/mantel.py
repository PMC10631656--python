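"""Mantel and partial Mantel permutation tests for distance matrices.

The Mantel statistic is the Pearson correlation between the strictly-lower-
triangle vectors of two symmetric distance matrices.  Significance comes from
permuting object labels (simultaneous row/column permutation of one matrix),
which preserves the internal dependence structure of each matrix.  Tests are
one-tailed against the positive (isolation-by-distance) alternative:

    p = (#{permuted r >= observed r} + 1) / (permutations + 1)

so with 1000 permutations the smallest attainable p is 1/1001.

The partial Mantel test correlates the residuals of X and Y after regressing
each on a third matrix Z; permutations relabel X's objects and re-residualize
each draw.  The masked ("threshold-matrix") variant restricts the correlation
to a fixed set of pairs — those connected in a thresholded network — while
permutations relabel the nodes and re-read values at the same mask positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedCorrelationError(ValueError):
    """A correlation input vector is constant (or too short)."""


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    permutations: int
    masked: bool
    seed: int


def _as_square(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(M), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return M


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant distance vector")
    return float((xc * yc).sum() / (sx * sy))


def _residuals(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    zc = z - z.mean()
    denom = (zc**2).sum()
    if denom == 0:
        raise UndefinedCorrelationError("constant covariate vector")
    beta = ((x - x.mean()) * zc).sum() / denom
    return x - x.mean() - beta * zc


def _mask_indices(n: int, mask) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a mask (boolean matrix or iterable of index/id pairs already
    mapped to indices) into lower-triangle-unique (i, j) index arrays."""
    if mask is None:
        iu, ju = np.tril_indices(n, k=-1)
        return iu, ju
    mask = np.asarray(mask)
    if mask.ndim == 2 and mask.shape == (n, n):
        mask = mask.astype(bool)
        mask = mask | mask.T
        iu, ju = np.where(np.tril(mask, k=-1))
        return iu, ju
    pairs = {(max(int(a), int(b)), min(int(a), int(b))) for a, b in mask}
    if not pairs:
        return np.array([], dtype=int), np.array([], dtype=int)
    arr = np.array(sorted(pairs))
    return arr[:, 0], arr[:, 1]


def mantel(
    X,
    Y,
    permutations: int = 1000,
    seed: int = 0,
    mask=None,
) -> MantelResult:
    """One-tailed Mantel test of positive association between X and Y.

    ``mask`` (optional) restricts the correlation to the given node pairs
    (boolean matrix or iterable of index pairs); permutations relabel X's
    nodes and re-read the masked positions.
    """
    X = _as_square(X, "X")
    Y = _as_square(Y, "Y")
    if X.shape != Y.shape:
        raise ValueError("X and Y must have the same shape")
    n = X.shape[0]
    iu, ju = _mask_indices(n, mask)
    if iu.size < 3:
        raise UndefinedCorrelationError("fewer than 3 pairs in the mask")
    y = Y[iu, ju]
    r_obs = _pearson(X[iu, ju], y)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = X[perm[iu], perm[ju]]
        try:
            rp = _pearson(xp, y)
        except UndefinedCorrelationError:
            continue
        if rp >= r_obs:
            count += 1
    p = (count + 1) / (permutations + 1)
    return MantelResult(
        r=r_obs, p=float(p), permutations=permutations,
        masked=mask is not None, seed=seed,
    )


def partial_mantel(
    X,
    Y,
    Z,
    permutations: int = 1000,
    seed: int = 0,
    mask=None,
) -> MantelResult:
    """Partial Mantel: correlation of X and Y controlling for Z.

    Residual-permutation scheme: X's node labels are permuted and the
    residualization on Z recomputed each draw, while Y's residuals stay
    fixed.
    """
    X = _as_square(X, "X")
    Y = _as_square(Y, "Y")
    Z = _as_square(Z, "Z")
    if not (X.shape == Y.shape == Z.shape):
        raise ValueError("X, Y, Z must have the same shape")
    n = X.shape[0]
    iu, ju = _mask_indices(n, mask)
    if iu.size < 3:
        raise UndefinedCorrelationError("fewer than 3 pairs in the mask")
    z = Z[iu, ju]
    ry = _residuals(Y[iu, ju], z)
    rx = _residuals(X[iu, ju], z)
    # a matrix explained exactly by the covariate leaves zero residuals:
    # nothing remains to correlate, so the partial association is 0
    if np.allclose(ry, 0.0) or np.allclose(rx, 0.0):
        return MantelResult(
            r=0.0, p=1.0, permutations=permutations,
            masked=mask is not None, seed=seed,
        )
    r_obs = _pearson(rx, ry)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        xp = X[perm[iu], perm[ju]]
        try:
            rp = _pearson(_residuals(xp, z), ry)
        except UndefinedCorrelationError:
            continue
        if rp >= r_obs:
            count += 1
    p = (count + 1) / (permutations + 1)
    return MantelResult(
        r=r_obs, p=float(p), permutations=permutations,
        masked=mask is not None, seed=seed,
    )


def masked_mantel(X, Y, mask, permutations: int = 1000, seed: int = 0) -> MantelResult:
    """Mantel test over the pairs retained in a thresholded network."""
    if mask is None:
        raise ValueError("masked_mantel requires a mask")
    return mantel(X, Y, permutations=permutations, seed=seed, mask=mask)


def edge_mask(network, ids) -> np.ndarray:
    """Boolean pair mask for the edges of a network, in the order of ``ids``."""
    idx = {node: k for k, node in enumerate(ids)}
    n = len(ids)
    mask = np.zeros((n, n), dtype=bool)
    for u, v in network.edges():
        i, j = idx[u], idx[v]
        mask[i, j] = mask[j, i] = True
    return mask
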