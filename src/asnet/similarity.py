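"""Pairwise assemblage similarity: Brainerd-Robinson and Jaccard indices.

Both indices live on [0, 1]: 1 means two assemblages are perfectly similar,
0 means they share nothing.  The Brainerd-Robinson (BR) index compares count
assemblages through their within-assemblage trait proportions,

    BR(a, b) = 1 - (1/2) * sum_k |p_ak - p_bk|,

i.e. the classical 0-200 statistic divided by 200.  The Jaccard index
compares presence/absence assemblages as trait sets, |A & B| / |A | B|.
The *cultural distance* fed to the isolation-by-distance tests is 1 - S.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_io import AssemblageMatrix


class UndefinedSimilarityError(ValueError):
    """Similarity is undefined for the given pair (zero row sum / empty sets)."""


def brainerd_robinson(a, b) -> float:
    """Brainerd-Robinson similarity of two count vectors, on [0, 1].

    Proportion-based, hence invariant to scaling either assemblage's total
    count.  Raises :class:`UndefinedSimilarityError` on a zero row sum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trait vectors differ in length: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise UndefinedSimilarityError("zero row sum: proportions undefined")
    return float(1.0 - 0.5 * np.abs(a / sa - b / sb).sum())


def jaccard(a, b) -> float:
    """Jaccard similarity of two presence/absence vectors, on [0, 1]."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"trait vectors differ in length: {a.shape} vs {b.shape}")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("presence vectors must be binary")
    a = a.astype(bool)
    b = b.astype(bool)
    union = (a | b).sum()
    if union == 0:
        raise UndefinedSimilarityError("both assemblages empty: Jaccard undefined")
    return float((a & b).sum() / union)


@dataclass
class SimilarityMatrix:
    """Symmetric occupation-pair similarity with its index of origin."""

    ids: list[str]
    S: np.ndarray
    index: str  # 'BR' | 'Jaccard'

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError(f"matrix shape {self.S.shape} does not match {n} ids")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair(self, i: str, j: str) -> float:
        return float(self.S[self.ids.index(i), self.ids.index(j)])

    def max_pair(self) -> tuple[float, tuple[str, str]]:
        """Largest off-diagonal similarity and the pair achieving it."""
        M = self.S.copy()
        np.fill_diagonal(M, -np.inf)
        i, j = np.unravel_index(np.argmax(M), M.shape)
        return float(M[i, j]), (self.ids[min(i, j)], self.ids[max(i, j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        """Square CSV with the occupation IDs as header row and column."""
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, index: str = "BR") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(c) for c in df.columns], S=df.to_numpy(), index=index)


def similarity_matrix(assemblage: AssemblageMatrix) -> SimilarityMatrix:
    """Full pairwise similarity for an assemblage table.

    Counts tables get Brainerd-Robinson, presence tables get Jaccard; the
    diagonal is exactly 1.
    """
    V = assemblage.values
    if assemblage.mode == "counts":
        sums = V.sum(axis=1)
        zero = np.flatnonzero(sums <= 0)
        if zero.size:
            raise UndefinedSimilarityError(
                f"occupation {assemblage.ids[zero[0]]!r}: zero row sum"
            )
        P = V / sums[:, None]
        # BR = 1 - cityblock(p_a, p_b) / 2
        S = 1.0 - squareform(pdist(P, metric="cityblock")) / 2.0
        index = "BR"
    else:
        empty = np.flatnonzero(V.sum(axis=1) == 0)
        if empty.size:
            raise UndefinedSimilarityError(
                f"occupation {assemblage.ids[empty[0]]!r}: empty presence set"
            )
        S = 1.0 - squareform(pdist(V.astype(bool), metric="jaccard"))
        index = "Jaccard"
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=list(assemblage.ids), S=S, index=index)


def cultural_distance(sim: SimilarityMatrix) -> np.ndarray:
    """Cultural distance D = 1 - S (zero diagonal, symmetric)."""
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    return D
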