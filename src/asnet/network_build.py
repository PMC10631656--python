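"""Building Archaeological Similarity Networks (ASN).

An ASN has one node per occupation and an undirected edge between every pair
whose similarity is at or above a threshold; the edge weight *is* the
similarity value (never rescaled).  The threshold convention follows the
connectivity-preserving rule: the minimum similarity value at which the
network still forms a single connected component, optionally tolerating a few
extreme outlier nodes left outside the main component.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import AssemblageMatrix
from .similarity import SimilarityMatrix


class ThresholdInfeasibleError(ValueError):
    """No threshold keeps a big-enough component (too many outliers required)."""


@dataclass(frozen=True)
class ThresholdResult:
    """Resolved connectivity threshold and the nodes it leaves outside."""

    threshold: float
    outliers: tuple[str, ...]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 1 if n else 0

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.max_size = max(self.max_size, self.size[ra])


def connectivity_threshold(
    sim: SimilarityMatrix, max_outliers: int = 0
) -> ThresholdResult:
    """Largest observed weight t such that edges {w >= t} leave at most
    ``max_outliers`` nodes outside the largest connected component.

    With ``max_outliers=0`` this is the bottleneck (minimum edge) weight of a
    maximum spanning tree of the complete similarity graph.
    """
    n = sim.n
    if n < 2:
        raise ValueError("need at least 2 occupations")
    if max_outliers < 0:
        raise ValueError("max_outliers must be non-negative")
    target = n - max_outliers
    if target <= 1:
        # a single edge (or even an isolated node) suffices
        t, _ = sim.max_pair()
        return ThresholdResult(threshold=t, outliers=_outliers_at(sim, t))

    iu, ju = np.triu_indices(n, k=1)
    w = sim.S[iu, ju]
    order = np.argsort(-w, kind="stable")
    uf = _UnionFind(n)
    k = 0
    m = len(order)
    # process edges in descending weight, whole tie-groups at a time
    while k < m:
        t = w[order[k]]
        while k < m and w[order[k]] == t:
            e = order[k]
            uf.union(int(iu[e]), int(ju[e]))
            k += 1
        if uf.max_size >= target:
            return ThresholdResult(threshold=float(t), outliers=_outliers_at(sim, t))
    raise ThresholdInfeasibleError(
        f"no threshold leaves a component of >= {target} nodes "
        f"(n={n}, max_outliers={max_outliers})"
    )


def _outliers_at(sim: SimilarityMatrix, threshold: float) -> tuple[str, ...]:
    g = nx.Graph()
    g.add_nodes_from(range(sim.n))
    iu, ju = np.triu_indices(sim.n, k=1)
    keep = sim.S[iu, ju] >= threshold
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    giant = max(nx.connected_components(g), key=len)
    return tuple(sorted(sim.ids[i] for i in set(range(sim.n)) - giant))


def build_asn(
    sim: SimilarityMatrix,
    threshold: float,
    assemblage: AssemblageMatrix | None = None,
) -> nx.Graph:
    """Threshold graph: edges are exactly the pairs with similarity >= t.

    Every occupation stays in the node set (isolates permitted).  If the
    source assemblage is supplied its metadata is attached to the nodes.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    g = nx.Graph(threshold=float(threshold), index=sim.index)
    g.add_nodes_from(sim.ids)
    iu, ju = np.triu_indices(sim.n, k=1)
    keep = sim.S[iu, ju] >= threshold
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(sim.ids[i], sim.ids[j], weight=float(sim.S[i, j]))
    if assemblage is not None:
        for rec in assemblage.records:
            if rec.occupation_id in g:
                g.nodes[rec.occupation_id].update(
                    culture=rec.culture,
                    site_name=rec.site_name,
                    latitude=rec.latitude,
                    longitude=rec.longitude,
                    date_early=rec.date_early,
                    date_late=rec.date_late,
                    sequences=";".join(str(s) for s in sorted(rec.sequences)),
                )
    return g


def layout(
    network: nx.Graph, method: str = "fruchterman_reingold", seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Node positions: force-directed (seeded, deterministic) or geographic.

    The geographic layout maps each node to (longitude, latitude) directly;
    occupations sharing coordinates overplot, as in the source figures.
    """
    if method == "fruchterman_reingold":
        pos = nx.spring_layout(network, weight="weight", seed=seed)
        return {node: (float(x), float(y)) for node, (x, y) in pos.items()}
    if method == "geographic":
        missing = [
            n
            for n, d in network.nodes(data=True)
            if not (
                np.isfinite(d.get("longitude", np.nan))
                and np.isfinite(d.get("latitude", np.nan))
            )
        ]
        if missing:
            raise ValueError(f"nodes without coordinates: {sorted(missing)}")
        return {
            n: (float(d["longitude"]), float(d["latitude"]))
            for n, d in network.nodes(data=True)
        }
    raise ValueError(f"unknown layout method {method!r}")
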