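"""Descriptive statistics of thresholded similarity networks.

Network level: density, cluster coefficient, and normalized Freeman
centralization of the weighted degree (strength), eigenvector, and
betweenness centralities.  Node level: the three weighted centralities.
Interval statistics: min/mean/max (with the pairs achieving the extremes) of
edge weight, geographic distance, and chronological distance over the
*retained* edges.  Cultural units get density and clustering on their induced
subgraphs, plus the similarity radius — per-pair geographic distance divided
by similarity, an indicator of how far cultural traits travelled per unit of
resemblance.

Conventions (documented because the field uses several):

* strength = sum of incident edge weights;
* eigenvector = leading eigenvector of the weighted adjacency matrix (power
  iteration, tolerance 1e-10), scaled so the mean score is 1;
* betweenness = shortest-path betweenness on the binarized threshold graph,
  unnormalized, with fractional splitting among equal-length paths;
* centralization = sum(c_max - c_i) over nodes, divided by the theoretical
  maximum attained by a star graph of the same size (for eigenvector the
  scores are rescaled to max 1 before centralizing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .chronospatial import DistanceMatrices
from .data_io import CULTURAL_UNITS
from .similarity import SimilarityMatrix

CLUSTER_VARIANTS = ("transitivity", "avg_local")
DEFAULT_CLUSTER_VARIANT = "transitivity"


def density(network: nx.Graph) -> float:
    """2E / n(n-1) over the full node set, isolates included."""
    if network.number_of_nodes() < 2:
        raise ValueError("density needs at least 2 nodes")
    return nx.density(network)


def cluster_coefficient(
    network: nx.Graph, variant: str = DEFAULT_CLUSTER_VARIANT
) -> float:
    """Triangle closure of the binarized threshold graph.

    ``transitivity`` = 3 * triangles / connected triples (global);
    ``avg_local`` = mean local clustering, isolates and degree-1 nodes
    contributing 0.
    """
    if network.number_of_nodes() < 3:
        raise ValueError("cluster coefficient needs at least 3 nodes")
    if variant == "transitivity":
        return nx.transitivity(network)
    if variant == "avg_local":
        return nx.average_clustering(network, count_zeros=True)
    raise ValueError(f"unknown cluster variant {variant!r}")


def _weighted_adjacency(network: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(network.nodes())
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    return nodes, A


def _leading_eigenvector(A: np.ndarray, tol: float = 1e-10, max_iter: int = 10000):
    """Power iteration for the leading eigenvector of a symmetric
    non-negative matrix; returns the non-negative unit vector."""
    n = A.shape[0]
    if not A.any():
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    x = np.full(n, 1.0 / math.sqrt(n))
    # shift by +I: same eigenvectors, but strictly dominant leading eigenvalue
    # even on bipartite graphs, so the iteration cannot oscillate
    for _ in range(max_iter):
        y = A @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("eigenvector centrality undefined on an edgeless graph")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    return np.abs(x)


def node_centralities(network: nx.Graph) -> pd.DataFrame:
    """Per-node strength, eigenvector (mean-1 scaled), and betweenness."""
    nodes, A = _weighted_adjacency(network)
    strength = A.sum(axis=1)
    if network.number_of_edges() == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    eig = _leading_eigenvector(A)
    eig = eig / eig.mean()  # mean-1 scaling
    bet = nx.betweenness_centrality(network, normalized=False, weight=None)
    return pd.DataFrame(
        {
            "node": nodes,
            "strength": strength,
            "eigenvector": eig,
            "betweenness": [bet[n] for n in nodes],
        }
    )


def centralization(node_scores, kind: str) -> float:
    """Normalized Freeman centralization of a centrality score vector.

    ``kind`` selects the star-graph theoretical maximum: ``degree`` (strengths
    with weights in [0,1]), ``betweenness`` (unnormalized), or ``eigenvector``
    (scores rescaled to max 1 first).
    """
    c = np.asarray(node_scores, dtype=float)
    n = c.size
    if n < 2:
        raise ValueError("centralization needs at least 2 nodes")
    if kind == "eigenvector":
        cmax = c.max()
        if cmax <= 0:
            raise ValueError("all-zero eigenvector scores")
        c = c / cmax
        denom = (n - 1) - math.sqrt(n - 1)
    elif kind == "degree":
        denom = (n - 1) * (n - 2)
    elif kind == "betweenness":
        denom = (n - 1) ** 2 * (n - 2) / 2.0
    else:
        raise ValueError(f"unknown centralization kind {kind!r}")
    if denom <= 0:
        raise ValueError(f"theoretical maximum is zero for n={n} ({kind})")
    return float((c.max() - c).sum() / denom)


@dataclass(frozen=True)
class Interval:
    """min/mean/max of a per-edge quantity, with the extreme pairs."""

    min: float
    mean: float
    max: float
    argmin: tuple[str, str] | None = None
    argmax: tuple[str, str] | None = None


def interval_stats(
    network: nx.Graph, distances: DistanceMatrices | None = None
) -> dict[str, Interval]:
    """Edge-weight (and, given distances, geographic and chronological)
    intervals over the retained edges only."""
    edges = list(network.edges(data=True))
    if not edges:
        raise ValueError("no edges retained: intervals undefined")

    def interval(values, pairs) -> Interval:
        values = np.asarray(values, dtype=float)
        lo, hi = int(np.argmin(values)), int(np.argmax(values))
        return Interval(
            min=float(values[lo]),
            mean=float(values.mean()),
            max=float(values[hi]),
            argmin=pairs[lo],
            argmax=pairs[hi],
        )

    pairs = [(u, v) for u, v, _ in edges]
    out = {"edge_weight": interval([d["weight"] for _, _, d in edges], pairs)}
    if distances is not None:
        km = [distances.pair(u, v)[0] for u, v in pairs]
        yrs = [distances.pair(u, v)[1] for u, v in pairs]
        out["geo_km"] = interval(km, pairs)
        out["chrono_years"] = interval(yrs, pairs)
    return out


def unit_stats(
    network: nx.Graph,
    members,
    cluster_variant: str = DEFAULT_CLUSTER_VARIANT,
) -> dict[str, float]:
    """Density and cluster coefficient of the induced subgraph of a unit."""
    members = [m for m in members if m in network]
    if len(members) < 2:
        raise ValueError("unit statistics need at least 2 member nodes")
    sub = network.subgraph(members)
    out = {"density": density(sub)}
    out["cluster_coefficient"] = (
        cluster_coefficient(sub, cluster_variant) if len(members) >= 3 else np.nan
    )
    return out


def similarity_radius(
    members,
    sim: SimilarityMatrix,
    distances: DistanceMatrices,
    network: nx.Graph | None = None,
) -> dict[str, float]:
    """Per-pair radius = geographic km / similarity over within-unit pairs.

    Passing a network restricts to pairs connected in it (threshold scope).
    A zero-distance pair has radius 0; a zero-similarity pair at positive
    distance has radius +inf.  An empty pair set yields the degenerate
    (min=+inf, mean=nan, max=-inf) triple, kept in-band deliberately: a unit
    represented by a single occupation reports exactly that.
    """
    members = list(members)
    radii = []
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            i, j = members[a], members[b]
            if network is not None and not network.has_edge(i, j):
                continue
            km, _ = distances.pair(i, j)
            s = sim.pair(i, j)
            if km == 0.0:
                radii.append(0.0)
            elif s == 0.0:
                radii.append(math.inf)
            else:
                radii.append(km / s)
    if not radii:
        return {"min": math.inf, "mean": math.nan, "max": -math.inf}
    arr = np.asarray(radii)
    return {"min": float(arr.min()), "mean": float(arr.mean()), "max": float(arr.max())}


@dataclass
class StatsReport:
    """All descriptive statistics for one network, as writable tables."""

    network_level: dict[str, float]
    node_level: pd.DataFrame
    intervals: dict[str, Interval]
    unit_level: pd.DataFrame
    meta: dict[str, str] = field(default_factory=dict)

    def network_level_frame(self) -> pd.DataFrame:
        rows = [{"statistic": k, "value": v} for k, v in self.network_level.items()]
        for name, iv in self.intervals.items():
            for stat in ("min", "mean", "max"):
                rows.append({"statistic": f"{name}_{stat}", "value": getattr(iv, stat)})
            if iv.argmin is not None:
                rows.append(
                    {"statistic": f"{name}_argmin", "value": "-".join(iv.argmin)}
                )
                rows.append(
                    {"statistic": f"{name}_argmax", "value": "-".join(iv.argmax)}
                )
        for k, v in self.meta.items():
            rows.append({"statistic": f"meta_{k}", "value": v})
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def node_level_frame(self) -> pd.DataFrame:
        return self.node_level.copy()

    def unit_level_frame(self) -> pd.DataFrame:
        return self.unit_level.copy()


def compute_stats(
    network: nx.Graph,
    sim: SimilarityMatrix,
    distances: DistanceMatrices | None = None,
    cluster_variant: str = DEFAULT_CLUSTER_VARIANT,
    units: dict[str, tuple[str, ...]] | None = None,
) -> StatsReport:
    """Full statistics report for one ASN.

    ``units`` maps unit names to culture codes; by default the three main
    cultural units plus each regional culture on its own.  Units with too few
    members report NaN rather than aborting the run.
    """
    nodes = list(network.nodes())
    cent = node_centralities(network)
    net_level = {
        "n_nodes": float(network.number_of_nodes()),
        "n_edges": float(network.number_of_edges()),
        "threshold": float(network.graph.get("threshold", np.nan)),
        "density": density(network),
        "cluster_coefficient": cluster_coefficient(network, cluster_variant),
        "centralization_degree": centralization(cent["strength"], "degree"),
        "centralization_eigen": centralization(cent["eigenvector"], "eigenvector"),
        "centralization_betweenness": centralization(
            cent["betweenness"], "betweenness"
        ),
    }
    intervals = interval_stats(network, distances) if network.number_of_edges() else {}

    if units is None:
        cultures_present = sorted(
            {network.nodes[n].get("culture", "NONE") for n in nodes} - {"NONE"}
        )
        units = {name: codes for name, codes in CULTURAL_UNITS.items()}
        units.update({c: (c,) for c in cultures_present})

    rows = []
    for name, codes in units.items():
        members = [n for n in nodes if network.nodes[n].get("culture") in codes]
        row: dict[str, object] = {"unit": name, "n_members": len(members)}
        try:
            row.update(unit_stats(network, members, cluster_variant))
        except ValueError:
            row.update({"density": np.nan, "cluster_coefficient": np.nan})
        if distances is not None:
            for scope, net in (("full", None), ("threshold", network)):
                rad = similarity_radius(members, sim, distances, network=net)
                for stat in ("min", "mean", "max"):
                    row[f"radius_{scope}_{stat}"] = rad[stat]
        rows.append(row)
    unit_level = pd.DataFrame(rows)

    return StatsReport(
        network_level=net_level,
        node_level=cent,
        intervals=intervals,
        unit_level=unit_level,
        meta={
            "cluster_variant": cluster_variant,
            "centralization": "freeman_star_normalized",
            "eigenvector_scaling": "mean_1",
        },
    )
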