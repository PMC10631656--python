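"""End-to-end orchestration: similarity -> threshold -> networks -> statistics
-> time-sequential subsets -> Mantel tests, from one serializable config.

Every run writes a provenance file next to its outputs with the resolved
configuration — including auto-selected thresholds — so a published run can
be reproduced exactly by pinning those values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chronospatial import distance_matrices, sequence_pair_subset
from .data_io import AssemblageMatrix, read_assemblage, write_network, write_stats
from .mantel import edge_mask, mantel, partial_mantel
from .network_build import build_asn, connectivity_threshold, layout
from .network_stats import DEFAULT_CLUSTER_VARIANT, compute_stats
from .similarity import cultural_distance, similarity_matrix

logger = logging.getLogger("asnet")

SCOPES = ("all", "12", "23")


@dataclass
class RunConfig:
    """One dataset through the whole workflow."""

    input: str
    mode: str  # 'counts' | 'presence'
    out_dir: str = "asn_out"
    worksheet: str | int | None = None
    schema: dict = field(default_factory=dict)
    threshold: dict = field(default_factory=lambda: {s: "auto" for s in SCOPES})
    max_outliers: int = 0
    cluster_variant: str = DEFAULT_CLUSTER_VARIANT
    chrono_method: str = "euclidean2d"
    scopes: tuple = SCOPES
    mantel_permutations: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("threshold", {s: "auto" for s in SCOPES})
        if not isinstance(raw["threshold"], dict):
            raw["threshold"] = {s: raw["threshold"] for s in SCOPES}
        raw["scopes"] = tuple(str(s) for s in raw.get("scopes", SCOPES))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


MANTEL_ROWS = (
    # (label, x, y, covariate, masked)
    ("cultural_vs_geo", "geo", None, False),
    ("cultural_vs_geo_threshold", "geo", None, True),
    ("cultural_vs_geo_given_chrono", "geo", "chrono", False),
    ("cultural_vs_geo_given_chrono_threshold", "geo", "chrono", True),
    ("cultural_vs_chrono", "chrono", None, False),
    ("cultural_vs_chrono_threshold", "chrono", None, True),
    ("cultural_vs_chrono_given_geo", "chrono", "geo", False),
    ("cultural_vs_chrono_given_geo_threshold", "chrono", "geo", True),
)


def mantel_table(
    cult, geo, chrono, network, ids, permutations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Isolation-by-distance test battery: the eight simple/partial x
    full/threshold combinations of cultural vs geographic/chronological
    distance."""
    mask = edge_mask(network, ids)
    mats = {"geo": geo, "chrono": chrono}
    rows = []
    for label, y, cov, masked in MANTEL_ROWS:
        kwargs = dict(
            permutations=permutations, seed=seed, mask=mask if masked else None
        )
        try:
            if cov is None:
                res = mantel(cult, mats[y], **kwargs)
            else:
                res = partial_mantel(cult, mats[y], mats[cov], **kwargs)
            rows.append(
                {"test": label, "r": res.r, "p": res.p,
                 "permutations": res.permutations, "masked": res.masked}
            )
        except ValueError as exc:
            rows.append(
                {"test": label, "r": float("nan"), "p": float("nan"),
                 "permutations": permutations, "masked": masked,
                 "note": str(exc)}
            )
    return pd.DataFrame(rows)


def _resolve_threshold(config: RunConfig, scope: str, sim):
    spec = config.threshold.get(scope, "auto")
    if spec == "auto":
        result = connectivity_threshold(sim, max_outliers=config.max_outliers)
        return result.threshold, list(result.outliers), "auto"
    return float(spec), [], "explicit"


def run_full(
    config: RunConfig, assemblage: AssemblageMatrix | None = None
) -> dict[str, dict]:
    """Run the whole workflow; returns a summary dict (also written to disk).

    For each requested scope (full dataset, sequences 1-2, sequences 2-3):
    similarity matrix, distances, resolved threshold, network (GraphML + edge
    list), layouts, statistics tables, and the Mantel test battery.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)

    try:
        if assemblage is None:
            assemblage, report = read_assemblage(
                config.input, config.mode,
                schema=config.schema or None, worksheet=config.worksheet,
            )
            logger.info("loaded %d occupations from %s", report.n_loaded, config.input)
            for occ, problems in report.flagged.items():
                logger.warning("flagged %s: %s", occ, "; ".join(problems))

        summary: dict[str, dict] = {}
        resolved_thresholds: dict[str, float] = {}
        for scope in config.scopes:
            try:
                subset = (
                    assemblage
                    if scope == "all"
                    else sequence_pair_subset(assemblage, scope)
                )
            except ValueError as exc:
                raise RuntimeError(f"stage subset[{scope}]: {exc}") from exc

            tag = f"{config.mode}_{scope}"
            try:
                sim = similarity_matrix(subset)
                dist = distance_matrices(subset, config.chrono_method)
                thr, outliers, thr_mode = _resolve_threshold(config, scope, sim)
                net = build_asn(sim, thr, subset)
                stats = compute_stats(
                    net, sim, dist, cluster_variant=config.cluster_variant
                )
                for u, v in net.edges():
                    km, yrs = dist.pair(u, v)
                    net.edges[u, v].update(km=km, years=yrs)
                fr = layout(net, "fruchterman_reingold", seed=config.seed)
                geo_pos = layout(net, "geographic")
                mtable = mantel_table(
                    cultural_distance(sim), dist.geo_km, dist.chrono_years,
                    net, sim.ids,
                    permutations=config.mantel_permutations, seed=config.seed,
                )
            except Exception as exc:
                raise RuntimeError(f"stage analysis[{scope}]: {exc}") from exc

            sim.to_csv(out_dir / f"{tag}_similarity.csv")
            pd.DataFrame(dist.geo_km, index=dist.ids, columns=dist.ids).to_csv(
                out_dir / f"{tag}_geo_km.csv"
            )
            pd.DataFrame(
                dist.chrono_years, index=dist.ids, columns=dist.ids
            ).to_csv(out_dir / f"{tag}_chrono_years.csv")
            write_network(net, out_dir / f"{tag}_network.graphml", "graphml")
            write_network(net, out_dir / f"{tag}_edges.csv", "edgelist_csv")
            write_stats(stats, out_dir, prefix=tag)
            pd.DataFrame(
                [
                    {"node": n, "fr_x": fr[n][0], "fr_y": fr[n][1],
                     "geo_x": geo_pos[n][0], "geo_y": geo_pos[n][1]}
                    for n in net.nodes()
                ]
            ).to_csv(out_dir / f"{tag}_layout.csv", index=False)
            mtable.to_csv(out_dir / f"{tag}_mantel.csv", index=False)

            resolved_thresholds[scope] = thr
            summary[scope] = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "threshold": thr,
                "threshold_mode": thr_mode,
                "outliers": outliers,
                "density": stats.network_level["density"],
                "cluster_coefficient": stats.network_level["cluster_coefficient"],
            }
            logger.info(
                "scope %s: threshold %.4f (%s), %d nodes, %d edges",
                scope, thr, thr_mode,
                net.number_of_nodes(), net.number_of_edges(),
            )

        provenance = asdict(config)
        provenance["resolved_thresholds"] = resolved_thresholds
        provenance["scopes"] = list(config.scopes)
        with open(out_dir / "provenance.yaml", "w") as out:
            yaml.safe_dump(provenance, out, sort_keys=False)
        with open(out_dir / "summary.json", "w") as out:
            json.dump(summary, out, indent=2)
        return summary
    finally:
        logger.removeHandler(fh)
        fh.close()
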