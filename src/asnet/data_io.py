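"""Reading and writing occupation/trait tables, networks, and statistic reports.

An *occupation* is a dated stratigraphic unit at an archaeological site; one
site may contribute several occupations.  Each occupation carries a cultural
affiliation (one of seven Early Neolithic Western-Mediterranean archaeological
cultures, or ``NONE`` for unaffiliated occupations), WGS84 coordinates, a
calibrated date range (cal BP, so the *early* bound is numerically larger),
and membership in one or more of three time sequences.

Assemblage tables come in two modes: trait *counts* (e.g. pottery decorative
techniques) and trait *presence/absence* (e.g. mutually exclusive bead types).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Archaeological culture codes used by the study datasets.  ``NONE`` marks an
#: occupation outside the seven named cultures (kept in networks, excluded
#: from per-cultural-unit statistics).
CULTURES = ("IMP", "TyC", "RPC", "LCC", "VC", "LCE", "VE", "NONE")

#: Main cultural units grouping the regional archaeological cultures.
CULTURAL_UNITS: dict[str, tuple[str, ...]] = {
    "Impressa": ("IMP",),
    "Cardial": ("TyC", "RPC", "LCC", "VC"),
    "Epicardial": ("LCE", "VE"),
}

#: Default column mapping for the study spreadsheet schema.  Override any
#: entry via the ``schema`` argument of :func:`read_assemblage`.
DEFAULT_SCHEMA: dict[str, str] = {
    "occupation_id": "occupation_id",
    "site_name": "site_name",
    "culture": "culture",
    "latitude": "latitude",
    "longitude": "longitude",
    "date_early": "date_early",
    "date_late": "date_late",
    "sequences": "sequences",
}

METADATA_FIELDS = tuple(DEFAULT_SCHEMA)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class ValidationError(ValueError):
    """A value violates the assemblage-table invariants."""


@dataclass(frozen=True)
class OccupationRecord:
    """Metadata for one archaeological occupation."""

    occupation_id: str
    site_name: str = ""
    culture: str = "NONE"
    latitude: float = np.nan
    longitude: float = np.nan
    date_early: float = np.nan
    date_late: float = np.nan
    sequences: frozenset[int] = frozenset()

    def validate(self, date_bounds: tuple[float, float] | None = None) -> list[str]:
        """Return a list of problems (empty if the record is internally valid)."""
        problems = []
        if not self.occupation_id:
            problems.append("empty occupation_id")
        if self.culture not in CULTURES:
            problems.append(f"unknown culture {self.culture!r}")
        if np.isnan(self.latitude) or np.isnan(self.longitude):
            problems.append("missing coordinates")
        else:
            if not -90.0 <= self.latitude <= 90.0:
                problems.append(f"latitude {self.latitude} outside [-90, 90]")
            if not -180.0 <= self.longitude <= 180.0:
                problems.append(f"longitude {self.longitude} outside [-180, 180]")
        if np.isnan(self.date_early) or np.isnan(self.date_late):
            problems.append("missing dates")
        else:
            if self.date_early < self.date_late:
                problems.append(
                    f"date_early {self.date_early} < date_late {self.date_late}"
                    " (cal BP counts backwards)"
                )
            if date_bounds is not None:
                lo, hi = date_bounds
                if not (lo <= self.date_late and self.date_early <= hi):
                    problems.append(f"dates outside bounds [{lo}, {hi}]")
        if not self.sequences:
            problems.append("no sequence membership")
        elif not self.sequences <= {1, 2, 3}:
            problems.append(f"sequences {sorted(self.sequences)} outside {{1,2,3}}")
        return problems


@dataclass
class LoadReport:
    """What happened while loading a table: nothing is ever silently dropped."""

    n_loaded: int = 0
    flagged: dict[str, list[str]] = field(default_factory=dict)

    def flag(self, occupation_id: str, problems: list[str]) -> None:
        if problems:
            self.flagged.setdefault(occupation_id, []).extend(problems)


@dataclass
class AssemblageMatrix:
    """Occupations x traits table with per-occupation metadata.

    ``mode='counts'`` requires non-negative integers with positive row sums;
    ``mode='presence'`` requires 0/1 values.
    """

    records: list[OccupationRecord]
    traits: list[str]
    values: np.ndarray
    mode: str  # 'counts' | 'presence'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("counts", "presence"):
            raise ValueError(f"mode must be 'counts' or 'presence', got {self.mode!r}")
        if self.values.shape != (len(self.records), len(self.traits)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.records)} records x {len(self.traits)} traits"
            )
        ids = [r.occupation_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate occupation ids: {dupes}")
        self._validate_values()

    def _validate_values(self) -> None:
        for i, rec in enumerate(self.records):
            row = self.values[i]
            if self.mode == "counts":
                bad = np.flatnonzero((row < 0) | (row != np.round(row)))
                if bad.size:
                    raise ValidationError(
                        f"occupation {rec.occupation_id!r}, trait "
                        f"{self.traits[bad[0]]!r}: counts must be non-negative "
                        f"integers (got {row[bad[0]]})"
                    )
                if row.sum() <= 0:
                    raise ValidationError(
                        f"occupation {rec.occupation_id!r}: zero row sum in counts mode"
                    )
            else:
                bad = np.flatnonzero(~np.isin(row, (0.0, 1.0)))
                if bad.size:
                    raise ValidationError(
                        f"occupation {rec.occupation_id!r}, trait "
                        f"{self.traits[bad[0]]!r}: presence values must be 0/1 "
                        f"(got {row[bad[0]]})"
                    )

    @property
    def ids(self) -> list[str]:
        return [r.occupation_id for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def record(self, occupation_id: str) -> OccupationRecord:
        for rec in self.records:
            if rec.occupation_id == occupation_id:
                return rec
        raise KeyError(occupation_id)

    def subset(self, keep_ids: Iterable[str]) -> "AssemblageMatrix":
        keep = set(keep_ids)
        idx = [i for i, r in enumerate(self.records) if r.occupation_id in keep]
        if not idx:
            raise ValueError("subset would be empty")
        return AssemblageMatrix(
            records=[self.records[i] for i in idx],
            traits=list(self.traits),
            values=self.values[idx],
            mode=self.mode,
        )

    def to_frame(self) -> pd.DataFrame:
        """Metadata columns followed by one column per trait."""
        meta = pd.DataFrame(
            {
                "occupation_id": [r.occupation_id for r in self.records],
                "site_name": [r.site_name for r in self.records],
                "culture": [r.culture for r in self.records],
                "latitude": [r.latitude for r in self.records],
                "longitude": [r.longitude for r in self.records],
                "date_early": [r.date_early for r in self.records],
                "date_late": [r.date_late for r in self.records],
                "sequences": [
                    ";".join(str(s) for s in sorted(r.sequences)) for r in self.records
                ],
            }
        )
        traits = pd.DataFrame(self.values, columns=self.traits).astype(int)
        return pd.concat([meta, traits], axis=1)


def _parse_sequences(raw) -> frozenset[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    if isinstance(raw, (int, np.integer)):
        return frozenset({int(raw)})
    tokens = str(raw).replace(",", ";").replace("|", ";").split(";")
    out = set()
    for tok in tokens:
        tok = tok.strip()
        if tok:
            out.add(int(float(tok)))
    return frozenset(out)


def _read_table(path: Path, worksheet: str | int | None) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=worksheet if worksheet is not None else 0)
    return pd.read_csv(path)


def read_assemblage(
    path: str | Path,
    mode: str,
    schema: Mapping[str, str] | None = None,
    worksheet: str | int | None = None,
    date_bounds: tuple[float, float] | None = None,
) -> tuple[AssemblageMatrix, LoadReport]:
    """Read an occupation x trait table from CSV or XLSX.

    Columns named in the (possibly overridden) schema are metadata; every
    remaining column is a trait.  Rows with missing coordinates or dates are
    loaded but flagged in the returned :class:`LoadReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = _read_table(path, worksheet)
    missing = [schema[f] for f in ("occupation_id",) if schema[f] not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s) {missing} in {path}")

    trait_cols = [c for c in df.columns if c not in set(schema.values())]
    if not trait_cols:
        raise SchemaError(f"no trait columns found in {path}")

    def col(row, name, default=np.nan):
        c = schema[name]
        if c not in df.columns:
            return default
        v = row[c]
        return default if pd.isna(v) else v

    report = LoadReport()
    records = []
    for _, row in df.iterrows():
        rec = OccupationRecord(
            occupation_id=str(row[schema["occupation_id"]]),
            site_name=str(col(row, "site_name", "")),
            culture=str(col(row, "culture", "NONE")),
            latitude=float(col(row, "latitude")),
            longitude=float(col(row, "longitude")),
            date_early=float(col(row, "date_early")),
            date_late=float(col(row, "date_late")),
            sequences=_parse_sequences(
                row[schema["sequences"]] if schema["sequences"] in df.columns else None
            ),
        )
        report.flag(rec.occupation_id, rec.validate(date_bounds))
        records.append(rec)

    values = df[trait_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"occupation {records[i].occupation_id!r}, trait {trait_cols[j]!r}: "
            "missing trait value"
        )
    matrix = AssemblageMatrix(records=records, traits=trait_cols, values=values, mode=mode)
    report.n_loaded = matrix.n
    return matrix, report


def write_assemblage(assemblage: AssemblageMatrix, path: str | Path) -> None:
    """Write the table in the same schema :func:`read_assemblage` reads."""
    path = Path(path)
    df = assemblage.to_frame()
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Networks


def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write an archaeological similarity network (ASN).

    GraphML carries all node attributes and the edge ``weight``; the CSV edge
    list has columns ``source,target,weight[,km,years]`` and loses node
    metadata (use GraphML for lossless round trips).
    """
    path = Path(path)
    if format == "graphml":
        g = network.copy()
        for _, data in g.nodes(data=True):
            if "sequences" in data and not isinstance(data["sequences"], str):
                data["sequences"] = ";".join(str(s) for s in sorted(data["sequences"]))
            for k, v in list(data.items()):
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    del data[k]
        nx.write_graphml(g, path)
    elif format == "edgelist_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            extra = ["km", "years"]
            has_extra = any(
                "km" in d or "years" in d for _, _, d in network.edges(data=True)
            )
            header = ["source", "target", "weight"] + (extra if has_extra else [])
            writer.writerow(header)
            for u, v, d in sorted(network.edges(data=True)):
                row = [u, v, repr(float(d["weight"]))]
                if has_extra:
                    row += [repr(float(d.get("km", np.nan))),
                            repr(float(d.get("years", np.nan)))]
                writer.writerow(row)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Inverse of :func:`write_network`; round trips are value-identical."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return g
    if format == "edgelist_csv":
        g = nx.Graph()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                attrs = {"weight": float(row["weight"])}
                for k in ("km", "years"):
                    if k in row and row[k] not in (None, ""):
                        attrs[k] = float(row[k])
                g.add_edge(row["source"], row["target"], **attrs)
        return g
    raise ValueError(f"unknown network format {format!r}")


def write_stats(report, out_dir: str | Path, prefix: str = "asn") -> dict[str, Path]:
    """Write a :class:`~asnet.network_stats.StatsReport` as three CSV tables.

    Returns the written paths keyed ``network``, ``nodes``, ``units``.
    Column order is deterministic and floats keep full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    net = report.network_level_frame()
    p = out_dir / f"{prefix}_network_stats.csv"
    net.to_csv(p, index=False, float_format=None)
    paths["network"] = p

    nodes = report.node_level_frame()
    p = out_dir / f"{prefix}_node_stats.csv"
    nodes.to_csv(p, index=False)
    paths["nodes"] = p

    units = report.unit_level_frame()
    p = out_dir / f"{prefix}_unit_stats.csv"
    units.to_csv(p, index=False)
    paths["units"] = p
    return paths
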