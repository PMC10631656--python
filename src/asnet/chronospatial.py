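"""Geographic and chronological pairwise distances; time-sequence handling.

Geographic distance is the great-circle (haversine) distance on a sphere of
radius 6371.0 km.  Chronological distance between two occupations compares
their calibrated date ranges (cal BP); three conventions are provided:

``euclidean2d`` (default)
    Euclidean distance between the (early, late) range vectors, divided by
    sqrt(2) so that two ranges shifted rigidly by *d* years are *d* years
    apart.
``gap``
    0 if the ranges overlap, else the separation between them.
``midpoint``
    Absolute difference of range midpoints.

The study splits its 1,500-year span into three overlapping time sequences;
an occupation belongs to every sequence its date range overlaps, unless the
dataset carries a curated label (which wins, because the windows overlap and
date-only assignment is not unique).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import AssemblageMatrix, OccupationRecord

EARTH_RADIUS_KM = 6371.0

CHRONO_METHODS = ("euclidean2d", "gap", "midpoint")


@dataclass(frozen=True)
class SequenceWindow:
    """One time sequence: ``start >= end`` in cal BP (BP counts backwards)."""

    id: int
    start: float
    end: float

    def overlaps(self, date_early: float, date_late: float) -> bool:
        return date_early >= self.end and date_late <= self.start


#: The study's three sequences: pioneer farming (8000-7600 BP), expansion and
#: style diversification (7650-6800 BP), late Early Neolithic (7000-6500 BP).
DEFAULT_WINDOWS = (
    SequenceWindow(1, 8000.0, 7600.0),
    SequenceWindow(2, 7650.0, 6800.0),
    SequenceWindow(3, 7000.0, 6500.0),
)


@dataclass
class DistanceMatrices:
    """Paired geographic (km) and chronological (years) distance matrices."""

    ids: list[str]
    geo_km: np.ndarray
    chrono_years: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("geo_km", "chrono_years"):
            M = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, M)
            if M.shape != (n, n):
                raise ValueError(f"{name} shape {M.shape} does not match {n} ids")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if (M < 0).any():
                raise ValueError(f"{name} must be non-negative")

    def pair(self, i: str, j: str) -> tuple[float, float]:
        a, b = self.ids.index(i), self.ids.index(j)
        return float(self.geo_km[a, b]), float(self.chrono_years[a, b])


def _check_coords(lat: float, lon: float) -> None:
    if not (np.isfinite(lat) and np.isfinite(lon)):
        raise ValueError("missing coordinate")
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinate ({lat}, {lon})")


def great_circle_km(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def chrono_distance(
    r1: Sequence[float], r2: Sequence[float], method: str = "euclidean2d"
) -> float:
    """Chronological distance in years between two (early, late) cal BP ranges."""
    e1, l1 = float(r1[0]), float(r1[1])
    e2, l2 = float(r2[0]), float(r2[1])
    for e, l in ((e1, l1), (e2, l2)):
        if not (np.isfinite(e) and np.isfinite(l)) or e < l:
            raise ValueError(f"invalid date range ({e}, {l})")
    if method == "euclidean2d":
        return float(np.hypot(e1 - e2, l1 - l2) / np.sqrt(2.0))
    if method == "gap":
        if e1 >= l2 and l1 <= e2:  # ranges overlap
            return 0.0
        return float(max(l1 - e2, l2 - e1))
    if method == "midpoint":
        return float(abs((e1 + l1) / 2.0 - (e2 + l2) / 2.0))
    raise ValueError(f"unknown chronological method {method!r}")


def distance_matrices(
    assemblage: AssemblageMatrix, chrono_method: str = "euclidean2d"
) -> DistanceMatrices:
    """All pairwise geographic and chronological distances for a dataset."""
    recs = assemblage.records
    lat = np.array([r.latitude for r in recs])
    lon = np.array([r.longitude for r in recs])
    for r in recs:
        _check_coords(r.latitude, r.longitude)

    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (
        np.sin(dphi / 2) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    )
    geo = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(geo, 0.0)

    n = len(recs)
    chrono = np.zeros((n, n))
    ranges = [(r.date_early, r.date_late) for r in recs]
    for i in range(n):
        for j in range(i + 1, n):
            d = chrono_distance(ranges[i], ranges[j], chrono_method)
            chrono[i, j] = chrono[j, i] = d
    return DistanceMatrices(ids=list(assemblage.ids), geo_km=geo, chrono_years=chrono)


def assign_sequences(
    record: OccupationRecord,
    windows: Iterable[SequenceWindow] = DEFAULT_WINDOWS,
) -> frozenset[int]:
    """Sequence membership: curated labels win, else date-range overlap."""
    if record.sequences:
        return record.sequences
    if not (np.isfinite(record.date_early) and np.isfinite(record.date_late)):
        raise ValueError(
            f"occupation {record.occupation_id!r}: no sequence label and no dates"
        )
    members = frozenset(
        w.id for w in windows if w.overlaps(record.date_early, record.date_late)
    )
    if not members:
        raise ValueError(
            f"occupation {record.occupation_id!r}: date range "
            f"({record.date_early}, {record.date_late}) overlaps no sequence window"
        )
    return members


def sequence_pair_subset(
    assemblage: AssemblageMatrix,
    pair: str,
    windows: Iterable[SequenceWindow] = DEFAULT_WINDOWS,
) -> AssemblageMatrix:
    """Occupations belonging to either sequence of a consecutive pair.

    ``pair`` is ``'12'`` (sequences 1-2) or ``'23'`` (sequences 2-3).
    """
    if pair not in ("12", "23"):
        raise ValueError(f"pair must be '12' or '23', got {pair!r}")
    wanted = {int(c) for c in pair}
    keep = [
        r.occupation_id
        for r in assemblage.records
        if assign_sequences(r, windows) & wanted
    ]
    if not keep:
        raise ValueError(f"no occupations in sequence pair {pair}")
    return assemblage.subset(keep)
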