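"""Geocode merging, precision filtering, region clipping and projection.

Each address may be geocoded by several providers of unequal quality.  The
merge rule is a fixed a-priori priority — a locally authoritative
parcel-based engine beats a commercial point-level service, which beats the
commercial street-segment (interpolated) service, which beats the
coordinates shipped with the data delivery.  Merged coordinates are
projected to a local transverse Mercator system (UTM 18N/NAD83 by default)
and rounded to the nearest 10 m so that 'same location' becomes an exact
equality test; locations outside the study region or below the configured
precision floor are excluded with per-year accounting, since precision
drift over calendar years is itself a finding worth reporting.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from shapely.geometry import Point, box, shape
from shapely.prepared import prep
from shapely.strtree import STRtree

from .model import (
    PRECISION_RANK,
    SOURCE_PRIORITY,
    GeocodeCandidate,
    LocationAssignment,
    Precision,
    RegistryBundle,
    RegistryError,
)
from .addressbook import YearLocationMap
from .projection import UTM_18N, TransverseMercator, round_to_grid

__all__ = [
    "merge_geocodes",
    "project_and_round",
    "resolve_locations",
    "filter_by_precision",
    "exclude_out_of_region",
    "Region",
    "ExclusionReport",
]


def merge_geocodes(candidates: Sequence[GeocodeCandidate]) -> GeocodeCandidate:
    """Pick the single best candidate for one (business, role).

    Priority is by source tier (gold_local > commercial_point >
    commercial_street > vendor_supplied); within a tier the tie-break is
    deterministic: source name, then (lat, lon) lexicographically.
    """
    if not candidates:
        raise RegistryError("merge_geocodes: empty candidate list (supply the vendor fallback)")
    roles = {(c.duns_id, c.role) for c in candidates}
    if len(roles) > 1:
        raise RegistryError(f"merge_geocodes: candidates span multiple keys {sorted(roles)}")
    return min(
        candidates,
        key=lambda c: (SOURCE_PRIORITY[c.source], c.source.value, c.lat, c.lon),
    )


def project_and_round(
    lat: float,
    lon: float,
    crs: TransverseMercator = UTM_18N,
    grid: float = 10.0,
) -> tuple[float, float]:
    """WGS84/NAD83 degrees -> planar metres rounded to the nearest ``grid`` m.

    Rounding ties go away from zero.  Points outside the nominal 6-degree
    zone width are still projected (accuracy degrades gracefully); the
    caller is expected to have clipped to the study region.
    """
    x, y = crs.forward(lat, lon)
    return round_to_grid(x, grid), round_to_grid(y, grid)


def resolve_locations(
    bundle: RegistryBundle,
    year_roles: YearLocationMap,
    crs: TransverseMercator = UTM_18N,
    grid: float = 10.0,
) -> tuple[list[LocationAssignment], list[tuple[str, int]]]:
    """Merge candidates per role and expand to one assignment per business-year.

    Returns (assignments, unresolved) where ``unresolved`` lists
    (duns_id, year) pairs whose in-force role has no geocode candidate at
    all (not even the vendor fallback).
    """
    from .model import Role

    has_move1 = {m.duns_id for m in bundle.moves if m.move_index == 1}

    def _candidates(duns_id: str, role: str):
        cands = bundle.candidates_for(duns_id, role)
        if cands or role != Role.FIRST:
            return cands
        # the first address has no delivery-supplied geocode of its own: it
        # is expected to equal the origin of move 1 (movers) or the most
        # recent address (non-movers), whose candidates stand in for it
        alt = Role.move_origin(1) if duns_id in has_move1 else Role.MOST_RECENT
        return bundle.candidates_for(duns_id, alt)

    merged: dict[tuple[str, str], GeocodeCandidate] = {}
    projected: dict[tuple[str, str], tuple[float, float]] = {}
    assignments: list[LocationAssignment] = []
    unresolved: list[tuple[str, int]] = []
    for (duns_id, year), role in year_roles.items():
        key = (duns_id, role)
        if key not in merged:
            cands = _candidates(duns_id, role)
            if not cands:
                unresolved.append((duns_id, year))
                continue
            merged[key] = merge_geocodes(cands)
            best = merged[key]
            projected[key] = project_and_round(best.lat, best.lon, crs=crs, grid=grid)
        elif key not in projected:  # pragma: no cover - defensive
            continue
        best = merged[key]
        x, y = projected[key]
        assignments.append(
            LocationAssignment(
                duns_id=duns_id, year=year, x=x, y=y,
                precision=best.precision, source=best.source,
            )
        )
    return assignments, unresolved


@dataclass
class ExclusionReport:
    """Accounting of records removed by a filtering step."""

    reason: str
    by_year: Counter = field(default_factory=Counter)
    by_source: Counter = field(default_factory=Counter)
    total: int = 0

    def add(self, a: LocationAssignment) -> None:
        self.total += 1
        self.by_year[a.year] += 1
        self.by_source[a.source.value] += 1


def filter_by_precision(
    assignments: Iterable[LocationAssignment],
    minimum: Precision = Precision.STREET_SEGMENT,
) -> tuple[list[LocationAssignment], ExclusionReport]:
    """Keep assignments geocoded at least as precisely as ``minimum``.

    The precision scale orders point > block_face > street_segment >
    block_group > tract_centroid > zip; the default floor (street segment)
    drops anything placed only to a block group, tract centroid or zip
    code, the levels too coarse for location-based deduplication.
    """
    if not isinstance(minimum, Precision):
        try:
            minimum = Precision(minimum)
        except ValueError:
            raise RegistryError(f"unknown precision level {minimum!r}") from None
    floor = PRECISION_RANK[minimum]
    kept: list[LocationAssignment] = []
    report = ExclusionReport(reason=f"precision below {minimum.value}")
    for a in assignments:
        if PRECISION_RANK[a.precision] <= floor:
            kept.append(a)
        else:
            report.add(a)
    return kept, report


class Region:
    """A set of named polygons in planar coordinates (study region/geographies).

    Built from GeoJSON in geographic coordinates; geometries are projected
    with the same transverse Mercator system as the point data so that
    point-in-polygon tests happen in one planar frame.  Boundary points
    count as inside.
    """

    def __init__(self, geometries: list, ids: list[str]):
        if not geometries:
            raise RegistryError("Region: empty polygon set")
        self.geometries = geometries
        self.ids = ids
        self._tree = STRtree(geometries)
        self._prepared = [prep(g) for g in geometries]

    @classmethod
    def from_geojson(
        cls,
        path: str,
        crs: TransverseMercator = UTM_18N,
        id_property: str = "geography_id",
    ) -> "Region":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        geometries, ids = [], []
        from shapely.ops import transform as shp_transform

        def _fwd(lon, lat):
            x, y = crs.forward(lat, lon)
            return x, y

        for i, feat in enumerate(feats):
            geom = shape(feat["geometry"] if "geometry" in feat else feat)
            geometries.append(shp_transform(_fwd, geom))
            props = feat.get("properties") or {}
            ids.append(str(props.get(id_property, i)))
        return cls(geometries, ids)

    #: numerical slack for the boundary-inclusive test, metres.  Polygons
    #: round-trip through geographic coordinates, which perturbs vertices at
    #: the nanometre scale; a point lying exactly on a boundary must still
    #: count as inside.
    BOUNDARY_TOL = 1e-6

    def locate(self, x: float, y: float) -> Optional[str]:
        """Geography id containing (x, y), or None; boundaries count as inside."""
        pt = Point(x, y)
        probe = box(x - self.BOUNDARY_TOL, y - self.BOUNDARY_TOL,
                    x + self.BOUNDARY_TOL, y + self.BOUNDARY_TOL)
        for idx in sorted(self._tree.query(probe)):
            g = self.geometries[int(idx)]
            if g.covers(pt) or g.distance(pt) <= self.BOUNDARY_TOL:
                return self.ids[int(idx)]
        return None

    def union_covers(self, x: float, y: float) -> bool:
        return self.locate(x, y) is not None


def exclude_out_of_region(
    assignments: Iterable[LocationAssignment],
    region: Region,
) -> tuple[list[LocationAssignment], ExclusionReport]:
    """Drop assignments whose planar point falls outside all region polygons.

    Headquarters listings and significant moves routinely place locations
    outside the licensed study region; those are excluded up front so that
    counts and densities refer to the region only.
    """
    kept: list[LocationAssignment] = []
    report = ExclusionReport(reason="outside study region")
    for a in assignments:
        if region.union_covers(a.x, a.y):
            a.in_region = True
            kept.append(a)
        else:
            a.in_region = False
            report.add(a)
    return kept, report
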