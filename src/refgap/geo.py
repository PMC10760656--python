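"""Geographic provenance of records against named region polygons.

Records carry WGS84 collection coordinates (BOLD only in practice); each
located record is classified inside/outside a region polygon with an
even-odd ray-casting test. Coordinates are treated as planar, which is
adequate at the continental-polygon scale this audit works at; polygons
crossing the antimeridian are rejected rather than silently misclassified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from refgap.errors import DegenerateRegionError, DomainError, ValidationError
from refgap.ingest import RecordTable

__all__ = [
    "RegionPolygon", "ProvenanceSummary", "point_in_region", "load_regions",
    "provenance_summary", "country_filter", "classify_records",
]

Ring = list[tuple[float, float]]  # closed: first vertex == last


@dataclass(frozen=True)
class RegionPolygon:
    """A named polygon: outer rings plus optional holes, (lon, lat) order."""

    name: str
    outer_rings: tuple[Ring, ...]
    holes: tuple[Ring, ...] = ()

    def __post_init__(self) -> None:
        if not self.outer_rings:
            raise ValidationError(f"{self.name}: at least one outer ring required")
        for ring in (*self.outer_rings, *self.holes):
            if len(ring) < 4 or ring[0] != ring[-1]:
                raise ValidationError(
                    f"{self.name}: rings need >=4 vertices with first == last"
                )
            lons = [p[0] for p in ring]
            for lon, lat in ring:
                if abs(lon) > 180.0 or abs(lat) > 90.0:
                    raise ValidationError(
                        f"{self.name}: vertex ({lon}, {lat}) out of range"
                    )
            if max(lons) - min(lons) > 180.0:
                raise ValidationError(
                    f"{self.name}: antimeridian-crossing polygons unsupported"
                )
        if all(_ring_area(r) == 0.0 for r in self.outer_rings):
            raise DegenerateRegionError(f"{self.name}: zero-area region")


def _ring_area(ring: Ring) -> float:
    s = 0.0
    for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def _on_segment(px, py, x0, y0, x1, y1, eps=1e-12) -> bool:
    cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
    if abs(cross) > eps * max(1.0, abs(x1 - x0), abs(y1 - y0)):
        return False
    return (min(x0, x1) - eps <= px <= max(x0, x1) + eps
            and min(y0, y1) - eps <= py <= max(y0, y1) + eps)


def _crossings(px: float, py: float, ring: Ring) -> int:
    """Count crossings of the +x ray from (px, py) with ring edges.

    The half-open vertex rule (yi > py) != (yj > py) is equivalent to
    nudging every vertex lying exactly on the ray upward by an epsilon,
    giving a deterministic tie-break for vertices and horizontal edges.
    """
    n = 0
    for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
        if (y0 > py) != (y1 > py):
            x_cross = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if x_cross > px:
                n += 1
    return n


def point_in_region(lon: float, lat: float, region: RegionPolygon) -> bool:
    """Even-odd point-in-polygon test; boundary points count as inside.

    True iff the point falls in an outer ring (odd crossing count) and not
    inside any hole; a point exactly on any ring edge is inside.
    """
    if abs(lon) > 180.0 or abs(lat) > 90.0:
        raise DomainError(f"invalid coordinates ({lon}, {lat})")
    for ring in (*region.outer_rings, *region.holes):
        for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
            if _on_segment(lon, lat, x0, y0, x1, y1):
                return True
    inside_outer = any(_crossings(lon, lat, r) % 2 == 1
                       for r in region.outer_rings)
    if not inside_outer:
        return False
    in_hole = any(_crossings(lon, lat, r) % 2 == 1 for r in region.holes)
    return not in_hole


def load_regions(path: str | Path) -> list[RegionPolygon]:
    """Load Polygon/MultiPolygon features from a GeoJSON file.

    The first ring of each polygon is the outer ring, subsequent rings are
    holes (GeoJSON convention). Feature names come from
    ``properties.name``.
    """
    data = json.loads(Path(path).read_text())
    features = data.get("features", [data]) if data.get("type") != "Feature" \
        else [data]
    regions = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry", feat)
        name = (feat.get("properties") or {}).get("name", f"region_{i}")
        gtype = geom.get("type")
        if gtype == "Polygon":
            polys = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            raise ValidationError(f"{name}: unsupported geometry {gtype!r}")
        outers, holes = [], []
        for rings in polys:
            outers.append([tuple(map(float, p)) for p in rings[0]])
            holes.extend([tuple(map(float, p)) for p in r] for r in rings[1:])
        regions.append(RegionPolygon(name=name, outer_rings=tuple(outers),
                                     holes=tuple(holes)))
    return regions


@dataclass(frozen=True)
class ProvenanceSummary:
    """Inside/outside/unlocated accounting for one region.

    Unlocated records are excluded from percentage denominators: provenance
    can only be judged for georeferenced samples. When no record is located
    the percentages are None and ``undefined`` is set.
    """

    region_name: str
    n_records_inside: int
    n_records_outside: int
    n_records_unlocated: int
    n_species_inside: int
    n_species_located: int
    pct_records_inside: float | None
    pct_species_inside: float | None

    @property
    def undefined(self) -> bool:
        return self.pct_records_inside is None

    @property
    def n_records_total(self) -> int:
        return (self.n_records_inside + self.n_records_outside
                + self.n_records_unlocated)


def classify_records(
    records: RecordTable, region: RegionPolygon
) -> dict[str, str]:
    """Per-record classification: record_id -> inside|outside|unlocated."""
    out = {}
    for rec in records:
        if not rec.located:
            out[rec.record_id] = "unlocated"
        elif point_in_region(rec.longitude, rec.latitude, region):
            out[rec.record_id] = "inside"
        else:
            out[rec.record_id] = "outside"
    return out


def provenance_summary(
    records: RecordTable, region: RegionPolygon
) -> ProvenanceSummary:
    """Record- and species-level inside proportions for one region.

    The species-level denominator is the number of species with at least one
    located record; a species is "inside" when any of its located records
    falls inside the region.
    """
    from refgap.gap_analysis import coverage_percentage

    n_in = n_out = n_unloc = 0
    species_located: set[str] = set()
    species_inside: set[str] = set()
    for rec in records:
        if not rec.located:
            n_unloc += 1
            continue
        species_located.add(rec.species_name)
        if point_in_region(rec.longitude, rec.latitude, region):
            n_in += 1
            species_inside.add(rec.species_name)
        else:
            n_out += 1
    located = n_in + n_out
    return ProvenanceSummary(
        region_name=region.name,
        n_records_inside=n_in,
        n_records_outside=n_out,
        n_records_unlocated=n_unloc,
        n_species_inside=len(species_inside),
        n_species_located=len(species_located),
        pct_records_inside=(
            coverage_percentage(n_in, located) if located else None),
        pct_species_inside=(
            coverage_percentage(len(species_inside), len(species_located))
            if species_located else None),
    )


def country_filter(
    records: RecordTable, country: str,
    country_region: RegionPolygon | None = None,
) -> RecordTable:
    """Keep records attributable to ``country``.

    A record qualifies when its country field matches case-insensitively OR
    its coordinates fall inside the supplied country polygon (union of both
    criteria, so georeferenced records with a blank country field are still
    credited).
    """
    target = country.strip().lower()
    kept = []
    for rec in records:
        by_field = (rec.country or "").strip().lower() == target
        by_geom = (
            country_region is not None and rec.located
            and point_in_region(rec.longitude, rec.latitude, country_region)
        )
        if by_field or by_geom:
            kept.append(rec)
    return RecordTable(records=kept, provenance_log=[
        f"country filter {country!r}: kept {len(kept)} of {len(records)}"
    ])
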