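"""Point-in-polygon geometry and provenance accounting."""

import json

import numpy as np
import pytest

from conftest import make_record
from oracle_util import winding_number_inside
from refgap.errors import (
    DegenerateRegionError, DomainError, ValidationError,
)
from refgap.geo import (
    RegionPolygon, country_filter, load_regions, point_in_region,
    provenance_summary,
)
from refgap.ingest import RecordTable

UNIT_SQUARE = RegionPolygon(
    name="unit", outer_rings=([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)],))

# concave (L-shaped) polygon with a square hole, used across geometry tests
CONCAVE = RegionPolygon(
    name="concave",
    outer_rings=([(0, 0), (10, 0), (10, 4), (4, 4), (4, 10), (0, 10),
                  (0, 0)],),
    holes=([(1, 1), (3, 1), (3, 3), (1, 3), (1, 1)],),
)


class TestPointInRegion:
    @pytest.mark.parametrize("lon,lat,expected", [
        (0.5, 0.5, True),
        (2.0, 2.0, False),
        (0.0, 0.5, True),     # boundary edge counts as inside
        (1.0, 1.0, True),     # boundary vertex counts as inside
        (-0.001, 0.5, False),
    ])
    def test_unit_square(self, lon, lat, expected):
        assert point_in_region(lon, lat, UNIT_SQUARE) is expected

    def test_hole_is_outside_but_hole_boundary_inside(self):
        assert not point_in_region(2.0, 2.0, CONCAVE)
        assert point_in_region(1.0, 2.0, CONCAVE)  # hole edge
        assert point_in_region(0.5, 0.5, CONCAVE)
        assert not point_in_region(8.0, 8.0, CONCAVE)  # concave notch

    def test_invalid_coordinates(self):
        with pytest.raises(DomainError):
            point_in_region(200.0, 0.0, UNIT_SQUARE)

    def test_agrees_with_winding_oracle_on_1000_random_points(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            lon = float(rng.uniform(-2, 12))
            lat = float(rng.uniform(-2, 12))
            assert point_in_region(lon, lat, CONCAVE) == \
                winding_number_inside(lon, lat, CONCAVE.outer_rings,
                                      CONCAVE.holes)

    def test_agrees_with_shapely(self):
        shapely = pytest.importorskip("shapely")
        poly = shapely.Polygon(CONCAVE.outer_rings[0],
                               [h for h in CONCAVE.holes])
        rng = np.random.default_rng(7)
        for _ in range(500):
            lon = float(rng.uniform(-2, 12))
            lat = float(rng.uniform(-2, 12))
            p = shapely.Point(lon, lat)
            assert point_in_region(lon, lat, CONCAVE) == bool(
                poly.contains(p) or poly.touches(p))


class TestRegionPolygon:
    def test_open_ring_rejected(self):
        with pytest.raises(ValidationError):
            RegionPolygon(name="open",
                          outer_rings=([(0, 0), (1, 0), (1, 1), (0, 1)],))

    def test_zero_area_rejected(self):
        with pytest.raises(DegenerateRegionError):
            RegionPolygon(name="line",
                          outer_rings=([(0, 0), (1, 0), (0, 0), (1, 0),
                                        (0, 0)],))

    def test_antimeridian_crossing_rejected(self):
        with pytest.raises(ValidationError, match="antimeridian"):
            RegionPolygon(name="wide",
                          outer_rings=([(-179, 0), (179, 0), (179, 1),
                                        (-179, 1), (-179, 0)],))


def _located(rid, species, lon, lat):
    return make_record(rid, species, latitude=lat, longitude=lon)


class TestProvenanceSummary:
    def test_sixty_eight_of_hundred_inside(self):
        records = [
            _located(f"R{i}", "Alphaus primus", 0.5, 0.5) for i in range(68)
        ] + [
            _located(f"S{i}", "Alphaus primus", 50.0, 50.0)
            for i in range(32)
        ]
        s = provenance_summary(RecordTable(records=records), UNIT_SQUARE)
        assert s.pct_records_inside == 68.0

    def test_all_unlocated_is_flagged_undefined(self):
        table = RecordTable(records=[make_record("R1", "Alphaus primus")])
        s = provenance_summary(table, UNIT_SQUARE)
        assert s.undefined
        assert s.pct_records_inside is None and s.pct_species_inside is None

    def test_species_vs_record_level_percentages(self):
        records = []
        for i in range(10):
            sp = f"Alphaus {'abcdefghij'[i] * 3}"
            records.append(_located(f"I{i}", sp, 0.5, 0.5))
            records.append(_located(f"O{i}", sp, 50.0, 50.0))
        s = provenance_summary(RecordTable(records=records), UNIT_SQUARE)
        assert s.pct_species_inside == 100.0
        assert s.pct_records_inside == 50.0

    def test_conservation_inside_outside_unlocated(self):
        records = [
            _located("R1", "Alphaus primus", 0.5, 0.5),
            _located("R2", "Alphaus primus", 50.0, 50.0),
            make_record("R3", "Alphaus primus"),
        ]
        table = RecordTable(records=records)
        s = provenance_summary(table, UNIT_SQUARE)
        assert (s.n_records_inside + s.n_records_outside
                + s.n_records_unlocated) == len(table)

    def test_shrinking_region_never_gains_inside_records(self):
        big = UNIT_SQUARE
        small = RegionPolygon(
            name="small",
            outer_rings=([(0, 0), (0.5, 0), (0.5, 0.5), (0, 0.5), (0, 0)],))
        rng = np.random.default_rng(3)
        records = [
            _located(f"R{i}", "Alphaus primus",
                     float(rng.uniform(-0.5, 1.5)),
                     float(rng.uniform(-0.5, 1.5)))
            for i in range(200)
        ]
        table = RecordTable(records=records)
        assert (provenance_summary(table, small).n_records_inside
                <= provenance_summary(table, big).n_records_inside)


class TestCountryFilter:
    def test_case_insensitive_country_field(self):
        records = [
            make_record(f"R{i}", "Alphaus primus", country=c)
            for i, c in enumerate(["Peru", "peru", "PERU"])
        ]
        out = country_filter(RecordTable(records=records), "Peru")
        assert len(out) == 3

    def test_coordinates_inside_polygon_retained_without_field(self):
        table = RecordTable(records=[
            _located("R1", "Alphaus primus", 0.5, 0.5),
        ])
        out = country_filter(table, "Peru", country_region=UNIT_SQUARE)
        assert len(out) == 1

    def test_wrong_country_no_coordinates_excluded(self):
        table = RecordTable(records=[
            make_record("R1", "Alphaus primus", country="Brazil"),
        ])
        assert len(country_filter(table, "Peru",
                                  country_region=UNIT_SQUARE)) == 0


def test_load_regions_geojson(tmp_path):
    path = tmp_path / "regions.geojson"
    path.write_text(json.dumps({
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "properties": {"name": "realm"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[0, 0], [10, 0], [10, 4], [4, 4], [4, 10], [0, 10],
                     [0, 0]],
                    [[1, 1], [3, 1], [3, 3], [1, 3], [1, 1]],
                ],
            },
        }],
    }))
    regions = load_regions(path)
    assert len(regions) == 1
    region = regions[0]
    assert region.name == "realm"
    assert len(region.holes) == 1
    assert point_in_region(0.5, 0.5, region)
    assert not point_in_region(2.0, 2.0, region)
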