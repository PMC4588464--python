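"""Geocode merging, precision filtering, region clipping: oracle equivalences."""

import itertools
import json

import numpy as np
import pytest
from shapely.geometry import Polygon

from bizscape.geoprocessing import (
    Region,
    exclude_out_of_region,
    filter_by_precision,
    merge_geocodes,
    project_and_round,
)
from bizscape.model import (
    SOURCE_PRIORITY,
    GeocodeCandidate,
    GeocodeSource,
    LocationAssignment,
    Precision,
    RegistryError,
)

D = "123456789"


def _cand(source, lat=40.7, lon=-74.0, precision=None):
    if precision is None:
        precision = (
            Precision.POINT
            if source in (GeocodeSource.GOLD_LOCAL, GeocodeSource.COMMERCIAL_POINT)
            else Precision.STREET_SEGMENT
        )
    return GeocodeCandidate(D, "most_recent", source, lat, lon, precision)


class TestMergeGeocodes:
    def test_gold_beats_commercial_point(self):
        best = merge_geocodes([_cand(GeocodeSource.COMMERCIAL_POINT),
                               _cand(GeocodeSource.GOLD_LOCAL)])
        assert best.source is GeocodeSource.GOLD_LOCAL

    def test_singleton(self):
        best = merge_geocodes([_cand(GeocodeSource.COMMERCIAL_STREET)])
        assert best.source is GeocodeSource.COMMERCIAL_STREET

    def test_vendor_used_when_all_providers_fail(self):
        best = merge_geocodes(
            [_cand(GeocodeSource.VENDOR_SUPPLIED, precision=Precision.ZIP)]
        )
        assert best.source is GeocodeSource.VENDOR_SUPPLIED

    def test_empty_list_is_error(self):
        with pytest.raises(RegistryError, match="empty"):
            merge_geocodes([])

    def test_equals_brute_force_max_over_all_source_subsets(self):
        """Exhaustive: every nonempty subset of the four sources."""
        sources = list(GeocodeSource)
        for r in range(1, 5):
            for subset in itertools.combinations(sources, r):
                cands = [_cand(s) for s in subset]
                best = merge_geocodes(cands)
                oracle = min(cands, key=lambda c: SOURCE_PRIORITY[c.source])
                assert best.source is oracle.source

    def test_tie_break_within_tier_is_coordinate_lexicographic(self):
        a = _cand(GeocodeSource.COMMERCIAL_POINT, lat=40.1, lon=-74.0)
        b = _cand(GeocodeSource.COMMERCIAL_POINT, lat=40.2, lon=-74.0)
        assert merge_geocodes([b, a]).lat == 40.1
        assert merge_geocodes([a, b]).lat == 40.1


class TestProjectAndRound:
    def test_rounded_to_ten_metres(self):
        x, y = project_and_round(40.7128, -74.0060)
        assert x % 10 == 0 and y % 10 == 0
        # unrounded UTM 18N easting/northing are (583959.4, 4507351.0)
        assert (x, y) == (583960.0, 4507350.0)

    def test_rounding_arithmetic(self):
        from bizscape.projection import round_to_grid

        assert round_to_grid(583960.4) == 583960.0
        assert round_to_grid(4507523.7) == 4507520.0
        assert round_to_grid(583960.0) == 583960.0


def _assign(precision, year=2000, source=GeocodeSource.VENDOR_SUPPLIED, x=0.0, y=0.0):
    return LocationAssignment(duns_id=D, year=year, x=x, y=y,
                              precision=precision, source=source)


class TestPrecisionFilter:
    def test_street_floor_keeps_point_drops_zip(self):
        kept, report = filter_by_precision(
            [_assign(Precision.POINT), _assign(Precision.ZIP)],
            Precision.STREET_SEGMENT,
        )
        assert [a.precision for a in kept] == [Precision.POINT]
        assert report.total == 1

    def test_zip_floor_keeps_everything(self):
        all_levels = [_assign(p) for p in Precision]
        kept, report = filter_by_precision(all_levels, Precision.ZIP)
        assert len(kept) == len(all_levels) and report.total == 0

    def test_unknown_precision_label_is_error(self):
        with pytest.raises(RegistryError, match="unknown precision"):
            filter_by_precision([], "rooftopish")

    def test_monotone_in_the_floor(self):
        rng = np.random.default_rng(7)
        levels = list(Precision)
        pool = [_assign(levels[i]) for i in rng.integers(0, len(levels), size=200)]
        kept_sizes = [len(filter_by_precision(pool, m)[0]) for m in levels]
        assert kept_sizes == sorted(kept_sizes)


class TestRegion:
    @pytest.fixture()
    def unit_square(self):
        return Region([Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])], ["sq"])

    def test_centroid_kept_far_point_excluded(self, unit_square):
        kept, excl = exclude_out_of_region(
            [_assign(Precision.POINT, x=0.5, y=0.5), _assign(Precision.POINT, x=50, y=50)],
            unit_square,
        )
        assert len(kept) == 1 and excl.total == 1
        assert kept[0].x == 0.5

    def test_boundary_point_counts_as_inside(self, unit_square):
        kept, _ = exclude_out_of_region([_assign(Precision.POINT, x=0.0, y=0.5)], unit_square)
        assert len(kept) == 1

    def test_empty_region_is_error(self):
        with pytest.raises(RegistryError, match="empty"):
            Region([], [])

    def test_matches_ray_casting_oracle_on_random_points(self, unit_square):
        """1,000 random points vs an independent crossing-number test."""

        def ray_cast(px, py, ring):
            inside = False
            for (x1, y1), (x2, y2) in zip(ring, ring[1:] + ring[:1]):
                if (y1 > py) != (y2 > py):
                    x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < x_int:
                        inside = not inside
            return inside

        ring = [(0, 0), (1, 0), (1, 1), (0, 1)]
        rng = np.random.default_rng(42)
        pts = rng.uniform(-0.5, 1.5, size=(1000, 2))
        for px, py in pts:
            assert unit_square.union_covers(px, py) == ray_cast(px, py, ring)

    def test_geojson_roundtrip_locates_counties(self, tmp_path):
        from bizscape.synth import GRID

        path = tmp_path / "region.geojson"
        path.write_text(json.dumps(GRID.region_geojson()))
        region = Region.from_geojson(str(path))
        # a point in the south-west county and one in the north-east county
        assert region.locate(GRID.e0 + 1000, GRID.n0 + 1000) == "C00"
        assert region.locate(GRID.e0 + GRID.width - 1000, GRID.n0 + GRID.height - 1000) == "C14"
        assert region.locate(GRID.e0 - 5000, GRID.n0) is None
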