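"""Collapsing, count tables and trend fits against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from bizscape.density import (
    BusinessYearPoint,
    CountTable,
    collapse_colocated,
    count_by_geography,
    fit_linear_trends,
    ols_line,
)
from bizscape.model import RegistryError


def _pt(duns, year=2000, category="pharmacy", x=100.0, y=200.0, gid="g1"):
    return BusinessYearPoint(duns_id=duns, year=year, category=category, x=x, y=y,
                             geography_id=gid)


class TestCollapse:
    def test_three_same_category_same_site_become_one(self):
        pts = [_pt("300000001"), _pt("300000002"), _pt("100000003")]
        collapsed, mapping = collapse_colocated(pts)
        assert len(collapsed) == 1
        assert collapsed[0].duns_id == "100000003"  # smallest id is the representative
        assert set(mapping.values()) == {"100000003"}

    def test_different_categories_at_same_site_stay_distinct(self):
        pts = [_pt("300000001", category="pharmacy"), _pt("300000002", category="bank")]
        collapsed, _ = collapse_colocated(pts)
        assert len(collapsed) == 2

    def test_different_years_at_same_site_stay_distinct(self):
        pts = [_pt("300000001", year=2000), _pt("300000001", year=2001)]
        assert len(collapse_colocated(pts)[0]) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        pts = [
            _pt(f"{100000000 + i}", year=int(rng.integers(1990, 2011)),
                category=["pharmacy", "bank"][int(rng.integers(2))],
                x=float(rng.integers(0, 5) * 10), y=float(rng.integers(0, 5) * 10))
            for i in range(300)
        ]
        once, _ = collapse_colocated(pts)
        twice, _ = collapse_colocated(once)
        assert sorted(p.duns_id for p in once) == sorted(p.duns_id for p in twice)


class TestCounts:
    def test_toy_fixture_matches_hand_count(self):
        pts = [
            _pt("100000001", year=2000, category="bank", gid="A"),
            _pt("100000002", year=2000, category="bank", gid="A", x=110.0),
            _pt("100000003", year=2000, category="bank", gid="B"),
            _pt("100000004", year=2000, category="pharmacy", gid="A"),
            _pt("100000005", year=2001, category="bank", gid="A"),
        ]
        table = count_by_geography(pts)
        assert table.cell("A", "bank", 2000) == (2, 2)
        assert table.cell("B", "bank", 2000) == (1, 1)
        assert table.cell("A", "pharmacy", 2000) == (1, 1)
        assert table.cell("A", "bank", 2001) == (1, 1)

    def test_empty_input_gives_empty_table(self):
        table = count_by_geography([])
        assert len(table.frame) == 0

    def test_zero_cells_emitted_over_year_range(self):
        pts = [_pt("100000001", year=2000, gid="A")]
        table = count_by_geography(pts, year_range=(1998, 2002))
        assert table.cell("A", "pharmacy", 1999) == (0, 0)
        assert len(table.frame) == 5

    def test_collapsed_never_exceeds_raw(self):
        rng = np.random.default_rng(11)
        pts = [
            _pt(f"{100000000 + i}", year=int(rng.integers(1990, 1995)),
                category=["pharmacy", "bank", "dental_care"][int(rng.integers(3))],
                x=float(rng.integers(0, 4) * 10), y=0.0,
                gid=["A", "B"][int(rng.integers(2))])
            for i in range(500)
        ]
        table = count_by_geography(pts)
        assert (table.frame["collapsed"] <= table.frame["raw"]).all()

    def test_matches_brute_force_grouping_oracle(self):
        """1,000 random points: exact agreement with a dict-based group-by."""
        rng = np.random.default_rng(23)
        pts = [
            _pt(f"{100000000 + i}",
                year=int(rng.integers(1990, 2011)),
                category=["pharmacy", "bank", "liquor_store"][int(rng.integers(3))],
                x=float(rng.integers(0, 20) * 10), y=float(rng.integers(0, 20) * 10),
                gid=["A", "B", "C"][int(rng.integers(3))])
            for i in range(1000)
        ]
        table = count_by_geography(pts)
        oracle_raw: dict = {}
        oracle_sites: dict = {}
        for p in pts:
            key = (p.geography_id, p.category, p.year)
            oracle_raw[key] = oracle_raw.get(key, 0) + 1
            oracle_sites.setdefault(key, set()).add((p.x, p.y))
        for key, n_raw in oracle_raw.items():
            raw, collapsed = table.cell(*key)
            assert raw == n_raw
            assert collapsed == len(oracle_sites[key])
        assert int(table.frame["raw"].sum()) == 1000


class TestTrendFits:
    def test_exact_line_has_slope_two_and_zero_se(self):
        years = np.arange(1990, 2011)
        counts = 10 + 2 * (years - 1990)
        slope, intercept, se = ols_line(years, counts)
        assert slope == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_has_zero_slope(self):
        years = np.arange(1990, 2011)
        slope, _, _ = ols_line(years, np.full(21, 7.0))
        assert slope == pytest.approx(0.0)

    def test_single_year_is_error(self):
        with pytest.raises(RegistryError):
            ols_line(np.array([2000, 2000]), np.array([1.0, 2.0]))

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        years = np.arange(1990, 2011, dtype=float)
        counts = 5 + 0.8 * (years - 1990) + rng.normal(0, 2, size=21)
        slope, intercept, se = ols_line(years, counts)
        fit = sm.OLS(counts, sm.add_constant(years)).fit()
        assert slope == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert se == pytest.approx(fit.bse[1], rel=1e-10)

    def test_fit_linear_trends_per_series(self):
        rows = []
        for year in range(1990, 2011):
            rows.append({"geography_id": "A", "category": "bank", "year": year,
                         "raw": 10 + 2 * (year - 1990), "collapsed": 10 + 2 * (year - 1990)})
            rows.append({"geography_id": "B", "category": "bank", "year": year,
                         "raw": 5, "collapsed": 5})
        fits = fit_linear_trends(CountTable(pd.DataFrame(rows)))
        by_gid = {f.geography_id: f for f in fits}
        assert by_gid["A"].slope == pytest.approx(2.0)
        assert by_gid["B"].slope == pytest.approx(0.0)
        assert by_gid["A"].n_years == 21
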