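"""Co-location collapsing, count tables and linear density trends.

Registries list multiple concurrent records for what is functionally one
establishment — franchise instances, co-registered LLCs, practitioners
sharing a suite — usually with small variations in the name field.  Since
category assignment already absorbs the name variation and coordinates are
rounded to a 10 m grid, 'potential duplicate' is operationalized exactly:
same researcher-defined category, same year, same rounded location.  Such
groups collapse to one representative record (smallest DUNS id, a
documented convention).  Records in different categories at one location
always stay distinct — a mall or medical office building legitimately
hosts many establishment types.

Counts are tabulated per geography x category x year both raw and
collapsed, and per-series ordinary least squares trends (count on calendar
year) summarize two decades of density change per geography.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import RegistryError

__all__ = [
    "BusinessYearPoint",
    "collapse_colocated",
    "assign_geography",
    "count_by_geography",
    "CountTable",
    "fit_linear_trends",
    "TrendFit",
    "UNASSIGNED_GEOGRAPHY",
]

UNASSIGNED_GEOGRAPHY = "__unassigned__"


@dataclass(frozen=True)
class BusinessYearPoint:
    """One categorized, located business-year."""

    duns_id: str
    year: int
    category: str
    x: float
    y: float
    geography_id: Optional[str] = None


def collapse_colocated(
    points: Sequence[BusinessYearPoint],
) -> tuple[list[BusinessYearPoint], dict[tuple[str, int], str]]:
    """One representative per (category, year, x, y) group.

    Returns the collapsed points plus a collapse map
    (duns_id, year) -> representative duns_id, identity for singletons.
    Idempotent by construction.
    """
    groups: dict[tuple, list[BusinessYearPoint]] = {}
    for p in points:
        # geography is a function of location, so including it is a no-op on
        # physical data; it keeps the grouping local for partial fixtures
        groups.setdefault((p.category, p.year, p.x, p.y, p.geography_id), []).append(p)
    collapsed: list[BusinessYearPoint] = []
    mapping: dict[tuple[str, int], str] = {}
    for members in groups.values():
        rep = min(members, key=lambda p: p.duns_id)
        collapsed.append(rep)
        for p in members:
            mapping[(p.duns_id, p.year)] = rep.duns_id
    return collapsed, mapping


def assign_geography(points: Iterable[BusinessYearPoint], region) -> list[BusinessYearPoint]:
    """Attach a geography id by point-in-polygon against a Region.

    Points covered by no polygon are routed to a sentinel geography rather
    than dropped, so conservation of totals is checkable.
    """
    out = []
    cache: dict[tuple[float, float], str] = {}
    for p in points:
        key = (p.x, p.y)
        gid = cache.get(key)
        if gid is None:
            gid = region.locate(p.x, p.y) or UNASSIGNED_GEOGRAPHY
            cache[key] = gid
        out.append(BusinessYearPoint(p.duns_id, p.year, p.category, p.x, p.y, gid))
    return out


@dataclass
class CountTable:
    """Long-format counts per (geography, category, year), raw and collapsed."""

    frame: pd.DataFrame  # columns: geography_id, category, year, raw, collapsed

    def cell(self, geography_id: str, category: str, year: int) -> tuple[int, int]:
        f = self.frame
        m = (
            (f["geography_id"] == geography_id)
            & (f["category"] == category)
            & (f["year"] == year)
        )
        if not m.any():
            return 0, 0
        row = f.loc[m].iloc[0]
        return int(row["raw"]), int(row["collapsed"])

    def totals_by_year(self, mode: str = "raw") -> pd.Series:
        return self.frame.groupby("year")[mode].sum()


def _counts(points: Sequence[BusinessYearPoint]) -> pd.DataFrame:
    if not points:
        return pd.DataFrame(columns=["geography_id", "category", "year", "n"])
    df = pd.DataFrame(
        {
            "geography_id": [p.geography_id or UNASSIGNED_GEOGRAPHY for p in points],
            "category": [p.category for p in points],
            "year": [p.year for p in points],
        }
    )
    return df.groupby(["geography_id", "category", "year"], as_index=False).size().rename(
        columns={"size": "n"}
    )


def count_by_geography(
    points: Sequence[BusinessYearPoint],
    year_range: Optional[tuple[int, int]] = None,
    include_uncategorized: bool = False,
) -> CountTable:
    """Exact group-by counts per geography x category x year.

    Both the raw and the collapsed count are produced for every cell;
    cells with no establishments inside the configured year range are
    emitted as zeros so that downstream trend fits see complete series.
    """
    if not include_uncategorized:
        from .categorize import UNCATEGORIZED

        points = [p for p in points if p.category != UNCATEGORIZED]
    collapsed_pts, _ = collapse_colocated(points)
    raw = _counts(points).rename(columns={"n": "raw"})
    col = _counts(collapsed_pts).rename(columns={"n": "collapsed"})
    merged = raw.merge(col, on=["geography_id", "category", "year"], how="outer")

    if year_range is not None and len(merged):
        lo, hi = year_range
        keys = merged[["geography_id", "category"]].drop_duplicates()
        grid = keys.merge(pd.DataFrame({"year": range(lo, hi + 1)}), how="cross")
        merged = grid.merge(merged, on=["geography_id", "category", "year"], how="left")
    merged[["raw", "collapsed"]] = (
        merged[["raw", "collapsed"]].fillna(0).astype(int) if len(merged) else 0
    )
    merged = merged.sort_values(["geography_id", "category", "year"], ignore_index=True)
    return CountTable(frame=merged)


@dataclass
class TrendFit:
    """OLS line for one geography x category count series."""

    geography_id: str
    category: str
    slope: float  # establishments per calendar year
    intercept: float
    slope_se: float
    n_years: int


def ols_line(years: np.ndarray, counts: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS of counts on years: slope, intercept, slope SE."""
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = len(years)
    if n < 2 or np.ptp(years) == 0:
        raise RegistryError("trend fit needs >= 2 distinct years")
    xbar, ybar = years.mean(), counts.mean()
    sxx = np.sum((years - xbar) ** 2)
    slope = float(np.sum((years - xbar) * (counts - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = counts - (intercept + slope * years)
    if n > 2:
        se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    else:
        se = 0.0
    return slope, intercept, se


def fit_linear_trends(table: CountTable, mode: str = "collapsed") -> list[TrendFit]:
    """Best-fit linear trend per geography x category series.

    ``mode`` selects which count (raw or collapsed) is regressed on
    calendar year.  Series with fewer than two distinct years are skipped.
    """
    fits: list[TrendFit] = []
    for (gid, cat), grp in table.frame.groupby(["geography_id", "category"]):
        years = grp["year"].to_numpy()
        if len(np.unique(years)) < 2:
            continue
        slope, intercept, se = ols_line(years, grp[mode].to_numpy())
        fits.append(TrendFit(gid, cat, slope, intercept, se, len(years)))
    return fits
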