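"""End-to-end pipeline: registry -> address book -> geocodes -> categories -> counts.

Stages mirror the refinement workflow for longitudinal establishment
data: (1) merge the delivery files, (2) build the comprehensive address
file and assign one location-role per business-year, (3) merge geocode
candidates by source priority, project to planar metres and round to the
10 m grid, (4) drop low-precision and out-of-region locations with
per-year accounting, (5) categorize businesses (overall or yearly mode),
(6) collapse co-located same-category records and tabulate counts per
geography x category x year, (7) fit per-geography linear trends.

Every stage logs records-in/records-out (the quality control for this
kind of processing is exactly the count surviving each step) and writes
its table to the output directory, so any stage can be re-run from the
previous stage's file output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import addressbook, categorize, density, geoprocessing, nets_io
from .model import Precision, RegistryError
from .projection import UTM_18N, TransverseMercator

__all__ = ["PipelineConfig", "RunResult", "run_pipeline", "default_categories_path"]

logger = logging.getLogger(__name__)


def default_categories_path() -> Path:
    """Path to the shipped category-definition template."""
    return Path(str(resources.files("bizscape.data") / "categories.yaml"))


class PipelineConfig(BaseModel):
    """Configuration for one pipeline run."""

    input_paths: list[str]
    region_geojson: str
    out_dir: str
    categories_path: Optional[str] = None
    file_overrides: dict[str, str] = Field(default_factory=dict)
    central_meridian_deg: float = -75.0  # UTM 18N
    min_precision: str = "street_segment"
    mode: str = "overall"  # overall | yearly
    counts: str = "both"  # raw | collapsed | both
    year_range: Optional[tuple[int, int]] = None
    destination_from_move_year: bool = True
    include_uncategorized_counts: bool = False
    seed: int = 0

    def validate_paths(self) -> None:
        missing = [p for p in self.input_paths + [self.region_geojson] if not Path(p).exists()]
        if self.categories_path and not Path(self.categories_path).exists():
            missing.append(self.categories_path)
        if missing:
            raise RegistryError(f"config error: missing input file(s) {missing}")


@dataclass
class RunResult:
    """Stage outputs and the run report of one pipeline execution."""

    counts: density.CountTable
    trends: list[density.TrendFit]
    assignment: categorize.CategoryAssignment
    points: list[density.BusinessYearPoint]
    report: dict = dc_field(default_factory=dict)


def _stage_log(stage: str, **counters) -> None:
    logger.info("%s", json.dumps({"stage": stage, **counters}, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute all stages in order; see module docstring.

    Raises :class:`RegistryError` on configuration problems before any
    stage runs; stage failures propagate with their stage noted.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    crs = (
        UTM_18N
        if config.central_meridian_deg == -75.0
        else TransverseMercator(central_meridian_deg=config.central_meridian_deg)
    )
    report: dict = {"seed": config.seed, "stages": {}}

    # 1. read + merge the delivery
    read_messages: list[str] = []
    dialect = nets_io.Dialect(file_overrides=config.file_overrides)
    bundle = nets_io.read_registry(config.input_paths, dialect=dialect, report=read_messages)
    n_est = len(bundle.establishments)
    _stage_log("read_registry", establishments=n_est, moves=len(bundle.moves),
               dropped_or_flagged=len(read_messages))
    report["stages"]["read_registry"] = {
        "establishments": n_est, "moves": len(bundle.moves), "messages": read_messages,
    }

    # 2. comprehensive address file + one location-role per business-year
    book = addressbook.build_address_book(bundle)
    year_roles = addressbook.assign_yearly_locations(
        bundle, book, destination_from_move_year=config.destination_from_move_year
    )
    _stage_log("address_book", roles=len(book.variants),
               discrepancies=len(book.discrepancies), business_years=len(year_roles))
    report["stages"]["address_book"] = {
        "roles": len(book.variants), "discrepancies": len(book.discrepancies),
        "business_years": len(year_roles),
    }
    pd.DataFrame(
        [
            {
                "duns_id": v.duns_id, "role": v.role,
                "street": v.address_string_primary,
                "street_alt": v.address_string_alternate or "",
                "zip5": v.zip5, "normalized": v.normalized or "",
            }
            for v in book.variants
        ]
    ).to_csv(out_dir / "address_book.csv", index=False)
    pd.DataFrame(
        [{"duns_id": d, "year": y, "role": r} for (d, y), r in sorted(year_roles.items())]
    ).to_csv(out_dir / "year_location.csv", index=False)

    # 3. merge candidates, project, round
    assignments, unresolved = geoprocessing.resolve_locations(bundle, year_roles, crs=crs)
    _stage_log("geocode", assigned=len(assignments), unresolved=len(unresolved))
    report["stages"]["geocode"] = {
        "assigned": len(assignments), "unresolved_business_years": len(unresolved),
    }

    # per-year precision distribution before filtering (precision-drift table)
    prec_rows: dict[tuple[int, str], int] = {}
    for a in assignments:
        prec_rows[(a.year, a.precision.value)] = prec_rows.get((a.year, a.precision.value), 0) + 1
    precision_by_year = pd.DataFrame(
        [{"year": y, "precision": p, "n": n} for (y, p), n in sorted(prec_rows.items())]
    )
    precision_by_year.to_csv(out_dir / "precision_by_year.csv", index=False)
    report["precision_by_year"] = precision_by_year

    # 4. precision floor, then region clip
    kept, precision_excl = geoprocessing.filter_by_precision(
        assignments, Precision(config.min_precision)
    )
    region = geoprocessing.Region.from_geojson(config.region_geojson, crs=crs)
    kept, region_excl = geoprocessing.exclude_out_of_region(kept, region)
    _stage_log("filter", kept=len(kept), below_precision=precision_excl.total,
               out_of_region=region_excl.total)
    report["stages"]["filter"] = {
        "kept": len(kept),
        "below_precision": precision_excl.total,
        "below_precision_by_year": dict(precision_excl.by_year),
        "out_of_region": region_excl.total,
    }
    pd.DataFrame(
        [
            {"reason": rep.reason, "year": y, "n": n}
            for rep in (precision_excl, region_excl)
            for y, n in sorted(rep.by_year.items())
        ]
    ).to_csv(out_dir / "exclusions.csv", index=False)
    pd.DataFrame(
        [
            {
                "duns_id": a.duns_id, "year": a.year, "x": a.x, "y": a.y,
                "precision": a.precision.value, "source": a.source.value,
                "in_region": a.in_region,
            }
            for a in kept
        ]
    ).to_csv(out_dir / "locations.csv", index=False)

    # 5. categorization
    categories = categorize.load_categories(
        config.categories_path or str(default_categories_path())
    )
    assignment = categorize.categorize_bundle(
        bundle.establishments, categories, mode=config.mode
    )
    cat_counts = pd.Series(list(assignment.overall.values())).value_counts()
    report["category_totals"] = cat_counts.to_dict()
    report["stages"]["categorize"] = {
        "businesses": len(assignment.overall),
        "categorized": int((cat_counts.drop(categorize.UNCATEGORIZED, errors="ignore")).sum()),
        "uncategorized": int(cat_counts.get(categorize.UNCATEGORIZED, 0)),
    }
    _stage_log("categorize", **report["stages"]["categorize"])
    pd.DataFrame(
        [{"duns_id": d, "category": c} for d, c in sorted(assignment.overall.items())]
    ).to_csv(out_dir / "assignments.csv", index=False)
    if assignment.yearly is not None:
        pd.DataFrame(
            [
                {"duns_id": d, "year": y, "category": c}
                for (d, y), c in sorted(assignment.yearly.items())
            ]
        ).to_csv(out_dir / "assignments_yearly.csv", index=False)

    # 6. business-year points -> geography -> collapse -> counts
    points = [
        density.BusinessYearPoint(
            duns_id=a.duns_id, year=a.year,
            category=assignment.category_for(a.duns_id, a.year),
            x=a.x, y=a.y,
        )
        for a in kept
    ]
    points = density.assign_geography(points, region)
    year_range = config.year_range
    if year_range is None and points:
        yrs = [p.year for p in points]
        year_range = (min(yrs), max(yrs))
    table = density.count_by_geography(
        points, year_range=year_range,
        include_uncategorized=config.include_uncategorized_counts,
    )
    _stage_log("counts", cells=len(table.frame))
    table.frame.to_csv(out_dir / "counts.csv", index=False)

    # 7. trends
    trend_mode = "collapsed" if config.counts in ("collapsed", "both") else "raw"
    trends = density.fit_linear_trends(table, mode=trend_mode)
    pd.DataFrame(
        [
            {
                "geography_id": t.geography_id, "category": t.category,
                "slope": t.slope, "intercept": t.intercept,
                "slope_se": t.slope_se, "n_years": t.n_years,
            }
            for t in trends
        ]
    ).to_csv(out_dir / "trends.csv", index=False)
    _stage_log("trends", series=len(trends))
    report["stages"]["trends"] = {"series": len(trends)}

    with open(out_dir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
                for k, v in report.items()
            },
            fh, indent=2, default=str,
        )
    return RunResult(counts=table, trends=trends, assignment=assignment,
                     points=points, report=report)
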