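"""Read and write registry files in the tab-delimited NETS-style dialect.

A data delivery arrives as a set of tab-delimited ASCII files of mixed
shape — a wide establishment file (one row per business, yearly SIC/sales/
employee columns, most recent name and address), a long moves file, a
first-address file, and per-source geocode files — that partially overlap
and must be merged into one relational view keyed by the nine-digit DUNS
identifier.  File naming varies across deliveries, so files are recognized
by their column signature, not their name (an explicit override map is
available for pathological deliveries).

The dialect here is a faithful logical reconstruction of the documented
content of such deliveries, not a bit-exact parser for any proprietary
layout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    DUNS_RE,
    AddressVariant,
    EstablishmentRecord,
    GeocodeCandidate,
    GeocodeSource,
    MoveRecord,
    Precision,
    RegistryBundle,
    RegistryError,
    Role,
)

__all__ = ["Dialect", "read_registry", "write_tables", "identify_file"]

logger = logging.getLogger(__name__)

_YEAR_COL = re.compile(r"^(sic|sales|emp|est)_(\d{4})$")


@dataclass
class Dialect:
    """Tab-delimited dialect parameters plus optional file-kind overrides.

    ``file_overrides`` maps a file kind (``establishments``, ``moves``,
    ``first_address``, ``geocodes``) to an explicit file name, bypassing
    signature detection for that kind.
    """

    sep: str = "\t"
    encoding: str = "utf-8"
    file_overrides: dict[str, str] = field(default_factory=dict)


_SIGNATURES = {
    # kind -> required columns
    "moves": {"duns_id", "move_index", "move_year"},
    "geocodes": {"duns_id", "role", "lat", "lon", "precision", "source"},
    "establishments": {"duns_id", "company_name"},
    "first_address": {"duns_id", "street", "zip5"},
}


def identify_file(columns: Iterable[str]) -> Optional[str]:
    """Classify a file by its column signature (checked most-specific first)."""
    cols = set(columns)
    for kind in ("moves", "geocodes", "establishments", "first_address"):
        if _SIGNATURES[kind] <= cols:
            if kind == "first_address" and _SIGNATURES["establishments"] <= cols:
                continue
            return kind
    return None


def _read(path: Path, dialect: Dialect) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=dialect.sep, encoding=dialect.encoding, dtype=str, keep_default_na=False
    )


def _check_duns(df: pd.DataFrame, path: Path, report: list[str]) -> pd.DataFrame:
    bad = ~df["duns_id"].str.fullmatch(DUNS_RE.pattern)
    for row in df.index[bad]:
        report.append(f"{path.name}: row {row + 2}: malformed DUNS id {df.at[row, 'duns_id']!r}")
    return df.loc[~bad]


def read_registry(
    paths: Sequence[str | Path],
    dialect: Optional[Dialect] = None,
    report: Optional[list[str]] = None,
) -> RegistryBundle:
    """Merge a delivery's files into one :class:`RegistryBundle`.

    ``paths`` may list the files in any order and under any names; content
    signatures decide each file's kind.  Rows in auxiliary files that
    reference a DUNS id absent from the establishment file are reported
    (appended to ``report`` and logged) and dropped.  A duplicate DUNS id
    in the wide establishment file is a hard error; malformed (non-9-digit)
    DUNS ids are record-level errors reported with their row number.
    """
    dialect = dialect or Dialect()
    report = report if report is not None else []
    by_kind: dict[str, list[pd.DataFrame]] = {}
    override_names = {Path(v).name: k for k, v in dialect.file_overrides.items()}

    for p in map(Path, paths):
        if not p.exists():
            raise FileNotFoundError(p)
        df = _read(p, dialect)
        kind = override_names.get(p.name) or identify_file(df.columns)
        if kind is None:
            report.append(f"{p.name}: unrecognized column signature, skipped")
            logger.warning("unrecognized file %s (columns %s)", p, list(df.columns))
            continue
        by_kind.setdefault(kind, []).append(_check_duns(df, p, report))

    if "establishments" not in by_kind:
        raise RegistryError("no establishment (wide) file found among inputs")
    wide = pd.concat(by_kind["establishments"], ignore_index=True)
    if wide["duns_id"].duplicated().any():
        dups = sorted(wide.loc[wide["duns_id"].duplicated(), "duns_id"].unique())
        raise RegistryError(f"duplicate DUNS id(s) in wide establishment file: {dups[:5]}")

    year_cols: dict[tuple[str, int], str] = {}
    for c in wide.columns:
        m = _YEAR_COL.match(c)
        if m:
            year_cols[(m.group(1), int(m.group(2)))] = c

    establishments: list[EstablishmentRecord] = []
    recent_addresses: dict[str, AddressVariant] = {}
    for _, row in wide.iterrows():
        d = row["duns_id"]
        sic_by_year, sales_by_year, emp_by_year, est_flags = {}, {}, {}, {}
        years_active: set[int] = set()
        for (kind_, year), col in year_cols.items():
            val = row[col].strip()
            if not val:
                continue
            years_active.add(year)
            if kind_ == "sic":
                sic_by_year[year] = val
            elif kind_ == "sales":
                sales_by_year[year] = float(val)
            elif kind_ == "emp":
                emp_by_year[year] = int(float(val))
            elif kind_ == "est":
                est_flags[year] = val in ("1", "true", "True")
        establishments.append(
            EstablishmentRecord(
                duns_id=d,
                years_active=years_active,
                sic_by_year=sic_by_year,
                company_name=row.get("company_name", ""),
                trade_name=row.get("trade_name", "") or None,
                sales_by_year=sales_by_year,
                employees_by_year=emp_by_year,
                estimated_flags=est_flags,
            )
        )
        if "recent_street" in wide.columns and row["recent_street"]:
            recent_addresses[d] = AddressVariant(
                duns_id=d,
                role=Role.MOST_RECENT,
                address_string_primary=row["recent_street"],
                zip5=row.get("recent_zip5", ""),
                address_string_alternate=row.get("recent_street_alt", "") or None,
            )
    known = {e.duns_id for e in establishments}

    def _filter_known(df: pd.DataFrame, name: str) -> pd.DataFrame:
        unknown = ~df["duns_id"].isin(known)
        for row_i in df.index[unknown]:
            report.append(
                f"{name}: row {row_i + 2}: unknown DUNS id {df.at[row_i, 'duns_id']}, dropped"
            )
        if unknown.any():
            logger.warning("%s: dropped %d rows with unknown DUNS ids", name, int(unknown.sum()))
        return df.loc[~unknown]

    moves: list[MoveRecord] = []
    for df in by_kind.get("moves", []):
        df = _filter_known(df, "moves")
        for _, row in df.iterrows():
            k = int(row["move_index"])
            moves.append(
                MoveRecord(
                    duns_id=row["duns_id"],
                    move_index=k,
                    move_year=int(row["move_year"]),
                    origin_address=AddressVariant(
                        duns_id=row["duns_id"],
                        role=Role.move_origin(k),
                        address_string_primary=row["origin_street"],
                        zip5=row["origin_zip5"],
                        address_string_alternate=row.get("origin_street_alt", "") or None,
                    ),
                    destination_address=AddressVariant(
                        duns_id=row["duns_id"],
                        role=Role.move_destination(k),
                        address_string_primary=row["dest_street"],
                        zip5=row["dest_zip5"],
                        address_string_alternate=row.get("dest_street_alt", "") or None,
                    ),
                )
            )

    first_addresses: dict[str, AddressVariant] = {}
    for df in by_kind.get("first_address", []):
        df = _filter_known(df, "first_address")
        for _, row in df.iterrows():
            first_addresses[row["duns_id"]] = AddressVariant(
                duns_id=row["duns_id"],
                role=Role.FIRST,
                address_string_primary=row["street"],
                zip5=row["zip5"],
                address_string_alternate=row.get("street_alt", "") or None,
            )

    geocodes: dict[tuple[str, str], list[GeocodeCandidate]] = {}
    for df in by_kind.get("geocodes", []):
        df = _filter_known(df, "geocodes")
        for _, row in df.iterrows():
            cand = GeocodeCandidate(
                duns_id=row["duns_id"],
                role=row["role"],
                source=GeocodeSource(row["source"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                precision=Precision(row["precision"]),
            )
            geocodes.setdefault((cand.duns_id, cand.role), []).append(cand)

    for msg in report:
        logger.info("read_registry: %s", msg)
    return RegistryBundle(
        establishments=establishments,
        moves=moves,
        first_addresses=first_addresses,
        recent_addresses=recent_addresses,
        geocodes=geocodes,
    )


def _no_tabs(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object and df[col].astype(str).str.contains("\t").any():
            raise RegistryError(f"embedded tab in column {col}; tab is the field separator")
    return df


def write_tables(bundle: RegistryBundle, outdir: str | Path, dialect: Optional[Dialect] = None) -> dict[str, Path]:
    """Write a bundle back to the NETS-style dialect file set.

    Produces ``establishments.tsv`` (wide), ``moves.tsv``,
    ``first_address.tsv`` and one ``geocodes_<source>.tsv`` per source,
    with deterministic column order; ``read_registry`` on the result
    round-trips to an equal bundle.
    """
    dialect = dialect or Dialect()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    years = sorted({y for e in bundle.establishments for y in e.years_active})
    rows = []
    for e in sorted(bundle.establishments, key=lambda e: e.duns_id):
        rec = bundle.recent_addresses.get(e.duns_id)
        row = {
            "duns_id": e.duns_id,
            "company_name": e.company_name,
            "trade_name": e.trade_name or "",
            "recent_street": rec.address_string_primary if rec else "",
            "recent_street_alt": (rec.address_string_alternate or "") if rec else "",
            "recent_zip5": rec.zip5 if rec else "",
        }
        for y in years:
            row[f"sic_{y}"] = e.sic_by_year.get(y, "")
            row[f"sales_{y}"] = (
                f"{e.sales_by_year[y]:.2f}" if y in e.sales_by_year else ""
            )
            row[f"emp_{y}"] = str(e.employees_by_year[y]) if y in e.employees_by_year else ""
            row[f"est_{y}"] = (
                "" if y not in e.estimated_flags else ("1" if e.estimated_flags[y] else "0")
            )
        rows.append(row)
    wide = _no_tabs(pd.DataFrame(rows))
    path = outdir / "establishments.tsv"
    wide.to_csv(path, sep=dialect.sep, index=False, encoding=dialect.encoding)
    written["establishments"] = path

    mrows = [
        {
            "duns_id": m.duns_id,
            "move_index": m.move_index,
            "move_year": m.move_year,
            "origin_street": m.origin_address.address_string_primary,
            "origin_street_alt": m.origin_address.address_string_alternate or "",
            "origin_zip5": m.origin_address.zip5,
            "dest_street": m.destination_address.address_string_primary,
            "dest_street_alt": m.destination_address.address_string_alternate or "",
            "dest_zip5": m.destination_address.zip5,
        }
        for m in sorted(bundle.moves, key=lambda m: (m.duns_id, m.move_index))
    ]
    mcols = [
        "duns_id", "move_index", "move_year", "origin_street", "origin_street_alt",
        "origin_zip5", "dest_street", "dest_street_alt", "dest_zip5",
    ]
    path = outdir / "moves.tsv"
    _no_tabs(pd.DataFrame(mrows, columns=mcols)).to_csv(
        path, sep=dialect.sep, index=False, encoding=dialect.encoding
    )
    written["moves"] = path

    frows = [
        {
            "duns_id": d,
            "street": v.address_string_primary,
            "street_alt": v.address_string_alternate or "",
            "zip5": v.zip5,
        }
        for d, v in sorted(bundle.first_addresses.items())
    ]
    path = outdir / "first_address.tsv"
    _no_tabs(pd.DataFrame(frows, columns=["duns_id", "street", "street_alt", "zip5"])).to_csv(
        path, sep=dialect.sep, index=False, encoding=dialect.encoding
    )
    written["first_address"] = path

    by_source: dict[str, list[GeocodeCandidate]] = {}
    for cands in bundle.geocodes.values():
        for c in cands:
            by_source.setdefault(c.source.value, []).append(c)
    for source, cands in sorted(by_source.items()):
        grows = [
            {
                "duns_id": c.duns_id,
                "role": c.role,
                "source": c.source.value,
                "lat": repr(c.lat),
                "lon": repr(c.lon),
                "precision": c.precision.value,
            }
            for c in sorted(cands, key=lambda c: (c.duns_id, c.role))
        ]
        path = outdir / f"geocodes_{source}.tsv"
        _no_tabs(
            pd.DataFrame(grows, columns=["duns_id", "role", "source", "lat", "lon", "precision"])
        ).to_csv(path, sep=dialect.sep, index=False, encoding=dialect.encoding)
        written[f"geocodes_{source}"] = path

    return written
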