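"""Assign establishments to mutually exclusive researcher-defined categories.

Categories (food environment, alcohol outlets, physical-activity venues,
medical facilities, other daily destinations) are defined by sets of
eight-digit SIC codes or prefixes, optional text patterns on the company
and trade names (some venue types, e.g. YMCAs, are not consistently
captured by any SIC), and optional size thresholds on sales volume or
employee count (large supermarkets are distinguished from smaller grocers
by size, not SIC).  Mutual exclusivity is enforced by a priority rank: of
all matching definitions, the lowest rank wins.

Two assignment modes are provided.  *Overall* mode derives one SIC per
business for all years: the modal SIC if it covers at least 75 % of the
SIC-reporting years (threshold inclusive), otherwise the most recently
reported SIC — recent codes tend to be more specific and more likely
corrected.  *Yearly* mode reclassifies each business-year from that year's
own SIC, names and size fields, as a sensitivity analysis.

Also here: MET banding of physical-activity venues (light/moderate
1.6–5.9 METs vs vigorous >= 6 METs) and the review-sampling helper used to
vet candidate SIC codes against their 2010 rosters.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .model import EstablishmentRecord, RegistryError

__all__ = [
    "CategoryDefinition",
    "CategorySet",
    "load_categories",
    "UNCATEGORIZED",
    "Attributes",
    "majority_sic",
    "resolve_overall_sic",
    "match_definition",
    "assign_category",
    "assign_yearly",
    "assign_frame",
    "CategoryAssignment",
    "categorize_bundle",
    "met_band",
    "review_sample_size",
    "draw_review_sample",
    "evaluate_review",
]

UNCATEGORIZED = "uncategorized"

_NAME_PUNCT = str.maketrans({c: " " for c in ".,;:#'\"()/&-"})


def _normalize_name(s: Optional[str]) -> str:
    if not s:
        return ""
    return " ".join(s.upper().translate(_NAME_PUNCT).split())


class CategoryDefinition(BaseModel):
    """One researcher-defined category.

    ``sic_codes`` entries shorter than eight digits act as prefixes.
    ``met_value`` is the metabolic-equivalent rating for physical-activity
    categories.  ``priority_rank`` resolves multi-matches: lower wins, so
    size-restricted definitions (large supermarket) must rank above the
    residual category they carve out of (convenience/small grocery).
    """

    name: str
    sic_codes: list[str] = Field(default_factory=list)
    name_include_patterns: list[str] = Field(default_factory=list)
    name_exclude_patterns: list[str] = Field(default_factory=list)
    min_employees: Optional[int] = None
    max_employees: Optional[int] = None
    min_sales: Optional[float] = None
    max_sales: Optional[float] = None
    met_value: Optional[float] = None
    priority_rank: int

    @field_validator("met_value")
    @classmethod
    def _met_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("met_value must be positive")
        return v

    @field_validator("sic_codes")
    @classmethod
    def _sic_digits(cls, v):
        for code in v:
            if not re.fullmatch(r"\d{1,8}", code):
                raise ValueError(f"SIC code/prefix must be 1-8 digits: {code!r}")
        return v

    @property
    def has_size_rule(self) -> bool:
        return any(
            t is not None
            for t in (self.min_employees, self.max_employees, self.min_sales, self.max_sales)
        )


@dataclass
class CategorySet:
    definitions: list[CategoryDefinition]

    def __post_init__(self):
        ranks = [d.priority_rank for d in self.definitions]
        if len(set(ranks)) != len(ranks):
            raise RegistryError("priority_rank values must be unique across category definitions")
        self.definitions = sorted(self.definitions, key=lambda d: d.priority_rank)

    def __iter__(self):
        return iter(self.definitions)

    def __len__(self):
        return len(self.definitions)

    def names(self) -> list[str]:
        return [d.name for d in self.definitions]


def load_categories(path: str) -> CategorySet:
    """Load a category-definition YAML file (list of definition mappings)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "categories" in raw:
        raw = raw["categories"]
    try:
        defs = [CategoryDefinition(**entry) for entry in raw]
    except Exception as exc:
        raise RegistryError(f"invalid category definition file {path}: {exc}") from exc
    return CategorySet(defs)


@dataclass
class Attributes:
    """The per-business (or per-business-year) fields a definition sees."""

    sic: Optional[str]
    names: Sequence[str] = ()
    sales: Optional[float] = None
    employees: Optional[int] = None


def majority_sic(sic_by_year: dict[int, str], threshold: float = 0.75):
    """Modal SIC and its fraction of SIC-reporting years; None below threshold.

    The threshold is inclusive (a code reported in exactly 75 % of reporting
    years qualifies).  Ties at the mode resolve toward the most recently
    reported of the tied codes.  The denominator is years with a reported
    SIC, not all active years.
    """
    if not sic_by_year:
        raise RegistryError("majority_sic: no reported SIC codes")
    counts: dict[str, int] = {}
    last_seen: dict[str, int] = {}
    for year in sorted(sic_by_year):
        code = sic_by_year[year]
        counts[code] = counts.get(code, 0) + 1
        last_seen[code] = year
    top = max(counts.values())
    tied = [c for c, k in counts.items() if k == top]
    modal = max(tied, key=lambda c: last_seen[c])
    fraction = top / len(sic_by_year)
    if fraction < threshold:
        return None
    return modal, fraction


def resolve_overall_sic(record: EstablishmentRecord, threshold: float = 0.75) -> Optional[str]:
    """One SIC to characterize the business across all years.

    Majority rule first; businesses without a >= 75 % modal SIC take their
    most recently reported SIC.  Returns None when no SIC was ever reported.
    """
    if not record.sic_by_year:
        return None
    maj = majority_sic(record.sic_by_year, threshold=threshold)
    if maj is not None:
        return maj[0]
    return record.most_recent_sic()


def _sic_matches(sic: Optional[str], codes: Sequence[str]) -> Optional[str]:
    if sic is None:
        return None
    for code in codes:
        if sic == code or (len(code) < 8 and sic.startswith(code)):
            return code
    return None


def match_definition(attrs: Attributes, definition: CategoryDefinition) -> bool:
    """Does a business (or business-year) satisfy one category definition?

    A definition fires when the SIC matches (exact or prefix) OR a name
    pattern matches the normalized company/trade name, provided no exclude
    pattern matches and all present size thresholds are met.  Size fields
    missing from the record fail a threshold-bearing definition — absence
    of evidence of size is treated conservatively.
    """
    names = [_normalize_name(n) for n in attrs.names if n]
    name_hit = any(pat.upper() in n for pat in definition.name_include_patterns for n in names)
    sic_hit = _sic_matches(attrs.sic, definition.sic_codes) is not None
    if not (sic_hit or name_hit):
        return False
    if any(pat.upper() in n for pat in definition.name_exclude_patterns for n in names):
        return False
    if definition.min_employees is not None and (
        attrs.employees is None or attrs.employees < definition.min_employees
    ):
        return False
    if definition.max_employees is not None and (
        attrs.employees is None or attrs.employees > definition.max_employees
    ):
        return False
    if definition.min_sales is not None and (
        attrs.sales is None or attrs.sales < definition.min_sales
    ):
        return False
    if definition.max_sales is not None and (
        attrs.sales is None or attrs.sales > definition.max_sales
    ):
        return False
    return True


def assign_category(attrs: Attributes, categories: CategorySet) -> tuple[str, str]:
    """Category label for one attribute set, with the basis of the decision.

    Among matching definitions the lowest priority rank wins; no match
    yields the sentinel ``uncategorized``.  The basis is ``sic:<code>`` or
    ``name`` depending on which clause fired, ``no_sic``/``no_match`` for
    the sentinel.
    """
    for d in categories:
        if match_definition(attrs, d):
            hit = _sic_matches(attrs.sic, d.sic_codes)
            basis = f"sic:{hit}" if hit is not None else "name"
            return d.name, basis
    if attrs.sic is None and not any(attrs.names):
        return UNCATEGORIZED, "no_sic"
    return UNCATEGORIZED, "no_match"


def assign_yearly(
    record: EstablishmentRecord, categories: CategorySet, year: int
) -> tuple[str, str]:
    """Category from the SIC, names and size fields of one specific year."""
    if year not in record.years_active:
        raise RegistryError(f"{record.duns_id}: year {year} outside activity")
    attrs = Attributes(
        sic=record.sic_by_year.get(year),
        names=(record.company_name, record.trade_name or ""),
        sales=record.sales_by_year.get(year),
        employees=record.employees_by_year.get(year),
    )
    return assign_category(attrs, categories)


def assign_frame(df: pd.DataFrame, categories: CategorySet) -> pd.Series:
    """Vectorized category assignment over a DataFrame.

    Expects columns ``sic`` (str or NA), ``name_norm`` (pre-normalized,
    space-joined company+trade name), ``sales``, ``employees``.  Returns a
    Series of category labels aligned to ``df``.  Semantically identical to
    applying :func:`assign_category` row-wise; used on the hot path where
    hundreds of thousands of business-years are classified.
    """
    n = len(df)
    out = pd.Series(UNCATEGORIZED, index=df.index, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    sic = df["sic"].fillna("").to_numpy(dtype=object)
    names = df["name_norm"].fillna("").to_numpy(dtype=object)
    sales = pd.to_numeric(df["sales"], errors="coerce").to_numpy(dtype=float)
    emps = pd.to_numeric(df["employees"], errors="coerce").to_numpy(dtype=float)

    sic_s = pd.Series(sic, dtype="string")
    name_s = pd.Series(names, dtype="string")
    for d in categories:
        exact = {c for c in d.sic_codes if len(c) == 8}
        prefixes = tuple(c for c in d.sic_codes if len(c) < 8)
        hit = sic_s.isin(exact).to_numpy(dtype=bool)
        if prefixes:
            hit |= sic_s.str.startswith(prefixes).fillna(False).to_numpy(dtype=bool)
        for pat in d.name_include_patterns:
            hit |= name_s.str.contains(re.escape(pat.upper()), regex=True).fillna(
                False
            ).to_numpy(dtype=bool)
        for pat in d.name_exclude_patterns:
            hit &= ~name_s.str.contains(re.escape(pat.upper()), regex=True).fillna(
                False
            ).to_numpy(dtype=bool)
        if d.min_employees is not None:
            hit &= ~np.isnan(emps) & (emps >= d.min_employees)
        if d.max_employees is not None:
            hit &= ~np.isnan(emps) & (emps <= d.max_employees)
        if d.min_sales is not None:
            hit &= ~np.isnan(sales) & (sales >= d.min_sales)
        if d.max_sales is not None:
            hit &= ~np.isnan(sales) & (sales <= d.max_sales)
        take = hit & unassigned
        out[take] = d.name
        unassigned &= ~take
    return out


@dataclass
class CategoryAssignment:
    """Assignment output for one registry, in one mode."""

    mode: str  # "overall" | "yearly"
    overall: dict[str, str]  # duns_id -> category (both modes: overall uses it directly)
    yearly: Optional[dict[tuple[str, int], str]] = None
    basis: Optional[dict[str, str]] = None

    def category_for(self, duns_id: str, year: int) -> str:
        if self.mode == "yearly" and self.yearly is not None:
            return self.yearly.get((duns_id, year), UNCATEGORIZED)
        return self.overall.get(duns_id, UNCATEGORIZED)


def categorize_bundle(
    establishments: Sequence[EstablishmentRecord],
    categories: CategorySet,
    mode: str = "overall",
    majority_threshold: float = 0.75,
) -> CategoryAssignment:
    """Classify every establishment (overall mode) or business-year (yearly).

    Overall mode uses the resolved single SIC plus the most recently
    reported name, sales and employee fields; yearly mode uses each year's
    own fields via the vectorized path.
    """
    if mode not in ("overall", "yearly"):
        raise RegistryError(f"unknown categorization mode {mode!r}")
    overall: dict[str, str] = {}
    basis: dict[str, str] = {}
    rows = []
    for est in establishments:
        rows.append(
            {
                "duns_id": est.duns_id,
                "sic": resolve_overall_sic(est, threshold=majority_threshold),
                "name_norm": _normalize_name(
                    f"{est.company_name} {est.trade_name or ''}"
                ),
                "sales": est.most_recent(est.sales_by_year),
                "employees": est.most_recent(est.employees_by_year),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        cats = assign_frame(frame, categories)
        overall = dict(zip(frame["duns_id"], cats))

    yearly = None
    if mode == "yearly":
        yrows = []
        for est in establishments:
            nm = _normalize_name(f"{est.company_name} {est.trade_name or ''}")
            for year in sorted(est.years_active):
                yrows.append(
                    {
                        "duns_id": est.duns_id,
                        "year": year,
                        "sic": est.sic_by_year.get(year),
                        "name_norm": nm,
                        "sales": est.sales_by_year.get(year),
                        "employees": est.employees_by_year.get(year),
                    }
                )
        yframe = pd.DataFrame(yrows)
        yearly = {}
        if len(yframe):
            ycats = assign_frame(yframe, categories)
            yearly = {
                (d, int(y)): c
                for d, y, c in zip(yframe["duns_id"], yframe["year"], ycats)
            }
    return CategoryAssignment(mode=mode, overall=overall, yearly=yearly, basis=basis)


def met_band(met_value: float) -> str:
    """Band a physical-activity MET rating: light/moderate 1.6–5.9, vigorous >= 6.

    Ratings below 1.6 METs are sedentary and outside the banding scheme.
    Values in the open gap (5.9, 6.0) — possible only for ratings finer than
    the customary one-decimal precision — fall to light/moderate.
    """
    if met_value < 1.6:
        raise RegistryError(f"MET {met_value} below 1.6 is sedentary, outside the scheme")
    return "vigorous" if met_value >= 6.0 else "light_moderate"


def review_sample_size(frequency_2010: int) -> int:
    """How many establishments to manually review for one candidate SIC.

    Below 50 establishments in 2010, all are reviewed; between 50 and 250,
    a 20 % random sample (rounded up); above 250, a flat 50.
    """
    if frequency_2010 < 0:
        raise RegistryError("frequency must be nonnegative")
    if frequency_2010 < 50:
        return frequency_2010
    if frequency_2010 <= 250:
        return math.ceil(0.20 * frequency_2010)
    return 50


def draw_review_sample(
    businesses: Sequence[EstablishmentRecord], seed: int
) -> pd.DataFrame:
    """Seeded uniform review sample for one SIC's 2010 roster.

    Returns a worksheet with the name fields and an empty ``relevant``
    column for the reviewer to mark.
    """
    n = review_sample_size(len(businesses))
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(businesses), size=n, replace=False)) if businesses else []
    return pd.DataFrame(
        [
            {
                "duns_id": businesses[i].duns_id,
                "company_name": businesses[i].company_name,
                "trade_name": businesses[i].trade_name or "",
                "relevant": "",
            }
            for i in idx
        ]
    )


def evaluate_review(worksheet: pd.DataFrame) -> bool:
    """Include the SIC iff at least 50 % of reviewed businesses are relevant.

    ``relevant`` is truthy per row (1/0, y/n, true/false); exactly 50 %
    counts as inclusion.
    """
    if len(worksheet) == 0:
        return False
    truthy = {"1", "y", "yes", "true", "t"}
    marks = worksheet["relevant"].astype(str).str.strip().str.lower().isin(truthy)
    return marks.mean() >= 0.5
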