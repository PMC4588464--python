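"""Synthetic establishment registries with planted ground truth.

Licensed registry data cannot be redistributed, so every downstream stage
is exercised against generated registries in which the right answer is
known: each synthetic business has a true category, a true planar location
per year, and a known mover/duplicate status, recorded in a
:class:`TruthTable`.

The generator emulates the documented error processes of real deliveries:

* 21 annual snapshots (1990-2010 by default) with establishment birth and
  death, one row per business in the wide file;
* significant moves (street AND zip change) for ~10 % of businesses, up to
  eight moves each;
* SIC churn: ~7.7 % of businesses report a deviating primary SIC in some
  years, concentrated in early years (recent codes tend to be the
  corrected, more specific ones), sometimes often enough to break the 75 %
  majority;
* vendor geocode precision that improves with calendar time: the
  delivery's own coordinates are zip-level for a fraction of businesses
  that shrinks with the business's last observed year (vendors only began
  systematic geocoding mid-window, so businesses that closed early keep
  poor coordinates), 31 %/16 %/2 % at 1990/2000/2010 by default;
* re-geocoding providers (a gold-standard local engine over part of the
  region, a commercial point service, a commercial street-segment
  service) that rescue most zip-only businesses but fail entirely for a
  small address-quality-limited remainder (~1.3 %);
* ~3 % of locations (headquarters etc.) falling outside the study region;
* co-located same-category clusters with name variation, concentrated in
  categories where suite-sharing is common (health practitioners,
  light/moderate physical-activity venues).

Geography is a synthetic street grid in UTM 18N planar metres: streets run
east-west every 200 m, address numbers step 10 m along the street, and
five-digit zip zones tile the region in 5 km cells, so the significant-move
predicate (street AND zip change) is controllable on both margins and a
grid address is exactly invertible to coordinates (which is what the mock
geocoding providers do).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
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
from .projection import UTM_18N

__all__ = ["SynthParams", "TruthTable", "generate_registry", "plant_duplicates", "GRID"]


# ---------------------------------------------------------------- geography

@dataclass(frozen=True)
class _Grid:
    """The synthetic street grid, in UTM 18N planar metres."""

    e0: float = 555_000.0
    n0: float = 4_475_000.0
    width: float = 50_000.0
    height: float = 50_000.0
    street_spacing: float = 200.0
    lot_spacing: float = 10.0
    zip_cell: float = 5_000.0
    county_cols: int = 5
    county_rows: int = 2

    def address_to_xy(self, number: int, street_index: int) -> tuple[float, float]:
        return self.e0 + number * self.lot_spacing, self.n0 + street_index * self.street_spacing

    def zip_for(self, x: float, y: float) -> str:
        ix = int((x - self.e0) // self.zip_cell)
        iy = int((y - self.n0) // self.zip_cell)
        return f"{10000 + ix * 100 + iy}"

    def zip_centroid(self, x: float, y: float) -> tuple[float, float]:
        ix = math.floor((x - self.e0) / self.zip_cell)
        iy = math.floor((y - self.n0) / self.zip_cell)
        return (
            self.e0 + (ix + 0.5) * self.zip_cell,
            self.n0 + (iy + 0.5) * self.zip_cell,
        )

    def tract_centroid(self, x: float, y: float) -> tuple[float, float]:
        half = self.zip_cell / 2.0
        ix = math.floor((x - self.e0) / half)
        iy = math.floor((y - self.n0) / half)
        return (self.e0 + (ix + 0.5) * half, self.n0 + (iy + 0.5) * half)

    def county_id(self, x: float, y: float) -> Optional[str]:
        cw = self.width / self.county_cols
        ch = self.height / self.county_rows
        cx = int((x - self.e0) // cw)
        cy = int((y - self.n0) // ch)
        if 0 <= cx < self.county_cols and 0 <= cy < self.county_rows:
            return f"C{cy}{cx}"
        return None

    def county_features(self) -> list[dict]:
        """County polygons as GeoJSON features in geographic coordinates."""
        cw = self.width / self.county_cols
        ch = self.height / self.county_rows
        feats = []
        for cy in range(self.county_rows):
            for cx in range(self.county_cols):
                corners_planar = [
                    (self.e0 + cx * cw, self.n0 + cy * ch),
                    (self.e0 + (cx + 1) * cw, self.n0 + cy * ch),
                    (self.e0 + (cx + 1) * cw, self.n0 + (cy + 1) * ch),
                    (self.e0 + cx * cw, self.n0 + (cy + 1) * ch),
                ]
                ring = []
                for x, y in corners_planar + corners_planar[:1]:
                    lat, lon = UTM_18N.inverse(x, y)
                    ring.append([lon, lat])
                feats.append(
                    {
                        "type": "Feature",
                        "properties": {"geography_id": f"C{cy}{cx}"},
                        "geometry": {"type": "Polygon", "coordinates": [ring]},
                    }
                )
        return feats

    def region_geojson(self) -> dict:
        return {"type": "FeatureCollection", "features": self.county_features()}


GRID = _Grid()


# ------------------------------------------------------------------ naming

_ADJECTIVES = [
    "RIVERSIDE", "PARKSIDE", "GOLDEN", "SILVER", "HARBOR", "SUNSET",
    "LIBERTY", "EMPIRE", "CRESCENT", "LAKEVIEW", "HILLTOP", "MERIDIAN",
]
_SURNAMES = [
    "ROSSI", "NGUYEN", "GARCIA", "COHEN", "OBRIEN", "PATEL",
    "KOWALSKI", "JOHNSON", "RIVERA", "SCHMIDT", "OKAFOR", "LINDQVIST",
]
_FAST_FOOD_CHAINS = ["MCDONALDS", "BURGER KING", "WENDYS", "TACO BELL", "KFC"]

#: category -> (list of concrete 8-digit SICs, name noun, employee range, sales range)
_CATEGORY_PROFILE: dict[str, tuple[list[str], str, tuple[int, int], tuple[float, float]]] = {
    "large_supermarket": (["54110000"], "SUPERMARKET", (30, 90), (3e6, 2e7)),
    "warehouse_discount_food": (["53310000"], "WAREHOUSE CLUB", (120, 300), (2e7, 8e7)),
    "fast_food_restaurant": (["58120300"], "", (5, 30), (3e5, 2e6)),
    "pizza_restaurant": (["58120600"], "PIZZA", (3, 15), (2e5, 1e6)),
    "other_restaurant": (["58120100"], "GRILL", (4, 40), (2e5, 3e6)),
    "bar_drinking_place": (["58130000"], "TAVERN", (2, 15), (1e5, 1e6)),
    "liquor_store": (["59210000"], "WINES AND SPIRITS", (2, 8), (2e5, 2e6)),
    "fish_market": (["54210200"], "FISH MARKET", (2, 8), (1e5, 1e6)),
    "meat_market": (["54210100"], "MEATS", (2, 10), (1e5, 1.5e6)),
    "fruit_vegetable_market": (["54310000"], "PRODUCE", (2, 10), (1e5, 1e6)),
    "natural_food_market": (["54990000"], "NATURAL FOODS", (2, 12), (1e5, 1.2e6)),
    "bakery_candy_store": (["54610000", "54410000"], "BAKERY", (2, 12), (1e5, 1e6)),
    "convenience_small_grocery": (["54110000", "54120000"], "GROCERY", (2, 10), (1e5, 9e5)),
    "multi_use_pa_venue": (["79910100"], "FITNESS CENTER", (5, 40), (2e5, 4e6)),
    "vigorous_pa_venue": (["79910200", "79970100"], "ATHLETIC CLUB", (3, 25), (1e5, 2e6)),
    "light_moderate_pa_venue": (["79910300", "79920000", "79330000"], "BOWLING LANES", (3, 25), (1e5, 2e6)),
    "urgent_care_hospital": (["80620000"], "MEDICAL CENTER", (50, 900), (1e7, 4e8)),
    "health_practitioner_office": (["80110000", "80410000", "80490000"], "FAMILY PRACTICE", (2, 15), (2e5, 3e6)),
    "residential_health_facility": (["80510000"], "NURSING HOME", (20, 150), (1e6, 2e7)),
    "pharmacy": (["59120000"], "PHARMACY", (3, 20), (5e5, 6e6)),
    "mental_health_care": (["80630000", "80930000"], "COUNSELING", (2, 30), (1e5, 3e6)),
    "dental_care": (["80210000"], "DENTAL", (2, 12), (2e5, 2e6)),
    "bank": (["60210000"], "SAVINGS BANK", (5, 40), (1e6, 5e7)),
    "credit_union": (["60610000"], "CREDIT UNION", (3, 20), (5e5, 1e7)),
    "other_destination": (["59440000", "78320000", "82310000"], "EMPORIUM", (2, 30), (1e5, 4e6)),
    "uncategorized": (
        ["73890000", "81110100", "72310000", "65310000", "17310000", "47240000"],
        "SERVICES", (1, 25), (5e4, 3e6),
    ),
}

#: Table-like default mix (share of all establishments per category).
_DEFAULT_MIX = {
    "other_destination": 0.0792,
    "health_practitioner_office": 0.0366,
    "other_restaurant": 0.0201,
    "convenience_small_grocery": 0.0149,
    "dental_care": 0.0087,
    "bakery_candy_store": 0.0045,
    "bar_drinking_place": 0.0040,
    "mental_health_care": 0.0038,
    "pharmacy": 0.0036,
    "bank": 0.0030,
    "liquor_store": 0.0029,
    "pizza_restaurant": 0.0029,
    "multi_use_pa_venue": 0.0026,
    "light_moderate_pa_venue": 0.0026,
    "fast_food_restaurant": 0.0021,
    "vigorous_pa_venue": 0.0017,
    "natural_food_market": 0.0013,
    "fruit_vegetable_market": 0.0011,
    "meat_market": 0.0011,
    "large_supermarket": 0.0010,
    "residential_health_facility": 0.0010,
    "urgent_care_hospital": 0.0009,
    "fish_market": 0.0006,
    "credit_union": 0.0004,
    "warehouse_discount_food": 0.0002,
    "uncategorized": 0.7994,
}

#: Relative propensity of a category to co-locate (suite-sharing).
_COLOCATION_MULTIPLIER = {
    "health_practitioner_office": 4.0,
    "light_moderate_pa_venue": 3.3,
    "dental_care": 2.0,
    "mental_health_care": 2.0,
    "large_supermarket": 0.8,
}


# ------------------------------------------------------------------ params

@dataclass
class SynthParams:
    """Generator parameters; the defaults are the reference study conditions."""

    n_establishments: int = 1000
    year_range: tuple[int, int] = (1990, 2010)
    move_probability: float = 0.10
    sic_churn_rate: float = 0.077
    #: target share of businesses active in each year whose delivery-supplied
    #: geocode is zip-level (the delivered precision-drift pattern)
    zip_only_fraction_by_year: dict[int, float] = field(
        default_factory=lambda: {1990: 0.31, 2000: 0.16, 2010: 0.02}
    )
    #: target share still zip-level after re-geocoding (all providers failed
    #: AND vendor coordinates were zip-level)
    residual_zip_fraction_by_year: dict[int, float] = field(
        default_factory=lambda: {1990: 0.05, 2000: 0.02, 2010: 0.01}
    )
    #: P(all re-geocoders fail | vendor geocode better than zip).
    provider_failure_base: float = 0.005
    #: fraction of businesses whose best provider result is street-segment only
    street_only_rate: float = 0.05
    out_of_region_rate: float = 0.03
    colocation_cluster_rate: float = 0.15
    sic_missing_rate: float = 0.02
    category_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.year_range
        if lo > hi:
            raise RegistryError(f"degenerate year_range {self.year_range}")
        for name in (
            "move_probability", "sic_churn_rate", "provider_failure_base",
            "street_only_rate", "out_of_region_rate", "colocation_cluster_rate",
            "sic_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise RegistryError(f"{name}={v} outside [0, 1]")
        unknown = set(self.category_mix) - set(_CATEGORY_PROFILE)
        if unknown:
            raise RegistryError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.category_mix.values())
        if total <= 0:
            raise RegistryError("category_mix weights must sum to a positive value")
        self.category_mix = {k: v / total for k, v in self.category_mix.items()}


def _interp_by_year(table: dict[int, float], year: int) -> float:
    """Piecewise-linear interpolation of a year-keyed rate table."""
    years = sorted(table)
    return float(np.interp(year, years, [table[y] for y in years]))


#: geometric parameter of the establishment-lifespan distribution
#: (span in snapshots = 1 + Geometric(p), minimum two snapshots, capped at
#: the window end); mean uncapped lifespan ~9 years
_LIFESPAN_P = 0.12


def _death_year_weights(year_range: tuple[int, int]) -> dict[int, np.ndarray]:
    """P(last active year = d | active in Y), for each calendar year Y.

    Derived analytically from the generator's own birth/death process:
    birth uniform on [lo, hi-1], lifespan 1 + Geometric(p) snapshots,
    censored at the window end.
    """
    lo, hi = year_range
    births = np.arange(lo, hi)  # birth year (hi excluded by construction)
    n_b = len(births)
    joint = np.zeros((n_b, hi - lo + 1))  # P(birth, death)
    for i, b in enumerate(births):
        max_span = hi - b + 1
        # span = 1 + G, G >= 1: P(span = s) = (1-p)^(s-2) p for s in 2..
        for s in range(2, max_span):
            joint[i, b + s - 1 - lo] += (1 - _LIFESPAN_P) ** (s - 2) * _LIFESPAN_P / n_b
        joint[i, hi - lo] += (1 - _LIFESPAN_P) ** max(0, max_span - 2) / n_b
    out: dict[int, np.ndarray] = {}
    deaths = np.arange(lo, hi + 1)
    for year in range(lo, hi + 1):
        active = np.zeros(hi - lo + 1)
        for i, b in enumerate(births):
            if b <= year:
                active[deaths >= year] += joint[i, deaths >= year]
        total = active.sum()
        out[year] = active / total if total > 0 else active
    return out


def _calibrate_cohort_curve(
    targets: dict[int, float],
    year_range: tuple[int, int],
    scale_by: Optional[dict[int, float]] = None,
) -> dict[int, float]:
    """Invert calendar-year target shares into a per-cohort probability curve.

    The generator draws one precision (or failure) state per business, as a
    function of its last active year d, but the documented drift patterns
    are shares among businesses *active in* a calendar year Y — a mixture
    over death cohorts.  With q(d) piecewise linear on the target knots,
    share(Y) = sum_d P(d | active in Y) * scale(d) * q(d) is linear in the
    knot values, so the knots solve a small least-squares system (clipped
    to [0, 1]).  ``scale_by`` supplies the per-cohort factor scale(d) for
    conditional processes (e.g. failure given zip-level).
    """
    knots = sorted(targets)
    if len(knots) == 1:
        return {knots[0]: min(1.0, max(0.0, next(iter(targets.values()))))}
    lo, hi = year_range
    deaths = np.arange(lo, hi + 1)
    weights = _death_year_weights(year_range)
    # hat-function basis of piecewise-linear interpolation on the knots
    basis = np.zeros((len(deaths), len(knots)))
    for j in range(len(knots)):
        unit = np.zeros(len(knots))
        unit[j] = 1.0
        basis[:, j] = np.interp(deaths, knots, unit)
    scale = np.array([scale_by.get(int(d), 0.0) if scale_by else 1.0 for d in deaths])
    A = np.array([(weights[y] * scale) @ basis for y in knots])
    s = np.array([targets[y] for y in knots])
    q, *_ = np.linalg.lstsq(A, s, rcond=None)
    return {y: float(np.clip(v, 0.0, 1.0)) for y, v in zip(knots, q)}


@dataclass
class TruthTable:
    """Planted ground truth for one generated registry."""

    true_category: dict[str, str]
    true_location_by_year: dict[str, dict[int, tuple[float, float]]]
    is_mover: dict[str, bool]
    in_region: dict[str, bool]
    collapse_group: dict[str, str] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = []
        for d, cat in self.true_category.items():
            rows.append(
                {
                    "duns_id": d,
                    "true_category": cat,
                    "is_mover": self.is_mover[d],
                    "in_region": self.in_region[d],
                    "collapse_group": self.collapse_group.get(d, d),
                }
            )
        return pd.DataFrame(rows)

    def locations_frame(self) -> pd.DataFrame:
        rows = []
        for d, by_year in self.true_location_by_year.items():
            for year, (x, y) in sorted(by_year.items()):
                rows.append({"duns_id": d, "year": year, "x": x, "y": y})
        return pd.DataFrame(rows)


# --------------------------------------------------------------- generator

def _street_string(rng, number: int, street_index: int, alternate: bool) -> str:
    # primary uses the abbreviated suffix; the alternate copy varies case,
    # suffix spelling and punctuation but normalizes to the same form
    if not alternate:
        return f"{number} GRID{street_index} ST"
    return f"{number} Grid{street_index} Street."


def _company_name(rng, category: str, use_name_rule: bool) -> str:
    sics, noun, _, _ = _CATEGORY_PROFILE[category]
    if category == "fast_food_restaurant":
        chain = _FAST_FOOD_CHAINS[rng.integers(len(_FAST_FOOD_CHAINS))]
        return f"{chain} #{rng.integers(100, 9999)}"
    if category == "multi_use_pa_venue" and use_name_rule:
        return f"YMCA OF GRIDVILLE BRANCH {rng.integers(1, 99)}"
    stem = (
        _ADJECTIVES[rng.integers(len(_ADJECTIVES))]
        if rng.random() < 0.5
        else _SURNAMES[rng.integers(len(_SURNAMES))]
    )
    return f"{stem} {noun}".strip()


def generate_registry(params: SynthParams) -> tuple[RegistryBundle, TruthTable]:
    """Generate a registry bundle and its truth table.

    Deterministic for a fixed (params, seed): byte-identical files on
    rewrite.  Realized mover and SIC-churn fractions are per-business
    Bernoulli draws, so they converge to the parameters as n grows.
    """
    rng = np.random.default_rng(params.seed)
    grid = GRID
    lo, hi = params.year_range
    n_streets = int(grid.height // grid.street_spacing)
    n_lots = int(grid.width // grid.lot_spacing)

    cats = list(params.category_mix)
    weights = np.array([params.category_mix[c] for c in cats])

    establishments: list[EstablishmentRecord] = []
    moves: list[MoveRecord] = []
    first_addresses: dict[str, AddressVariant] = {}
    recent_addresses: dict[str, AddressVariant] = {}
    geocodes: dict[tuple[str, str], list[GeocodeCandidate]] = {}
    truth = TruthTable({}, {}, {}, {})

    # sites of already-placed in-region non-movers, per category, for clustering
    sites_by_category: dict[str, list[tuple[int, int]]] = {}
    all_sics = [s for prof in _CATEGORY_PROFILE.values() for s in prof[0]]

    # invert the calendar-year precision targets into per-cohort curves
    q_zip = _calibrate_cohort_curve(params.zip_only_fraction_by_year, params.year_range)
    zip_scale = {d: _interp_by_year(q_zip, d) for d in range(lo, hi + 1)}
    f_fail_given_zip = _calibrate_cohort_curve(
        params.residual_zip_fraction_by_year, params.year_range, scale_by=zip_scale
    )

    def draw_site(in_region: bool) -> tuple[int, int]:
        if in_region:
            return int(rng.integers(0, n_lots)), int(rng.integers(0, n_streets))
        # east of the study region
        return int(rng.integers(n_lots + 200, n_lots + 1200)), int(rng.integers(0, n_streets))

    def draw_cluster_host(category: str):
        """An existing same-category site to share, or None.

        Co-located records model concurrent suite-sharing, so a joiner also
        aligns its birth year inside the host's active span.
        """
        mult = _COLOCATION_MULTIPLIER.get(category, 1.0)
        eff = min(0.7, params.colocation_cluster_rate * mult)
        pool = sites_by_category.get(category, [])
        if pool and rng.random() < eff:
            return pool[rng.integers(len(pool))]
        return None

    def make_variant(duns: str, role: str, num: int, street: int) -> AddressVariant:
        x, y = grid.address_to_xy(num, street)
        return AddressVariant(
            duns_id=duns,
            role=role,
            address_string_primary=_street_string(rng, num, street, alternate=False),
            address_string_alternate=_street_string(rng, num, street, alternate=True),
            zip5=grid.zip_for(x, y),
        )

    def add_candidate(c: GeocodeCandidate) -> None:
        geocodes.setdefault((c.duns_id, c.role), []).append(c)

    def emit_geocodes(duns: str, role: str, x: float, y: float, *, vendor_zip: bool,
                      provider_failed: bool, street_only: bool, is_vendor_role: bool) -> None:
        """Candidates for one role at true planar (x, y)."""
        lat_t, lon_t = UTM_18N.inverse(x, y)
        if is_vendor_role:
            if vendor_zip:
                zx, zy = grid.zip_centroid(x, y)
                vlat, vlon = UTM_18N.inverse(zx, zy)
                add_candidate(GeocodeCandidate(duns, role, GeocodeSource.VENDOR_SUPPLIED,
                                               vlat, vlon, Precision.ZIP))
            else:
                r = rng.random()
                if r < 0.5:
                    vx, vy, prec = x + 10.0, y, Precision.BLOCK_FACE
                elif r < 0.9:
                    vx, vy, prec = x + 20.0, y, Precision.STREET_SEGMENT
                else:
                    vx, vy = grid.tract_centroid(x, y)
                    prec = Precision.TRACT_CENTROID
                vlat, vlon = UTM_18N.inverse(vx, vy)
                add_candidate(GeocodeCandidate(duns, role, GeocodeSource.VENDOR_SUPPLIED,
                                               vlat, vlon, prec))
        if provider_failed:
            return
        if street_only:
            slat, slon = UTM_18N.inverse(x + 30.0, y)
            add_candidate(GeocodeCandidate(duns, role, GeocodeSource.COMMERCIAL_STREET,
                                           slat, slon, Precision.STREET_SEGMENT))
            return
        add_candidate(GeocodeCandidate(duns, role, GeocodeSource.COMMERCIAL_POINT,
                                       lat_t, lon_t, Precision.POINT))
        # the gold-standard local engine covers the 'city': southern county row
        if grid.n0 <= y < grid.n0 + grid.height / grid.county_rows:
            add_candidate(GeocodeCandidate(duns, role, GeocodeSource.GOLD_LOCAL,
                                           lat_t, lon_t, Precision.POINT))
        slat, slon = UTM_18N.inverse(x + 30.0, y)
        add_candidate(GeocodeCandidate(duns, role, GeocodeSource.COMMERCIAL_STREET,
                                       slat, slon, Precision.STREET_SEGMENT))

    for i in range(params.n_establishments):
        duns = f"{100000000 + i}"
        category = cats[rng.choice(len(cats), p=weights)]
        in_region = rng.random() >= params.out_of_region_rate

        is_mover = in_region and rng.random() < params.move_probability
        # a mover cannot share a clustering site (its location changes)
        host = draw_cluster_host(category) if in_region and not is_mover else None

        # lifespan: at least two annual snapshots; cluster joiners start
        # while their host is active (co-location is concurrent)
        if host is not None:
            h_num, h_street, h_birth, h_death = host
            birth = int(rng.integers(h_birth, min(h_death, hi - 1) + 1))
        else:
            birth = int(rng.integers(lo, hi))  # lo..hi-1
        span = 1 + int(rng.geometric(_LIFESPAN_P))
        death = min(hi, birth + span - 1)
        years = set(range(birth, death + 1))

        num, street = (h_num, h_street) if host is not None else draw_site(in_region)
        x0, y0 = grid.address_to_xy(num, street)

        move_sites: list[tuple[int, int]] = []
        move_years: list[int] = []
        if is_mover:
            max_moves = min(8, len(years) - 1)
            k = min(max_moves, 1 + int(rng.geometric(0.55)) - 1)
            move_years = sorted(
                int(y) for y in rng.choice(
                    np.arange(birth + 1, death + 1), size=k, replace=False
                )
            )
            prev = (num, street)
            for _ in move_years:
                while True:
                    cand = draw_site(in_region)
                    cx, cy = grid.address_to_xy(*cand)
                    px, py = grid.address_to_xy(*prev)
                    if cand[1] != prev[1] and grid.zip_for(cx, cy) != grid.zip_for(px, py):
                        break
                move_sites.append(cand)
                prev = cand

        # true location per active year
        locs: dict[int, tuple[float, float]] = {}
        site_seq = [(num, street)] + move_sites
        for year in sorted(years):
            idx = sum(1 for my in move_years if year >= my)
            locs[year] = grid.address_to_xy(*site_seq[idx])

        # SIC reporting with churn and occasional missingness
        true_sic = _CATEGORY_PROFILE[category][0][
            rng.integers(len(_CATEGORY_PROFILE[category][0]))
        ]
        reporting = [y for y in sorted(years) if rng.random() >= params.sic_missing_rate]
        if not reporting:
            reporting = [max(years)]
        sic_by_year = {y: true_sic for y in reporting}
        if rng.random() < params.sic_churn_rate and len(reporting) >= 2:
            # deviant years are early ones; most churners keep a >= 75 % majority
            frac = 0.2 if rng.random() < 0.8 else 0.4
            n_dev = max(1, int(frac * len(reporting)))
            n_dev = min(n_dev, len(reporting) - 1)
            deviant = all_sics[rng.integers(len(all_sics))]
            for y in reporting[:n_dev]:
                sic_by_year[y] = deviant

        # size fields consistent with the category's size rules
        _, _, emp_range, sales_range = _CATEGORY_PROFILE[category]
        emp0 = int(rng.integers(emp_range[0], emp_range[1] + 1))
        sales0 = float(rng.uniform(*sales_range))
        employees_by_year = {}
        sales_by_year = {}
        estimated_flags = {}
        for year in sorted(years):
            jitter = 1.0 + 0.1 * (rng.random() - 0.5)
            employees_by_year[year] = max(emp_range[0], int(round(emp0 * jitter)))
            sales_by_year[year] = round(sales0 * jitter, 2)
            estimated_flags[year] = bool(rng.random() < 0.2)

        use_name_rule = rng.random() < 0.5
        company = _company_name(rng, category, use_name_rule)
        if category == "multi_use_pa_venue" and use_name_rule:
            # generic SIC: only the name identifies the venue
            sic_by_year = {y: "82990000" for y in reporting}
            true_sic = "82990000"
        trade = f"THE {company}" if rng.random() < 0.3 else None

        establishments.append(
            EstablishmentRecord(
                duns_id=duns, years_active=years, sic_by_year=sic_by_year,
                company_name=company, trade_name=trade,
                sales_by_year=sales_by_year, employees_by_year=employees_by_year,
                estimated_flags=estimated_flags,
            )
        )

        first_addresses[duns] = make_variant(duns, Role.FIRST, num, street)
        last_site = site_seq[-1]
        recent_addresses[duns] = make_variant(duns, Role.MOST_RECENT, *last_site)
        prev_site = (num, street)
        for j, (my, site) in enumerate(zip(move_years, move_sites), start=1):
            moves.append(
                MoveRecord(
                    duns_id=duns, move_index=j, move_year=my,
                    origin_address=make_variant(duns, Role.move_origin(j), *prev_site),
                    destination_address=make_variant(duns, Role.move_destination(j), *site),
                )
            )
            prev_site = site

        # geocode error processes, tied to the business's last observed year
        vendor_zip = rng.random() < _interp_by_year(q_zip, death)
        if vendor_zip:
            p_fail = _interp_by_year(f_fail_given_zip, death)
        else:
            p_fail = params.provider_failure_base
        provider_failed = rng.random() < p_fail
        street_only = (not provider_failed) and rng.random() < params.street_only_rate

        # vendor supplies coordinates for most_recent and each move role;
        # providers re-geocode every role in the comprehensive address file
        vendor_roles = {Role.MOST_RECENT} | {
            Role.move_origin(j) for j in range(1, len(move_years) + 1)
        } | {Role.move_destination(j) for j in range(1, len(move_years) + 1)}
        role_sites = {Role.FIRST: (num, street), Role.MOST_RECENT: last_site}
        prev_site = (num, street)
        for j, site in enumerate(move_sites, start=1):
            role_sites[Role.move_origin(j)] = prev_site
            role_sites[Role.move_destination(j)] = site
            prev_site = site
        for role, site in role_sites.items():
            sx, sy = grid.address_to_xy(*site)
            emit_geocodes(
                duns, role, sx, sy,
                vendor_zip=vendor_zip, provider_failed=provider_failed,
                street_only=street_only, is_vendor_role=role in vendor_roles,
            )

        if in_region and not is_mover:
            sites_by_category.setdefault(category, []).append((num, street, birth, death))

        truth.true_category[duns] = category
        truth.true_location_by_year[duns] = locs
        truth.is_mover[duns] = bool(is_mover)
        truth.in_region[duns] = bool(in_region)
        truth.collapse_group[duns] = duns

    bundle = RegistryBundle(
        establishments=establishments, moves=moves,
        first_addresses=first_addresses, recent_addresses=recent_addresses,
        geocodes=geocodes,
    )
    return bundle, truth


def plant_duplicates(
    bundle: RegistryBundle,
    truth: TruthTable,
    k_per_site: int,
    seed: int,
    n_sites: Optional[int] = None,
) -> tuple[RegistryBundle, TruthTable]:
    """Add co-located same-category clone records with perturbed names.

    Each selected site business gains ``k_per_site - 1`` clones at the same
    address with the same category, years and size fields; names differ
    only by suffix/punctuation edits so that name-rule matches survive.
    The truth table records the collapse group.  ``k_per_site=1`` is the
    identity.
    """
    if k_per_site < 1:
        raise RegistryError("k_per_site must be >= 1")
    if k_per_site == 1:
        return bundle, truth
    rng = np.random.default_rng(seed)
    candidates = [
        e for e in bundle.establishments
        if truth.in_region.get(e.duns_id, True)
        and not truth.is_mover.get(e.duns_id, False)
        and truth.true_category.get(e.duns_id) != "uncategorized"
    ]
    if n_sites is not None and n_sites < len(candidates):
        idx = sorted(rng.choice(len(candidates), size=n_sites, replace=False))
        candidates = [candidates[i] for i in idx]

    used = {e.duns_id for e in bundle.establishments}
    next_id = 900_000_000
    suffixes = [" LLC", " INC", " CO", " GROUP", " ASSOCIATES"]
    for host in candidates:
        for j in range(k_per_site - 1):
            while str(next_id) in used:
                next_id += 1
            clone_id = str(next_id)
            used.add(clone_id)
            next_id += 1
            suffix = suffixes[int(rng.integers(len(suffixes)))]
            clone = EstablishmentRecord(
                duns_id=clone_id,
                years_active=set(host.years_active),
                sic_by_year=dict(host.sic_by_year),
                company_name=host.company_name + suffix,
                trade_name=host.trade_name,
                sales_by_year=dict(host.sales_by_year),
                employees_by_year=dict(host.employees_by_year),
                estimated_flags=dict(host.estimated_flags),
            )
            bundle.establishments.append(clone)

            def _copy_variant(v: AddressVariant) -> AddressVariant:
                return AddressVariant(
                    duns_id=clone_id, role=v.role,
                    address_string_primary=v.address_string_primary,
                    address_string_alternate=v.address_string_alternate,
                    zip5=v.zip5,
                )

            bundle.first_addresses[clone_id] = _copy_variant(
                bundle.first_addresses[host.duns_id]
            )
            bundle.recent_addresses[clone_id] = _copy_variant(
                bundle.recent_addresses[host.duns_id]
            )
            for (d, role), cands in list(bundle.geocodes.items()):
                if d == host.duns_id:
                    bundle.geocodes[(clone_id, role)] = [
                        GeocodeCandidate(clone_id, role, c.source, c.lat, c.lon, c.precision)
                        for c in cands
                    ]
            truth.true_category[clone_id] = truth.true_category[host.duns_id]
            truth.true_location_by_year[clone_id] = dict(
                truth.true_location_by_year[host.duns_id]
            )
            truth.is_mover[clone_id] = False
            truth.in_region[clone_id] = truth.in_region[host.duns_id]
            truth.collapse_group[clone_id] = host.duns_id
    return bundle, truth
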