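"""Core domain types for longitudinal establishment registries.

The registry model follows the logical content of NETS-style data
deliveries: annual January snapshots of business establishments keyed by a
stable nine-digit DUNS identifier, with yearly eight-digit SIC codes, sales
and employee counts, a relocation history of "significant moves" (street
address AND five-digit zip both changed), and geocodes of varying spatial
precision from multiple sources.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "DUNS_RE",
    "Role",
    "EstablishmentRecord",
    "AddressVariant",
    "MoveRecord",
    "GeocodeSource",
    "Precision",
    "GeocodeCandidate",
    "LocationAssignment",
    "RegistryBundle",
    "RegistryError",
]

DUNS_RE = re.compile(r"^\d{9}$")


class RegistryError(ValueError):
    """Raised for structural violations of the registry model."""


class Role:
    """Location-role labels for one business.

    Roles are plain strings of the forms ``first``, ``most_recent``,
    ``move_origin_<k>`` and ``move_destination_<k>`` (k is the 1-based move
    ordinal).  Helpers here build and parse them.
    """

    FIRST = "first"
    MOST_RECENT = "most_recent"

    @staticmethod
    def move_origin(k: int) -> str:
        return f"move_origin_{k}"

    @staticmethod
    def move_destination(k: int) -> str:
        return f"move_destination_{k}"

    _MOVE_RE = re.compile(r"^move_(origin|destination)_(\d+)$")

    @classmethod
    def parse_move(cls, role: str) -> Optional[tuple[str, int]]:
        """Return (kind, ordinal) for a move role, else None."""
        m = cls._MOVE_RE.match(role)
        return (m.group(1), int(m.group(2))) if m else None

    @classmethod
    def is_valid(cls, role: str) -> bool:
        return role in (cls.FIRST, cls.MOST_RECENT) or cls.parse_move(role) is not None


@dataclass
class AddressVariant:
    """One address string for one business location-role.

    Two versions of the string are retained per location because the same
    address is frequently recorded with character-level deviations across
    files; ``normalized`` is the canonical comparison form (see
    :func:`bizscape.addressbook.normalize_address`).
    """

    duns_id: str
    role: str
    address_string_primary: str
    zip5: str
    address_string_alternate: Optional[str] = None
    normalized: Optional[str] = None

    def __post_init__(self):
        if self.zip5 and not re.fullmatch(r"\d{5}", self.zip5):
            raise RegistryError(
                f"zip5 must be 5 digits, got {self.zip5!r} for {self.duns_id}/{self.role}"
            )


@dataclass
class EstablishmentRecord:
    """One business establishment across the study window."""

    duns_id: str
    years_active: set[int]
    sic_by_year: dict[int, str] = field(default_factory=dict)
    company_name: str = ""
    trade_name: Optional[str] = None
    sales_by_year: dict[int, float] = field(default_factory=dict)
    employees_by_year: dict[int, int] = field(default_factory=dict)
    estimated_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not DUNS_RE.match(self.duns_id):
            raise RegistryError(f"malformed DUNS id {self.duns_id!r}")
        if not self.years_active:
            raise RegistryError(f"{self.duns_id}: years_active is empty")
        extra = set(self.sic_by_year) - self.years_active
        if extra:
            raise RegistryError(f"{self.duns_id}: SIC reported outside active years {sorted(extra)}")

    @property
    def last_active_year(self) -> int:
        return max(self.years_active)

    @property
    def first_active_year(self) -> int:
        return min(self.years_active)

    def most_recent_sic(self) -> Optional[str]:
        """SIC from the latest SIC-reporting year, or None if never reported."""
        if not self.sic_by_year:
            return None
        return self.sic_by_year[max(self.sic_by_year)]

    def most_recent(self, by_year: dict[int, object]):
        if not by_year:
            return None
        return by_year[max(by_year)]


@dataclass
class MoveRecord:
    """One significant move (street AND zip changed) of one business."""

    duns_id: str
    move_index: int
    move_year: int
    origin_address: AddressVariant
    destination_address: AddressVariant

    def __post_init__(self):
        if self.move_index < 1:
            raise RegistryError(f"{self.duns_id}: move_index must be >= 1")


class GeocodeSource(str, enum.Enum):
    """Candidate providers in descending a-priori quality.

    ``gold_local`` models a locally authoritative parcel-based engine,
    ``commercial_point`` and ``commercial_street`` a commercial geocoder's
    point and interpolated street-segment services, ``vendor_supplied`` the
    coordinates shipped with the data delivery (the fallback of last resort).
    """

    GOLD_LOCAL = "gold_local"
    COMMERCIAL_POINT = "commercial_point"
    COMMERCIAL_STREET = "commercial_street"
    VENDOR_SUPPLIED = "vendor_supplied"


#: Merge priority: lower number wins.
SOURCE_PRIORITY = {
    GeocodeSource.GOLD_LOCAL: 0,
    GeocodeSource.COMMERCIAL_POINT: 1,
    GeocodeSource.COMMERCIAL_STREET: 2,
    GeocodeSource.VENDOR_SUPPLIED: 3,
}


class Precision(str, enum.Enum):
    """Spatial precision of a geocode, best to worst."""

    POINT = "point"
    BLOCK_FACE = "block_face"
    STREET_SEGMENT = "street_segment"
    BLOCK_GROUP = "block_group"
    TRACT_CENTROID = "tract_centroid"
    ZIP = "zip"


#: Rank on the precision scale: lower is more precise.
PRECISION_RANK = {p: i for i, p in enumerate(Precision)}


@dataclass(frozen=True)
class GeocodeCandidate:
    """Coordinates + precision + source for one (business, location-role)."""

    duns_id: str
    role: str
    source: GeocodeSource
    lat: float
    lon: float
    precision: Precision

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0 or not -180.0 <= self.lon <= 180.0:
            raise RegistryError(
                f"{self.duns_id}/{self.role}: coordinates ({self.lat}, {self.lon}) out of range"
            )
        if (
            self.source in (GeocodeSource.GOLD_LOCAL, GeocodeSource.COMMERCIAL_POINT)
            and self.precision is not Precision.POINT
        ):
            raise RegistryError(
                f"{self.duns_id}/{self.role}: source {self.source.value} must be point precision"
            )


@dataclass
class LocationAssignment:
    """Resolved planar location for one business-year.

    ``x``/``y`` are projected metres rounded to the 10 m grid; the rounding
    makes 'same location' a well-defined equality test downstream.
    """

    duns_id: str
    year: int
    x: float
    y: float
    precision: Precision
    source: GeocodeSource
    in_region: bool = True


@dataclass
class RegistryBundle:
    """A merged registry: the relational view of one data delivery."""

    establishments: list[EstablishmentRecord]
    moves: list[MoveRecord] = field(default_factory=list)
    first_addresses: dict[str, AddressVariant] = field(default_factory=dict)
    recent_addresses: dict[str, AddressVariant] = field(default_factory=dict)
    geocodes: dict[tuple[str, str], list[GeocodeCandidate]] = field(default_factory=dict)

    def __post_init__(self):
        known = {e.duns_id for e in self.establishments}
        if len(known) != len(self.establishments):
            raise RegistryError("duplicate DUNS ids among establishments")
        for m in self.moves:
            if m.duns_id not in known:
                raise RegistryError(f"move references unknown DUNS {m.duns_id}")
        for d in list(self.first_addresses) + list(self.recent_addresses):
            if d not in known:
                raise RegistryError(f"address references unknown DUNS {d}")

    @property
    def by_duns(self) -> dict[str, EstablishmentRecord]:
        return {e.duns_id: e for e in self.establishments}

    @property
    def vendor_geocodes(self) -> dict[tuple[str, str], GeocodeCandidate]:
        """The delivery-supplied candidate per (duns_id, role), where present."""
        out = {}
        for key, cands in self.geocodes.items():
            for c in cands:
                if c.source is GeocodeSource.VENDOR_SUPPLIED:
                    out[key] = c
        return out

    def moves_for(self, duns_id: str) -> list[MoveRecord]:
        ms = sorted((m for m in self.moves if m.duns_id == duns_id), key=lambda m: m.move_index)
        for i, m in enumerate(ms, start=1):
            if m.move_index != i:
                raise RegistryError(f"{duns_id}: move indices not consecutive from 1")
        return ms

    def candidates_for(self, duns_id: str, role: str) -> list[GeocodeCandidate]:
        return list(self.geocodes.get((duns_id, role), []))


def validate_years(years: Iterable[int], year_range: tuple[int, int]) -> None:
    lo, hi = year_range
    bad = [y for y in years if not lo <= y <= hi]
    if bad:
        raise RegistryError(f"years {bad} outside study window {year_range}")
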