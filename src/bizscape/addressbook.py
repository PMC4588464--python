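"""Comprehensive address file: every location a business ever occupied.

A business with no significant moves has two addresses on file — the first
reported address and the most recent address — which are expected to be
equivalent.  A business with k significant moves additionally has an origin
and a destination address per move, giving 2 + 2k location-roles but at
most k + 1 distinct physical locations.  This module reconciles those
partially redundant roles into an address book, checks the expected
equivalences (origin of move 1 vs first address, destination of move k vs
origin of move k+1, destination of the last move vs most recent address),
and assigns exactly one location-role to each business-year.

Because the same address is often recorded with character-string deviations
("10 Main St." vs "10  MAIN STREET"), comparisons run on a normalized
canonical form, not the raw strings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .model import AddressVariant, MoveRecord, RegistryBundle, RegistryError, Role

__all__ = [
    "load_suffix_table",
    "normalize_address",
    "is_significant_move",
    "build_address_book",
    "assign_yearly_locations",
    "AddressBook",
    "YearLocationMap",
]

logger = logging.getLogger(__name__)

_PUNCT = str.maketrans({c: " " for c in ".,;:#'\"()/&-"})


def load_suffix_table(path: Optional[str] = None) -> dict[str, str]:
    """Street-suffix abbreviation table (ST -> STREET, ...).

    Shipped as editable package data so regional dialects can be swapped in
    without code changes; pass ``path`` to use a custom table.
    """
    if path is not None:
        fh = open(path, newline="", encoding="utf-8")
    else:
        fh = (resources.files("bizscape.data") / "street_suffixes.csv").open(
            newline="", encoding="utf-8"
        )
    with fh:
        return {row["abbrev"].upper(): row["expansion"].upper() for row in csv.DictReader(fh)}


_DEFAULT_SUFFIXES = None


def _suffixes() -> dict[str, str]:
    global _DEFAULT_SUFFIXES
    if _DEFAULT_SUFFIXES is None:
        _DEFAULT_SUFFIXES = load_suffix_table()
    return _DEFAULT_SUFFIXES


def normalize_address(s: str, suffix_table: Optional[dict[str, str]] = None) -> str:
    """Canonicalize an address string for comparison.

    Uppercases, strips punctuation, collapses whitespace and expands street
    suffix abbreviations token-wise.  Idempotent: expansions are full words
    that are not themselves abbreviations.
    """
    if not s:
        return ""
    table = suffix_table if suffix_table is not None else _suffixes()
    tokens = s.upper().translate(_PUNCT).split()
    return " ".join(table.get(t, t) for t in tokens)


def is_significant_move(origin: AddressVariant, dest: AddressVariant) -> bool:
    """True iff BOTH the street address and the five-digit zip changed.

    This is the registry's definition of a relocation worth recording; a
    street change within the same zip (or vice versa) does not qualify.
    Streets are compared on normalized form.
    """
    if not origin.zip5 or not dest.zip5:
        raise RegistryError(
            f"{origin.duns_id}: cannot evaluate significant-move predicate without zip5"
        )
    street_changed = normalize_address(origin.address_string_primary) != normalize_address(
        dest.address_string_primary
    )
    return street_changed and origin.zip5 != dest.zip5


@dataclass
class AddressBook:
    """All location-roles per business, plus reconciliation findings."""

    variants: list[AddressVariant]
    discrepancies: list[str] = field(default_factory=list)

    def for_duns(self, duns_id: str) -> dict[str, AddressVariant]:
        return {v.role: v for v in self.variants if v.duns_id == duns_id}

    def distinct_locations(self, duns_id: str) -> set[tuple[str, str]]:
        """Distinct (normalized street, zip5) pairs on file for one business."""
        return {
            (v.normalized, v.zip5) for v in self.variants if v.duns_id == duns_id
        }


def _norm(v: AddressVariant) -> AddressVariant:
    if v.normalized is None:
        v.normalized = normalize_address(v.address_string_primary)
    return v


def build_address_book(bundle: RegistryBundle) -> AddressBook:
    """Assemble the comprehensive address file from the merged registry.

    For every business the roles ``first`` and ``most_recent`` are emitted;
    for a k-mover also ``move_origin_1..k`` and ``move_destination_1..k``.
    Expected equivalences are checked on normalized strings and logged when
    violated (the move-chain destination is preferred over a disagreeing
    stored address, since the moves file is the authoritative relocation
    record).
    """
    variants: list[AddressVariant] = []
    discrepancies: list[str] = []
    moves_by_duns: dict[str, list[MoveRecord]] = {}
    for m in bundle.moves:
        moves_by_duns.setdefault(m.duns_id, []).append(m)

    for est in bundle.establishments:
        d = est.duns_id
        first = bundle.first_addresses.get(d)
        recent = bundle.recent_addresses.get(d)
        if first is None or recent is None:
            raise RegistryError(f"{d}: missing first or most-recent address")
        first, recent = _norm(first), _norm(recent)
        moves = sorted(moves_by_duns.get(d, []), key=lambda m: m.move_index)
        for i, m in enumerate(moves, start=1):
            if m.move_index != i:
                raise RegistryError(f"{d}: move rows incomplete or out of order")

        if not moves:
            if (first.normalized, first.zip5) != (recent.normalized, recent.zip5):
                discrepancies.append(
                    f"{d}: non-mover first/most_recent addresses disagree "
                    f"({first.normalized!r} vs {recent.normalized!r})"
                )
        else:
            o1 = _norm(moves[0].origin_address)
            if (o1.normalized, o1.zip5) != (first.normalized, first.zip5):
                discrepancies.append(f"{d}: origin of move 1 differs from first address")
            for m, m_next in zip(moves, moves[1:]):
                dk = _norm(m.destination_address)
                ok = _norm(m_next.origin_address)
                if (dk.normalized, dk.zip5) != (ok.normalized, ok.zip5):
                    discrepancies.append(
                        f"{d}: destination of move {m.move_index} differs from "
                        f"origin of move {m_next.move_index}"
                    )
            dlast = _norm(moves[-1].destination_address)
            if (dlast.normalized, dlast.zip5) != (recent.normalized, recent.zip5):
                discrepancies.append(
                    f"{d}: destination of last move differs from most-recent address"
                )

        variants.append(first)
        for m in moves:
            variants.append(_norm(m.origin_address))
            variants.append(_norm(m.destination_address))
        variants.append(recent)

    for msg in discrepancies:
        logger.warning("address discrepancy: %s", msg)
    return AddressBook(variants=variants, discrepancies=discrepancies)


#: (duns_id, year) -> location-role in force that year.
YearLocationMap = dict[tuple[str, int], str]


def assign_yearly_locations(
    bundle: RegistryBundle,
    book: Optional[AddressBook] = None,
    destination_from_move_year: bool = True,
) -> YearLocationMap:
    """Assign a single location-role to each active business-year.

    The first-address role applies from the first active year up to the year
    before move 1; thereafter the destination of move k applies from the
    move year itself (snapshots are each January, so a recorded move year is
    taken as already at the destination; set
    ``destination_from_move_year=False`` to keep the origin through the move
    year instead) until the year before move k+1.  Non-movers keep the
    ``first`` role throughout, which is expected to equal ``most_recent``.
    """
    moves_by_duns: dict[str, list[MoveRecord]] = {}
    for m in bundle.moves:
        moves_by_duns.setdefault(m.duns_id, []).append(m)

    out: YearLocationMap = {}
    for est in bundle.establishments:
        moves = sorted(moves_by_duns.get(est.duns_id, []), key=lambda m: m.move_index)
        years = sorted(m.move_year for m in moves)
        if years != [m.move_year for m in moves]:
            raise RegistryError(f"{est.duns_id}: moves out of chronological order")
        offset = 0 if destination_from_move_year else 1
        for year in sorted(est.years_active):
            role = Role.FIRST
            for m in moves:
                if year >= m.move_year + offset:
                    role = Role.move_destination(m.move_index)
            out[(est.duns_id, year)] = role
    return out
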