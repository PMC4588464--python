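"""Address normalization, the significant-move predicate, and the address book."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bizscape.addressbook import (
    assign_yearly_locations,
    build_address_book,
    is_significant_move,
    load_suffix_table,
    normalize_address,
)
from bizscape.model import AddressVariant, RegistryError, Role
from bizscape.synth import SynthParams, generate_registry


def _variant(street, zip5, duns="111111111", role=Role.FIRST):
    return AddressVariant(duns_id=duns, role=role, address_string_primary=street, zip5=zip5)


class TestNormalizeAddress:
    def test_deviating_strings_canonicalize_identically(self):
        assert normalize_address("10 Main St.") == normalize_address("10  MAIN STREET")

    def test_canonical_string_unchanged(self):
        assert normalize_address("10 MAIN STREET") == "10 MAIN STREET"

    def test_empty_in_empty_out(self):
        assert normalize_address("") == ""

    def test_suffix_table_is_applied_for_every_entry(self):
        # oracle: direct token substitution from the shipped table
        table = load_suffix_table()
        assert len(table) >= 20
        for abbrev, full in table.items():
            assert normalize_address(f"12 ELM {abbrev}") == f"12 ELM {full}"

    @settings(derandomize=True, max_examples=200)
    @given(
        st.text(
            alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789 .,#'-",
            max_size=60,
        )
    )
    def test_idempotent(self, s):
        once = normalize_address(s)
        assert normalize_address(once) == once


class TestSignificantMove:
    def test_same_street_different_zip_is_not_significant(self):
        assert not is_significant_move(_variant("10 Main St", "10001"),
                                       _variant("10 MAIN STREET", "10402"))

    def test_different_street_different_zip_is_significant(self):
        assert is_significant_move(_variant("10 Main St", "10001"),
                                   _variant("77 Oak Ave", "10402"))

    def test_identical_addresses_not_significant(self):
        assert not is_significant_move(_variant("10 Main St", "10001"),
                                       _variant("10 Main St", "10001"))

    def test_different_street_same_zip_is_not_significant(self):
        assert not is_significant_move(_variant("10 Main St", "10001"),
                                       _variant("77 Oak Ave", "10001"))

    def test_missing_zip_is_an_error(self):
        with pytest.raises(RegistryError, match="zip5"):
            is_significant_move(_variant("10 Main St", ""), _variant("77 Oak Ave", "10402"))


class TestAddressBook:
    def test_non_mover_two_roles_one_location(self, toy_bundle):
        book = build_address_book(toy_bundle)
        roles = book.for_duns("222222222")
        assert set(roles) == {Role.FIRST, Role.MOST_RECENT}
        # "5 Grid7 St" vs "5 Grid7 Street." normalize to the same location
        assert len(book.distinct_locations("222222222")) == 1

    def test_one_mover_four_roles_two_locations(self, toy_bundle):
        """The origin of a single move must coincide with the first address."""
        book = build_address_book(toy_bundle)
        roles = book.for_duns("111111111")
        assert set(roles) == {
            Role.FIRST, Role.MOST_RECENT, Role.move_origin(1), Role.move_destination(1)
        }
        assert len(book.distinct_locations("111111111")) == 2
        assert not any("111111111" in d for d in book.discrepancies)

    def test_chain_discrepancy_logged_not_fatal(self, toy_bundle):
        toy_bundle.recent_addresses["111111111"].address_string_primary = "1 Other Rd"
        toy_bundle.recent_addresses["111111111"].zip5 = "10999"
        book = build_address_book(toy_bundle)
        assert any("last move" in d for d in book.discrepancies)

    def test_role_count_is_two_plus_two_k(self, default_registry):
        _, bundle, truth = default_registry
        book = build_address_book(bundle)
        k_by_duns = {}
        for m in bundle.moves:
            k_by_duns[m.duns_id] = max(k_by_duns.get(m.duns_id, 0), m.move_index)
        for est in bundle.establishments[:300]:
            k = k_by_duns.get(est.duns_id, 0)
            assert len(book.for_duns(est.duns_id)) == 2 + 2 * k
            assert len(book.distinct_locations(est.duns_id)) <= k + 1

    def test_synthetic_location_count_matches_truth(self):
        params = SynthParams(n_establishments=1000, seed=33, sic_missing_rate=0.0)
        bundle, truth = generate_registry(params)
        book = build_address_book(bundle)
        for duns, by_year in list(truth.true_location_by_year.items())[:400]:
            assert len(book.distinct_locations(duns)) == len(set(by_year.values()))


class TestYearlyLocations:
    def test_non_mover_same_role_all_years(self, toy_bundle):
        ylm = assign_yearly_locations(toy_bundle)
        roles = {ylm[("333333333", y)] for y in range(1990, 2011)}
        assert roles == {Role.FIRST}

    def test_move_year_boundary_convention(self, toy_bundle):
        """Destination in force from the move year itself (January snapshots)."""
        ylm = assign_yearly_locations(toy_bundle)
        assert ylm[("111111111", 1999)] == Role.FIRST
        assert ylm[("111111111", 2000)] == Role.move_destination(1)
        assert ylm[("111111111", 2010)] == Role.move_destination(1)

    def test_boundary_convention_switch(self, toy_bundle):
        ylm = assign_yearly_locations(toy_bundle, destination_from_move_year=False)
        assert ylm[("111111111", 2000)] == Role.FIRST
        assert ylm[("111111111", 2001)] == Role.move_destination(1)

    def test_total_on_active_years_and_piecewise_constant(self, default_registry):
        _, bundle, truth = default_registry
        ylm = assign_yearly_locations(bundle)
        move_years = {}
        for m in bundle.moves:
            move_years.setdefault(m.duns_id, set()).add(m.move_year)
        for est in bundle.establishments:
            years = sorted(est.years_active)
            prev = None
            for y in years:
                role = ylm[(est.duns_id, y)]
                if prev is not None and role != prev:
                    assert y in move_years.get(est.duns_id, set())
                prev = role

    def test_agrees_with_planted_locations(self):
        params = SynthParams(n_establishments=500, seed=44)
        bundle, truth = generate_registry(params)
        ylm = assign_yearly_locations(bundle)
        book = build_address_book(bundle)
        by_role = {(v.duns_id, v.role): v for v in book.variants}
        from bizscape.synth import GRID

        for duns, by_year in truth.true_location_by_year.items():
            for year, (x, y) in by_year.items():
                v = by_role[(duns, ylm[(duns, year)])]
                num, street = v.address_string_primary.split()[0], v.address_string_primary.split()[1]
                gx, gy = GRID.address_to_xy(int(num), int(street.removeprefix("GRID")))
                assert (gx, gy) == (x, y)
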