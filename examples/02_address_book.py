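"""Build the comprehensive address file and assign one location per year.

A business with k significant moves carries 2 + 2k location-roles (first,
most recent, and an origin/destination per move) but at most k + 1 distinct
locations; the address book reconciles them on normalized strings.
"""

from bizscape import SynthParams, generate_registry
from bizscape.addressbook import (
    assign_yearly_locations,
    build_address_book,
    normalize_address,
)

print(repr(normalize_address("10  Main St.")), "==",
      repr(normalize_address("10 MAIN STREET")))

bundle, truth = generate_registry(SynthParams(n_establishments=500, seed=7))
book = build_address_book(bundle)
year_roles = assign_yearly_locations(bundle)

mover = next(d for d, m in truth.is_mover.items() if m)
roles = book.for_duns(mover)
print(f"\nmover {mover}: {len(roles)} roles, "
      f"{len(book.distinct_locations(mover))} distinct locations")
for role in sorted(roles):
    print(f"  {role:22s} {roles[role].address_string_primary}  zip {roles[role].zip5}")
years = sorted(y for d, y in year_roles if d == mover)
print("role in force by year:")
for y in years:
    print(f"  {y}: {year_roles[(mover, y)]}")
# the destination role takes over in the move year itself (January snapshots)
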