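"""Shared fixtures: hand-built toy registries and generated synthetic ones."""

from __future__ import annotations

import json

import pytest

from bizscape import nets_io
from bizscape.model import (
    AddressVariant,
    EstablishmentRecord,
    GeocodeCandidate,
    GeocodeSource,
    MoveRecord,
    Precision,
    RegistryBundle,
    Role,
)
from bizscape.pipeline import PipelineConfig, run_pipeline
from bizscape.synth import GRID, SynthParams, generate_registry


def _variant(duns, role, street, zip5):
    return AddressVariant(
        duns_id=duns, role=role, address_string_primary=street, zip5=zip5
    )


@pytest.fixture
def toy_bundle() -> RegistryBundle:
    """Three businesses, one with a single significant move in 2000."""
    est = [
        EstablishmentRecord(
            duns_id="111111111",
            years_active=set(range(1990, 2011)),
            sic_by_year={y: "58120100" for y in range(1990, 2011)},
            company_name="RIVERSIDE GRILL",
        ),
        EstablishmentRecord(
            duns_id="222222222",
            years_active=set(range(1995, 2006)),
            sic_by_year={y: "54110000" for y in range(1995, 2006)},
            company_name="GARCIA GROCERY",
            employees_by_year={y: 5 for y in range(1995, 2006)},
            sales_by_year={y: 400000.0 for y in range(1995, 2006)},
        ),
        EstablishmentRecord(
            duns_id="333333333",
            years_active=set(range(1990, 2011)),
            sic_by_year={y: "80110000" for y in range(1990, 2011)},
            company_name="COHEN FAMILY PRACTICE",
        ),
    ]
    moves = [
        MoveRecord(
            duns_id="111111111",
            move_index=1,
            move_year=2000,
            origin_address=_variant("111111111", Role.move_origin(1), "10 Main St", "10001"),
            destination_address=_variant(
                "111111111", Role.move_destination(1), "77 Oak Ave", "10402"
            ),
        )
    ]
    first = {
        "111111111": _variant("111111111", Role.FIRST, "10 MAIN STREET", "10001"),
        "222222222": _variant("222222222", Role.FIRST, "5 Grid7 St", "10000"),
        "333333333": _variant("333333333", Role.FIRST, "900 Grid12 St", "10001"),
    }
    recent = {
        "111111111": _variant("111111111", Role.MOST_RECENT, "77 OAK AVENUE", "10402"),
        "222222222": _variant("222222222", Role.MOST_RECENT, "5 Grid7 Street.", "10000"),
        "333333333": _variant("333333333", Role.MOST_RECENT, "900 GRID12 ST", "10001"),
    }
    geocodes = {}
    for duns, role, lat, lon in [
        ("111111111", Role.MOST_RECENT, 40.75, -74.00),
        ("111111111", Role.move_origin(1), 40.70, -74.02),
        ("111111111", Role.move_destination(1), 40.75, -74.00),
        ("222222222", Role.MOST_RECENT, 40.72, -73.99),
        ("333333333", Role.MOST_RECENT, 40.73, -73.98),
    ]:
        geocodes[(duns, role)] = [
            GeocodeCandidate(duns, role, GeocodeSource.VENDOR_SUPPLIED, lat, lon,
                             Precision.BLOCK_FACE)
        ]
    return RegistryBundle(
        establishments=est, moves=moves, first_addresses=first,
        recent_addresses=recent, geocodes=geocodes,
    )


@pytest.fixture(scope="session")
def default_registry():
    """A moderately sized registry under the reference study conditions."""
    params = SynthParams(n_establishments=2000, seed=101)
    bundle, truth = generate_registry(params)
    return params, bundle, truth


ZERO_NOISE = dict(
    sic_churn_rate=0.0,
    zip_only_fraction_by_year={1990: 0.0},
    provider_failure_base=0.0,
    street_only_rate=0.0,
    out_of_region_rate=0.0,
    sic_missing_rate=0.0,
)


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory):
    """Full pipeline on a 10,000-business zero-noise registry, via files."""
    tmp = tmp_path_factory.mktemp("zero_noise")
    params = SynthParams(n_establishments=10_000, seed=202, **ZERO_NOISE)
    bundle, truth = generate_registry(params)
    written = nets_io.write_tables(bundle, tmp)
    region_path = tmp / "region.geojson"
    region_path.write_text(json.dumps(GRID.region_geojson()))
    config = PipelineConfig(
        input_paths=[str(p) for p in written.values()],
        region_geojson=str(region_path),
        out_dir=str(tmp / "out"),
        seed=202,
    )
    result = run_pipeline(config)
    return params, bundle, truth, result
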