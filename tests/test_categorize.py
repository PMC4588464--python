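"""Category assignment rules: majority SIC, matching, MET bands, review sampling."""

import numpy as np
import pandas as pd
import pytest

from bizscape.categorize import (
    Attributes,
    CategoryDefinition,
    CategorySet,
    UNCATEGORIZED,
    assign_category,
    assign_frame,
    assign_yearly,
    categorize_bundle,
    draw_review_sample,
    evaluate_review,
    load_categories,
    majority_sic,
    match_definition,
    met_band,
    resolve_overall_sic,
    review_sample_size,
)
from bizscape.model import EstablishmentRecord, RegistryError
from bizscape.pipeline import default_categories_path
from bizscape.synth import SynthParams, generate_registry


def _record(sic_by_year, **kw):
    years = kw.pop("years_active", set(sic_by_year))
    return EstablishmentRecord(
        duns_id="123456789", years_active=years, sic_by_year=sic_by_year,
        company_name=kw.pop("company_name", "ACME"), **kw,
    )


class TestMajoritySic:
    def test_eighty_percent_majority(self):
        sics = {y: "A" for y in range(1990, 1998)} | {1998: "B", 1999: "B"}
        assert majority_sic(sics) == ("A", 0.80)

    def test_threshold_inclusive_at_exactly_75(self):
        sics = {1990: "A", 1991: "A", 1992: "A", 1993: "B"}
        assert majority_sic(sics) == ("A", 0.75)

    def test_sixty_percent_is_below_threshold(self):
        sics = {y: "A" for y in range(1990, 1996)} | {y: "B" for y in range(1996, 2000)}
        assert majority_sic(sics) is None  # 6/10 = 0.60

    def test_tie_resolves_to_most_recent_of_tied(self):
        sics = {1990: "A", 1991: "B"}
        # tie at 50 %: below threshold overall -> None; but with threshold 0.5
        assert majority_sic(sics, threshold=0.5) == ("B", 0.5)

    def test_empty_is_error(self):
        with pytest.raises(RegistryError):
            majority_sic({})


class TestResolveOverallSic:
    def test_constant_sic(self):
        rec = _record({y: "58120100" for y in range(1990, 2000)})
        assert resolve_overall_sic(rec) == "58120100"

    def test_inconsistent_sic_falls_back_to_most_recent(self):
        """60 % early code A, latest year code B -> B characterizes the business."""
        sics = {y: "A" for y in range(1990, 1996)} | {y: "B" for y in range(1996, 2000)}
        sics[1999] = "B"
        rec = _record(sics)
        assert resolve_overall_sic(rec) == "B"

    def test_single_active_year(self):
        rec = _record({2005: "54110000"})
        assert resolve_overall_sic(rec) == "54110000"

    def test_never_reported_gives_none(self):
        rec = _record({}, years_active={2000})
        assert resolve_overall_sic(rec) is None


@pytest.fixture(scope="module")
def categories():
    return load_categories(str(default_categories_path()))


class TestMatching:
    def test_name_rule_catches_ymca_under_generic_sic(self, categories):
        attrs = Attributes(sic="82990000", names=("YMCA OF GRIDVILLE BRANCH 3",))
        cat, basis = assign_category(attrs, categories)
        assert cat == "multi_use_pa_venue" and basis == "name"

    def test_grocery_below_supermarket_size_is_not_a_supermarket(self, categories):
        big = next(d for d in categories if d.name == "large_supermarket")
        attrs = Attributes(sic="54110000", names=("GARCIA GROCERY",), employees=5,
                           sales=400000.0)
        assert not match_definition(attrs, big)
        assert assign_category(attrs, categories)[0] == "convenience_small_grocery"

    def test_missing_size_fields_fail_threshold_definitions(self, categories):
        big = next(d for d in categories if d.name == "large_supermarket")
        attrs = Attributes(sic="54110000", names=("SOME FOODS",))
        assert not match_definition(attrs, big)

    def test_unmatched_sic_and_name_is_uncategorized(self, categories):
        attrs = Attributes(sic="73890000", names=("KOWALSKI SERVICES",))
        assert assign_category(attrs, categories)[0] == UNCATEGORIZED

    def test_multi_match_resolved_by_priority_rank(self, categories):
        attrs = Attributes(sic="54110000", names=("EMPIRE SUPERMARKET",),
                           employees=60, sales=8e6)
        # matches both large_supermarket (rank 10) and convenience (rank 60)
        assert assign_category(attrs, categories)[0] == "large_supermarket"

    def test_duplicate_priority_ranks_rejected(self):
        with pytest.raises(RegistryError, match="unique"):
            CategorySet([
                CategoryDefinition(name="a", sic_codes=["1111"], priority_rank=1),
                CategoryDefinition(name="b", sic_codes=["2222"], priority_rank=1),
            ])


class TestYearlyMode:
    def test_constant_sic_yearly_equals_overall(self, categories):
        rec = _record({y: "58130000" for y in range(1990, 2000)})
        overall = assign_category(
            Attributes(sic=resolve_overall_sic(rec), names=(rec.company_name,)), categories
        )[0]
        for y in range(1990, 2000):
            assert assign_yearly(rec, categories, y)[0] == overall

    def test_category_switch_at_sic_change(self, categories):
        sics = {y: "54120000" for y in range(1990, 2005)}
        sics |= {y: "58130000" for y in range(2005, 2011)}
        rec = _record(sics)
        assert assign_yearly(rec, categories, 2004)[0] == "convenience_small_grocery"
        assert assign_yearly(rec, categories, 2005)[0] == "bar_drinking_place"
        # overall stays single: majority (15/21) is below 0.75 -> most recent
        assert resolve_overall_sic(rec) == "58130000"

    def test_year_outside_activity_is_error(self, categories):
        rec = _record({2000: "58120100"})
        with pytest.raises(RegistryError):
            assign_yearly(rec, categories, 1995)

    def test_vectorized_path_matches_scalar_oracle(self, categories, default_registry):
        """assign_frame must equal row-wise assign_category (independent path)."""
        _, bundle, _ = default_registry
        rows = []
        for est in bundle.establishments[:400]:
            for year in sorted(est.years_active):
                rows.append({
                    "sic": est.sic_by_year.get(year),
                    "name_norm": f"{est.company_name} {est.trade_name or ''}".upper().strip(),
                    "sales": est.sales_by_year.get(year),
                    "employees": est.employees_by_year.get(year),
                })
        df = pd.DataFrame(rows)
        fast = assign_frame(df, categories)
        for i, row in df.iterrows():
            attrs = Attributes(
                sic=row["sic"] if pd.notna(row["sic"]) else None,
                names=(row["name_norm"],),
                sales=row["sales"] if pd.notna(row["sales"]) else None,
                employees=row["employees"] if pd.notna(row["employees"]) else None,
            )
            assert assign_category(attrs, categories)[0] == fast[i]


class TestMutualExclusivity:
    def test_accounting_identity(self, categories, default_registry):
        """categorized + uncategorized must equal the total business count."""
        _, bundle, _ = default_registry
        assignment = categorize_bundle(bundle.establishments, categories)
        counts = pd.Series(list(assignment.overall.values())).value_counts()
        assert int(counts.sum()) == len(bundle.establishments)
        assert (
            int(counts.drop(UNCATEGORIZED, errors="ignore").sum())
            + int(counts.get(UNCATEGORIZED, 0))
            == len(bundle.establishments)
        )

    def test_zero_churn_recovers_planted_categories(self, categories):
        params = SynthParams(
            n_establishments=1500, seed=55, sic_churn_rate=0.0, sic_missing_rate=0.0
        )
        bundle, truth = generate_registry(params)
        assignment = categorize_bundle(bundle.establishments, categories)
        for duns, cat in truth.true_category.items():
            assert assignment.overall[duns] == cat


class TestMetBand:
    @pytest.mark.parametrize("met,band", [
        (1.6, "light_moderate"),   # lower bound of the band
        (5.9, "light_moderate"),   # upper bound of the band
        (6.0, "vigorous"),         # vigorous threshold
        (9.8, "vigorous"),
    ])
    def test_printed_boundaries(self, met, band):
        assert met_band(met) == band

    def test_sedentary_rating_is_error(self):
        with pytest.raises(RegistryError):
            met_band(1.5)


class TestReviewSampling:
    @pytest.mark.parametrize("n,expected", [
        (40, 40),    # under 50: review all
        (100, 20),   # 50-250: 20 % sample
        (300, 50),   # over 250: flat 50
        (0, 0),
        (49, 49),
        (50, 10),
        (250, 50),
        (251, 50),
    ])
    def test_strata(self, n, expected):
        assert review_sample_size(n) == expected

    def test_negative_is_error(self):
        with pytest.raises(RegistryError):
            review_sample_size(-1)

    def test_piecewise_monotone_then_constant(self):
        # nondecreasing within each stratum (it drops at the 50 boundary,
        # where full review gives way to the 20 % sample)
        low = [review_sample_size(n) for n in range(0, 50)]
        mid = [review_sample_size(n) for n in range(50, 251)]
        assert low == sorted(low)
        assert mid == sorted(mid)
        assert all(review_sample_size(n) == 50 for n in range(251, 400, 7))

    def test_sample_deterministic_and_threshold_inclusive(self):
        pool = [
            EstablishmentRecord(
                duns_id=f"{100000000 + i}", years_active={2010},
                sic_by_year={2010: "79970100"}, company_name=f"CLUB {i}",
            )
            for i in range(60)
        ]
        ws1 = draw_review_sample(pool, seed=5)
        ws2 = draw_review_sample(pool, seed=5)
        assert list(ws1["duns_id"]) == list(ws2["duns_id"])
        assert len(ws1) == review_sample_size(60) == 12
        marked = ws1.copy()
        marked["relevant"] = ["1"] * 6 + ["0"] * 6
        assert evaluate_review(marked)  # exactly 50 % -> include
        marked["relevant"] = ["1"] * 5 + ["0"] * 7
        assert not evaluate_review(marked)  # below 50 % -> exclude
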