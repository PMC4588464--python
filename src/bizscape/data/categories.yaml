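# Researcher-defined health-relevant business categories.
#
# This file is a TEMPLATE with illustrative, NON-CANONICAL definitions:
# the SIC rosters, name patterns and size thresholds here are plausible
# defaults meant to exercise every rule type (SIC prefix, name include,
# size threshold, MET band), not a vetted instrument.  Projects should
# replace them with definitions validated for their own research question.
#
# Matching semantics (see bizscape.categorize):
#   - sic_codes shorter than 8 digits are prefixes of the 8-digit SIC.
#   - a definition fires on SIC match OR name_include match, minus
#     name_exclude, subject to any size thresholds (missing size data
#     fails a threshold-bearing definition).
#   - mutual exclusivity: lowest priority_rank among matches wins, so
#     size-restricted definitions rank above the residual categories they
#     carve out of (large supermarket above convenience/small grocery,
#     fast food and pizza above the restaurant residual).
#   - met_value bands physical-activity venues: 1.6-5.9 light/moderate,
#     >= 6 vigorous.
categories:
  - name: large_supermarket
    priority_rank: 10
    sic_codes: ["5411"]
    min_employees: 25
    min_sales: 2000000
  - name: warehouse_discount_food
    priority_rank: 11
    sic_codes: ["5311", "5331"]
    min_employees: 100
  - name: fast_food_restaurant
    priority_rank: 30
    sic_codes: ["581203"]
    name_include_patterns: ["MCDONALD", "BURGER KING", "WENDY", "TACO BELL", "KFC", "SUBWAY SANDWICH"]
  - name: pizza_restaurant
    priority_rank: 31
    sic_codes: ["581206"]
    name_include_patterns: ["PIZZA", "PIZZERIA"]
  - name: other_restaurant
    priority_rank: 40
    sic_codes: ["5812"]
  - name: bar_drinking_place
    priority_rank: 50
    sic_codes: ["5813"]
  - name: liquor_store
    priority_rank: 51
    sic_codes: ["5921"]
  - name: fish_market
    priority_rank: 52
    sic_codes: ["542102"]
  - name: meat_market
    priority_rank: 53
    sic_codes: ["542101"]
  - name: fruit_vegetable_market
    priority_rank: 54
    sic_codes: ["5431"]
  - name: natural_food_market
    priority_rank: 55
    sic_codes: ["5499"]
  - name: bakery_candy_store
    priority_rank: 56
    sic_codes: ["5461", "5441"]
  - name: convenience_small_grocery
    priority_rank: 60
    sic_codes: ["5411", "5412"]
  - name: multi_use_pa_venue
    priority_rank: 70
    sic_codes: ["799101"]
    name_include_patterns: ["YMCA", "YWCA", "JEWISH COMMUNITY CENTER", "JCC"]
  - name: vigorous_pa_venue
    priority_rank: 71
    sic_codes: ["799102", "799701"]
    met_value: 7.0
  - name: light_moderate_pa_venue
    priority_rank: 72
    sic_codes: ["799103", "7992", "7933"]
    met_value: 3.5
  - name: urgent_care_hospital
    priority_rank: 80
    sic_codes: ["8062"]
  - name: health_practitioner_office
    priority_rank: 81
    sic_codes: ["8011", "8041", "8049"]
  - name: residential_health_facility
    priority_rank: 82
    sic_codes: ["8051"]
  - name: pharmacy
    priority_rank: 83
    sic_codes: ["5912"]
  - name: mental_health_care
    priority_rank: 84
    sic_codes: ["8063", "8093"]
  - name: dental_care
    priority_rank: 85
    sic_codes: ["8021"]
  - name: bank
    priority_rank: 86
    sic_codes: ["6021", "6022"]
  - name: credit_union
    priority_rank: 87
    sic_codes: ["6061", "6062"]
  - name: other_destination
    priority_rank: 90
    sic_codes: ["5944", "7832", "8231", "5331", "5311"]
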