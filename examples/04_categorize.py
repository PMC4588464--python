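"""Category assignment: the 75 % majority rule, name rules, and size rules."""

from bizscape import Attributes, EstablishmentRecord, assign_category, load_categories
from bizscape.categorize import majority_sic, met_band, resolve_overall_sic
from bizscape.pipeline import default_categories_path

categories = load_categories(str(default_categories_path()))

# 75 % majority rule (threshold inclusive), else most-recent SIC
sics = {y: "58120100" for y in range(1990, 1996)} | {y: "58130000" for y in range(1996, 2000)}
rec = EstablishmentRecord(duns_id="123456789", years_active=set(range(1990, 2000)),
                          sic_by_year=sics, company_name="ROSSI GRILL")
print("majority:", majority_sic(sics), "-> overall SIC:", resolve_overall_sic(rec))
# 6/10 years is below 75 %, so the most recently reported code (5813) wins

# a name rule catches venues whose SIC is uninformative
ymca = Attributes(sic="82990000", names=("YMCA OF GRIDVILLE",))
print("YMCA under a generic SIC ->", assign_category(ymca, categories))

# size thresholds split supermarkets from small grocers sharing SIC 5411
big = Attributes(sic="54110000", names=("EMPIRE SUPERMARKET",), employees=60, sales=8e6)
small = Attributes(sic="54110000", names=("GARCIA GROCERY",), employees=5, sales=4e5)
print("60 employees, $8M ->", assign_category(big, categories)[0])
print(" 5 employees, $400k ->", assign_category(small, categories)[0])

# MET banding of physical-activity venues
for met in (1.6, 5.9, 6.0):
    print(f"MET {met} -> {met_band(met)}")
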