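"""The pool variable: five shared categories packed into one integer key.

Shows the encode/decode bijection over the 288 bins and the location-
stratified income terciles that supply the fifth dimension.
"""

from rpgen import assign_income_categories, decode_pool, encode_pool
from rpgen.enums import FamilyCategory, HouseType, IncomeCategory, Region, Setting

idx = encode_pool(Setting.RURAL, Region.SOUTH, HouseType.MULTI_STRUCTURE,
                  FamilyCategory.MULTI_ADULT_NO_CHILDREN, IncomeCategory.MIDDLE)
print(f"(rural, South, multi-structure, 2+ adults/0 children, middle) -> pool {idx}")
print(f"pool {idx} decodes back to: {decode_pool(idx)}")

# Terciles are computed within each (setting, region) location, so the same
# dollar income can land in different categories in different local markets.
incomes = [10_000, 20_000, 30_000, 100_000, 200_000, 30_000]
locations = ["rural-South"] * 3 + ["urban-Northeast"] * 3
cats = assign_income_categories(incomes, locations)
for inc, loc, cat in zip(incomes, locations, cats):
    print(f"  income {inc:>7,} in {loc:<15} -> category {cat} (1=high, 3=low)")
# Note the two 30,000 households: top of the rural-South ranking (category 1)
# but bottom of the urban-Northeast one (category 3).
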