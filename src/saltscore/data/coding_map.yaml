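# Ordinal coding of salt-related behavior items.
# Frequency boundaries are closed on the left, open on the right:
# a value equal to an upper bound falls in the NEXT category.
version: 1
items:
  taste_preference:
    kind: labels
    labels: [very mild, mild, common, strong, very strong]
  soy_sauce:
    kind: labels
    labels: [unused, rarely, sometimes, almost always, always]
  noodle_soup:
    kind: labels
    labels: [almost none, 1/3 of a bowl, half of a bowl, 2/3 of a bowl, almost all]
  spices:              # mustard, chili pepper, ginger (grouped)
    kind: frequency
    unit: per_week
    upper_bounds: [1, 3, 5]
  wasabi:
    kind: frequency
    unit: per_week
    upper_bounds: [0.4, 1, 3]
  processed_meat:
    kind: frequency
    unit: per_week
    upper_bounds: [1, 3, 5]
  salted_fish:
    kind: frequency
    unit: per_week
    upper_bounds: [1, 3, 5]
  noodles:
    kind: frequency
    unit: per_week
    upper_bounds: [1, 3, 5]
  pickled_vegetables:
    kind: frequency
    unit: per_week
    upper_bounds: [3, 7, 14]
  instant_food:
    kind: frequency
    unit: per_month
    upper_bounds: [1, 3, 13]   # <1/mo; 1-3/mo; 1-2/wk; >=3/wk
  eating_out:
    kind: frequency
    unit: per_month
    upper_bounds: [1, 3, 13]
  miso_soup_bowls:
    kind: frequency
    unit: per_day
    upper_bounds: [0.5, 1, 2]
quartile_groups: [vegetables, fruits, milk_products]
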