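# Canonical data dictionary for person-level cohort tables.
# User files with different headers are mapped onto these names via the
# `column_map` argument of read_cohort / RunConfig.
schema_version: "1.0"
columns:
  - pid
  - site
  - age
  - sex
  - height
  - weight
  - walk_time_10m
  - education
  - marital
  - assets
  - smoking
  - alcohol
  - phys_activity
  - impairments
  - dementia
  - depression
  - diabetes
  - stroke
enums:
  sex: [female, male]
  education: [none, incomplete_primary, primary, secondary, tertiary]
  marital: [never, married_cohab, widowed, divorced_sep]
  smoking: [never, ever]
  alcohol: [none_or_heavy, moderate]
  phys_activity: [low, high]
  impairments: [none, one_two, three_plus]
bounds:
  age: {min: 65}
  height: {min: 1.0, max: 2.2, exclusive: true}
  weight: {min: 25.0, max: 250.0, exclusive: true, nullable: true}
  walk_time_10m: {min: 0.0, exclusive: true, nullable: true}
  assets: {min: 0, max: 7}
binary_flags: [dementia, depression, diabetes, stroke]
# Default site set (the nine 10/66 catchment areas) and the ethnicity used to
# resolve the additive constant of the limb-muscle prediction equation.
sites:
  cuba: {ethnicity: white_hispanic}
  dominican_republic: {ethnicity: white_hispanic}
  peru_urban: {ethnicity: white_hispanic}
  peru_rural: {ethnicity: white_hispanic}
  mexico_urban: {ethnicity: white_hispanic}
  mexico_rural: {ethnicity: white_hispanic}
  china_urban: {ethnicity: asian}
  china_rural: {ethnicity: asian}
  puerto_rico: {ethnicity: white_hispanic}
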