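columns:
  person_id: PID
  household_id: HHID
  age: AGEP
  gender: SEX
  race: RAC1P
  ethnicity: HISP
  state_fips: ST
  puma_id: PUMA
  puma_density: DENSITY
  household_income: HINCP
  n_adults: NRA
  n_children: NRC
  raw_house_type: BLD
  weight: PWGTP
recodes:
  gender:
    '1': M
    '2': F
  race:
    '1': W
    '2': B
    '3': N
    '4': A
    '5': P
    '6': O
  ethnicity:
    '1': N
    '2': M
    '3': O
house_type_recodes:
  '01': standalone
  '02': standalone
  '03': multi_structure
  '04': multi_structure
  '05': other
  '06': other
  '07': group_quarters
  08: group_quarters
  09: group_quarters
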