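columns:
  energy_id: DOEID
  has_washer: WASHER
  n_cooktops: NUMCOOK
  fuel: FUEL
  metro_class: METRO
  region: REGION
  household_income: MONEYPY
  raw_house_type: TYPEHUQ
  n_adults: NRA
  n_children: NRC
  weight: NWEIGHT
recodes:
  fuel:
    '1': electricity
    '2': natural_gas
    '3': fuel_oil
    '4': propane
    '5': wood
    '6': other
  metro_class:
    METRO: metropolitan
    MICRO: micropolitan
    NONE: neither
  region:
    '1': Northeast
    '2': Midwest
    '3': South
    '4': West
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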