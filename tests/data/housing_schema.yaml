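columns:
  housing_id: CONTROL
  rooms: ROOMS
  bedrooms: BEDRMS
  bathrooms: BATHS
  area_sqft: UNITSF
  raw_house_type: BLD
  metro_class: METRO
  region: REGION
  household_income: HINCP
  tenure: TEN
  occupancy: VAC
  n_ceiling_fans: CEILFAN
  n_windows: WINDOWS
  has_pool: POOL
  has_vehicle: VEH
  high_ceilings: HICEIL
  n_adults: NRA
  n_children: NRC
  weight: WEIGHT
recodes:
  metro_class:
    '1': metropolitan
    '2': micropolitan
    '3': neither
  region:
    '1': Northeast
    '2': Midwest
    '3': South
    '4': West
  tenure:
    '1': own
    '2': rent
    '3': occupy_without_rent
  occupancy:
    '0': occupied
    '1': vacant
  has_pool:
    '1': 'true'
    '2': 'false'
  has_vehicle:
    '1': 'true'
    '2': 'false'
  high_ceilings:
    '1': 'true'
    '2': 'false'
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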