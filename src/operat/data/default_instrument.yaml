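# Default OPERAT instrument: 16 items across four domains.
#
# Domain structure, EAG weights and the per-domain raw maxima (9, 10, 13, 14)
# follow the published instrument.  The split of each domain's maximum into
# per-item integer multipliers is RECONSTRUCTED (the published per-item weight
# table is not publicly deposited): multipliers are plausible integers in 1-4
# constrained so that each domain's sum equals the published raw maximum.
# Every multiplier can be overridden by editing this file or supplying an
# alternative config.
instrument_name: OPERAT
domains:
  - domain_id: natural_elements
    name: Natural Elements
    eag_weight: 1
  - domain_id: incivilities_nuisance
    name: Incivilities and Nuisance
    eag_weight: 1
  - domain_id: navigation_mobility
    name: Navigation and Mobility
    eag_weight: 2
  - domain_id: territorial_functioning
    name: Territorial Functioning
    eag_weight: 1
items:
  # --- Natural Elements (raw max 9 = 3 + 3 + 3) ---
  - item_id: public_grass_verges
    label: Public grass or verges present
    domain_id: natural_elements
    value_kind: binary
    desirable_direction: presence_good
    multiplier: 3
    loading: 0.87
  - item_id: sounds_of_nature
    label: Sounds of nature audible
    domain_id: natural_elements
    value_kind: binary
    desirable_direction: presence_good
    multiplier: 3
    loading: 0.56
  - item_id: private_trees
    label: Proportion of properties with trees in the garden
    domain_id: natural_elements
    value_kind: proportion
    desirable_direction: presence_good
    multiplier: 3
    loading: -0.49
  # --- Incivilities and Nuisance (raw max 10 = 3 + 4 + 3) ---
  - item_id: traffic_industrial_noise
    label: Traffic, industrial or other loud noise
    domain_id: incivilities_nuisance
    value_kind: ordinal
    ordinal_levels: 4
    desirable_direction: presence_bad
    multiplier: 3
    loading: 0.80
  - item_id: litter_dog_fouling
    label: Litter, dog fouling or broken glass
    domain_id: incivilities_nuisance
    value_kind: ordinal
    ordinal_levels: 4
    desirable_direction: presence_bad
    multiplier: 4
    loading: 0.57
  - item_id: cars_passing
    label: Volume of cars passing
    domain_id: incivilities_nuisance
    value_kind: ordinal
    ordinal_levels: 4
    desirable_direction: presence_bad
    multiplier: 3
    loading: 0.80
  # --- Navigation and Mobility (raw max 13 = 2 + 3 + 3 + 3 + 2) ---
  - item_id: legible_road_signs
    label: Clear and easy to read road name signs
    domain_id: navigation_mobility
    value_kind: binary
    desirable_direction: presence_good
    multiplier: 2
    loading: 0.58
  - item_id: street_alley_lighting
    label: Lights on the streets and in alleyways
    domain_id: navigation_mobility
    value_kind: binary
    desirable_direction: presence_good
    multiplier: 3
    loading: 0.58
  - item_id: pavement_maintenance
    label: Pavement maintenance and width
    domain_id: navigation_mobility
    value_kind: ordinal
    ordinal_levels: 4
    desirable_direction: presence_good
    multiplier: 3
    loading: 0.73
  - item_id: road_maintenance
    label: Road maintenance
    domain_id: navigation_mobility
    value_kind: ordinal
    ordinal_levels: 4
    desirable_direction: presence_good
    multiplier: 3
    loading: 0.79
  - item_id: pavement_road_gradient
    label: Pavement or road gradient
    domain_id: navigation_mobility
    value_kind: ordinal
    ordinal_levels: 4
    desirable_direction: presence_bad
    multiplier: 2
    loading: 0.48
  # --- Territorial Functioning (raw max 14 = 2 + 2 + 4 + 4 + 2) ---
  - item_id: external_beautification
    label: Proportion of properties with external beautification
    domain_id: territorial_functioning
    value_kind: proportion
    desirable_direction: presence_good
    multiplier: 2
    loading: 0.49
  - item_id: nature_of_parking
    label: Nature of parking
    domain_id: territorial_functioning
    value_kind: binary
    desirable_direction: presence_bad
    multiplier: 2
    loading: -0.42
  - item_id: garden_maintenance
    label: Proportion of properties with well maintained gardens
    domain_id: territorial_functioning
    value_kind: proportion
    desirable_direction: presence_good
    multiplier: 4
    loading: 0.89
  - item_id: property_maintenance
    label: Proportion of properties well maintained
    domain_id: territorial_functioning
    value_kind: proportion
    desirable_direction: presence_good
    multiplier: 4
    loading: 0.63
  - item_id: industrial_outlook
    label: Industrial, agricultural-industrial or commercial outlook
    domain_id: territorial_functioning
    value_kind: binary
    desirable_direction: presence_bad
    multiplier: 2
    loading: -0.79
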