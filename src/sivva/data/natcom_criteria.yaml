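# Default criteria registry for the natural-community (NATCOM) variant.
# Criterion ids and short descriptions paraphrase the published module
# inventory; weights default to 1.0 and are meant to be adjusted per study.
variant: natcom
modules:
  - id: ES
    name: Ecosystem Status
    criteria:
      - {id: es_area_50yr, set_id: area_decline, weight: 1.0,
         description: Decline in community area over the last 50 years}
      - {id: es_area_1750, set_id: area_decline, weight: 1.0,
         description: Decline in community area since 1750 (pre-industrial baseline)}
      - {id: es_area_any50, set_id: area_decline, weight: 1.0,
         description: Decline in area over any 50-year window including present and future}
      - {id: es_func_50yr, set_id: function_decline, weight: 1.0,
         description: Decline in ecosystem function over the last 50 years}
      - {id: es_func_1750, set_id: function_decline, weight: 1.0,
         description: Decline in ecosystem function since 1750}
      - {id: es_func_any50, set_id: function_decline, weight: 1.0,
         description: Decline in function over any 50-year window including present and future}
      - {id: es_rarity_extent, set_id: rarity, weight: 1.0,
         description: Rarity measured as geographic extent of the community type}
      - {id: es_rarity_aoo, set_id: rarity, weight: 1.0,
         description: Rarity measured as area of occupancy (patchiness-aware)}
      - {id: es_rarity_total, set_id: rarity, weight: 1.0,
         description: Rarity measured as total area of the community type}
  - id: VU
    name: Vulnerability
    criteria:
      - {id: vu_slr_loss, weight: 1.0,
         description: Projected area loss due to sea-level rise}
      - {id: vu_landuse_loss, weight: 1.0,
         description: Projected area loss due to land-use change}
      - {id: vu_fragmentation, weight: 1.0,
         description: Fragmentation of habitat patches}
      - {id: vu_disturbance, weight: 1.0,
         description: Alteration of the natural disturbance regime}
      - {id: vu_hydrology, weight: 1.0,
         description: Altered hydrology}
      - {id: vu_range_limits, weight: 1.0,
         description: Inherent or imposed limits on range shifts}
      - {id: vu_abiotic_degradation, weight: 1.0,
         description: Degradation of the abiotic environment}
      - {id: vu_biotic_processes, weight: 1.0,
         description: Altered biotic processes and interactions}
      - {id: vu_other, weight: 1.0,
         description: Other factors affecting community viability}
  - id: CV
    name: Conservation Value
    criteria:
      - {id: cv_endemism, weight: 1.0,
         description: Endemism of the community type}
      - {id: cv_key_species, weight: 1.0,
         description: Number of highly interactive or rare species supported}
      - {id: cv_ecosystem_services, weight: 1.0,
         description: Ecosystem services provided}
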