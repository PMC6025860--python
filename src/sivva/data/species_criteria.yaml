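# Default criteria registry for the species variant.
# Ids and short descriptions paraphrase the published module inventory
# (exposure + sensitivity, adaptive capacity, value, information);
# weights default to 1.0 and are meant to be adjusted per study.
variant: species
modules:
  - id: V
    name: Vulnerability (Exposure + Sensitivity)
    criteria:
      - {id: v_slr_habitat_loss, weight: 1.0,
         description: Habitat loss to sea-level rise}
      - {id: v_erosion, weight: 1.0,
         description: Habitat loss to coastal erosion}
      - {id: v_landuse_change, weight: 1.0,
         description: Habitat loss to land-use change}
      - {id: v_fragmentation, weight: 1.0,
         description: Habitat fragmentation}
      - {id: v_temp_sensitivity, weight: 1.0,
         description: Sensitivity to temperature change}
      - {id: v_precip_sensitivity, weight: 1.0,
         description: Sensitivity to precipitation change}
      - {id: v_salinity_sensitivity, weight: 1.0,
         description: Sensitivity to salinity change}
      - {id: v_disturbance, weight: 1.0,
         description: Altered disturbance regime in occupied habitat}
      - {id: v_hydrology, weight: 1.0,
         description: Altered hydrology in occupied habitat}
      - {id: v_range_limits, weight: 1.0,
         description: Limits on range shifts (inherent or imposed)}
      - {id: v_abiotic_degradation, weight: 1.0,
         description: Degradation of abiotic habitat features}
      - {id: v_biotic_interactions, weight: 1.0,
         description: Loss or alteration of key biotic interactions}
  - id: AC
    name: Adaptive Capacity
    criteria:
      - {id: ac_mobility, weight: 1.0,
         description: Ability to shift distribution in response to threats}
      - {id: ac_genetic_diversity, weight: 1.0,
         description: Genetic diversity supporting adaptation}
      - {id: ac_colonization, weight: 1.0,
         description: Ability to colonize newly available habitat}
      - {id: ac_plasticity, weight: 1.0,
         description: Behavioural or physiological plasticity}
      - {id: ac_reproduction, weight: 1.0,
         description: Reproductive rate and recovery from declines}
      - {id: ac_niche_breadth, weight: 1.0,
         description: Breadth of diet and habitat requirements}
  - id: CV
    name: Conservation Value
    criteria:
      - {id: cv_endemism, weight: 1.0,
         description: Endemism within the assessment region}
      - {id: cv_evolutionary_distinctiveness, weight: 1.0,
         description: Evolutionary distinctiveness}
      - {id: cv_ecological_interactions, weight: 1.0,
         description: Importance as a highly interactive species}
      - {id: cv_ecosystem_services, weight: 1.0,
         description: Contribution to ecosystem services}
      - {id: cv_recovery_potential, weight: 1.0,
         description: Potential for recovery given intervention}
  - id: IA
    name: Information Availability
    criteria:
      - {id: ia_life_history, weight: 1.0,
         description: Published literature on basic life history}
      - {id: ia_threat_responses, weight: 1.0,
         description: Documented responses to threats}
      - {id: ia_distribution, weight: 1.0,
         description: Quality of distribution and abundance data}
      - {id: ia_monitoring, weight: 1.0,
         description: Existence of ongoing monitoring programs}
      - {id: ia_demography, weight: 1.0,
         description: Demographic and population-trend data}
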