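# Universal tests on the merged toy multi-tissue model: every tissue's
# biomass maintenance runs on a glucose medium, storage functions work,
# and nothing is produced from an empty medium.
- name: biomass_liver_on_glucose
  medium:
    "EX_glc[bl]": [-10, 0]
    "EX_o2[bl]": [-100, 0]
    "EX_co2[bl]": [-100, 100]
    "EX_hco3[bl]": [-100, 100]
    "EX_h2o[bl]": [-100, 100]
  target: {"BIOMASS[h]": 1}
  expectation: feasible_positive

- name: biomass_muscle_on_glucose
  medium:
    "EX_glc[bl]": [-10, 0]
    "EX_o2[bl]": [-100, 0]
    "EX_co2[bl]": [-100, 100]
    "EX_hco3[bl]": [-100, 100]
    "EX_h2o[bl]": [-100, 100]
  target: {"BIOMASS[m]": 1}
  expectation: feasible_positive

- name: biomass_fat_on_glucose
  medium:
    "EX_glc[bl]": [-10, 0]
    "EX_o2[bl]": [-100, 0]
    "EX_co2[bl]": [-100, 100]
    "EX_hco3[bl]": [-100, 100]
    "EX_h2o[bl]": [-100, 100]
  target: {"BIOMASS[a]": 1}
  expectation: feasible_positive

- name: glycogen_storage_on_glucose
  medium:
    "EX_glc[bl]": [-10, 0]
    "EX_o2[bl]": [-100, 0]
    "EX_co2[bl]": [-100, 100]
    "EX_hco3[bl]": [-100, 100]
    "EX_h2o[bl]": [-100, 100]
  target: {"GLYSTOR[h]": 1, "GLYSTOR[m]": 1}
  expectation: feasible_positive

- name: triacylglycerol_storage_on_glucose
  medium:
    "EX_glc[bl]": [-10, 0]
    "EX_o2[bl]": [-100, 0]
    "EX_co2[bl]": [-100, 100]
    "EX_hco3[bl]": [-100, 100]
    "EX_h2o[bl]": [-100, 100]
  target: {"TAGSTOR[a]": 1}
  expectation: feasible_positive

- name: no_biomass_on_empty_medium
  medium:
    "EX_h2o[bl]": [-100, 100]
  target: {"BIOMASS[h]": 1}
  expectation: zero
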