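# Functional validation of the toy liver (tagged tissue model, pre-merge).
# Media override exchange bounds; all other exchanges are closed first.
- name: gluconeogenesis_from_lactate
  medium:
    "EX_lac[h]": [-10, 0]
    "EX_glc[h]": [0, 100]
    "EX_o2[h]": [-100, 0]
    "EX_co2[h]": [-100, 100]
    "EX_h[h]": [-100, 100]
    "EX_h2o[h]": [-100, 100]
  target: {"EX_glc[h]": 1}
  expectation: feasible_positive

- name: gluconeogenesis_from_alanine
  medium:
    "EX_ala[h]": [-10, 0]
    "EX_glc[h]": [0, 100]
    "EX_o2[h]": [-100, 0]
    "EX_co2[h]": [-100, 100]
    "EX_urea[h]": [0, 100]
    "EX_h[h]": [-100, 100]
    "EX_h2o[h]": [-100, 100]
  target: {"EX_glc[h]": 1}
  expectation: feasible_positive

- name: urea_production_from_alanine
  medium:
    "EX_ala[h]": [-10, 0]
    "EX_urea[h]": [0, 100]
    "EX_o2[h]": [-100, 0]
    "EX_co2[h]": [-100, 100]
    "EX_glc[h]": [0, 100]
    "EX_h[h]": [-100, 100]
    "EX_h2o[h]": [-100, 100]
  target: {"EX_urea[h]": 1}
  expectation: feasible_positive

- name: glycogen_storage_from_glucose
  medium:
    "EX_glc[h]": [-10, 0]
    "EX_o2[h]": [-100, 0]
    "EX_co2[h]": [-100, 100]
    "EX_h[h]": [-100, 100]
    "EX_h2o[h]": [-100, 100]
  target: glgc[h_c]
  expectation: feasible_positive

- name: no_glucose_without_carbon_source
  medium:
    "EX_o2[h]": [-100, 0]
    "EX_co2[h]": [-100, 100]
    "EX_h[h]": [-100, 100]
    "EX_h2o[h]": [-100, 100]
  target: {"EX_glc[h]": 1}
  expectation: zero
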