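# Functional validation of the toy muscle (tagged tissue model, pre-merge).
- name: atp_from_glucose
  medium:
    "EX_glc[m]": [-1, 0]
    "EX_lac[m]": [0, 100]
    "EX_h[m]": [-100, 100]
    "EX_h2o[m]": [-100, 100]
  target: {"ATPM[m]": 1}
  expectation: feasible_positive

- name: alanine_export_from_glucose_and_ammonia
  medium:
    "EX_glc[m]": [-10, 0]
    "EX_nh4[m]": [-10, 0]
    "EX_lac[m]": [0, 100]
    "EX_ala[m]": [0, 100]
    "EX_h[m]": [-100, 100]
    "EX_h2o[m]": [-100, 100]
  target: {"EX_ala[m]": 1}
  expectation: feasible_positive

- name: glycogen_storage_from_glucose
  medium:
    "EX_glc[m]": [-10, 0]
    "EX_lac[m]": [0, 100]
    "EX_h[m]": [-100, 100]
    "EX_h2o[m]": [-100, 100]
  target: glgc[m_c]
  expectation: feasible_positive

- name: no_atp_without_carbon_source
  medium:
    "EX_h[m]": [-100, 100]
    "EX_h2o[m]": [-100, 100]
  target: {"ATPM[m]": 1}
  expectation: zero
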