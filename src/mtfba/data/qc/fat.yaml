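# Functional validation of the toy fat tissue (tagged tissue model, pre-merge).
- name: triacylglycerol_storage_from_glucose
  medium:
    "EX_glc[a]": [-10, 0]
    "EX_o2[a]": [-100, 0]
    "EX_co2[a]": [0, 100]
    "EX_h[a]": [-100, 100]
    "EX_h2o[a]": [-100, 100]
  target: {"TAGSTOR[a]": 1}
  expectation: feasible_positive

- name: lactate_from_glucose
  medium:
    "EX_glc[a]": [-10, 0]
    "EX_lac[a]": [0, 100]
    "EX_h[a]": [-100, 100]
    "EX_h2o[a]": [-100, 100]
  target: {"EX_lac[a]": 1}
  expectation: feasible_positive

- name: glycerol_from_glucose
  medium:
    "EX_glc[a]": [-10, 0]
    "EX_o2[a]": [-100, 0]
    "EX_co2[a]": [0, 100]
    "EX_glycerol[a]": [0, 100]
    "EX_h[a]": [-100, 100]
    "EX_h2o[a]": [-100, 100]
  target: {"EX_glycerol[a]": 1}
  expectation: feasible_positive

- name: no_lipid_without_carbon_source
  medium:
    "EX_o2[a]": [-100, 0]
    "EX_co2[a]": [0, 100]
    "EX_h2o[a]": [-100, 100]
  target: {"TAGSTOR[a]": 1}
  expectation: zero
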