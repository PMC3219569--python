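name: absorptive
close_exchanges: true
deactivate_tissues: []
bounds:
  EX_glc[bl]:
  - -10.0
  - 0.0
  EX_o2[bl]:
  - -1000.0
  - 0.0
  EX_co2[bl]:
  - -1000.0
  - 1000.0
  EX_hco3[bl]:
  - -1000.0
  - 1000.0
  EX_h2o[bl]:
  - -1000.0
  - 1000.0
  EX_urea[bl]:
  - 0.0
  - 1000.0
  EX_glycerol[bl]:
  - 0.0
  - 1000.0
  T_glc[a]:
  - 0.0
  - 6.5
  ATPM[h]:
  - 16.0
  - 1000.0
  ATPM[m]:
  - 2.0
  - 1000.0
objectives:
- coefficients:
    TAGSTOR[a]: 1.0
  direction: max
  fraction: 1.0
- coefficients:
    GLYSTOR[h]: 1.0
    GLYSTOR[m]: 1.0
  direction: max
  fraction: 1.0
carbon_sources:
- EX_glc[bl]
sinks:
  triacylglycerol:
  - TAGSTOR[a]
  glycogen:
  - GLYSTOR[h]
  - GLYSTOR[m]
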