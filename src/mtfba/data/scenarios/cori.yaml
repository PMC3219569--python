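name: cori
close_exchanges: true
deactivate_tissues:
- a
bounds:
  EX_lac[bl]:
  - -6.0
  - -6.0
  EX_glc[bl]:
  - 0.0
  - 1000.0
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
  ATPM[h]:
  - 30.0
  - 1000.0
  ATPM[m]:
  - 0.0
  - 1000.0
objectives:
- coefficients:
    EX_glc[bl]: 1.0
  direction: max
  fraction: 1.0
carbon_sources:
- EX_lac[bl]
sinks:
  glucose:
  - EX_glc[bl]
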