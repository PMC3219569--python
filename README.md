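# mtfba — multi-tissue constraint-based metabolic modeling

`mtfba` merges tissue-specific genome-scale metabolic models into one
multi-tissue model connected through a blood compartment, simulates
integrated metabolic states with linear programming, quality-controls the
models, and extracts expression-driven context-specific models.

Main capabilities:

* **model_core** — domain types (metabolites with Hill-notation formulas
  and charges, reactions with bounds and boolean gene–protein–reaction
  rules), elemental/charge balance checking, and readers/writers for SBML
  (Level 3 + fbc on write; legacy Level 2 kinetic-law bounds are read
  transparently via COBRApy) and a tab-delimited table format.
* **integrate** — tissue tagging (`glc[c]` → `glc[h_c]`), merging through
  a new blood compartment `bl` (tissue exchanges removed, transporters
  bridge to blood, whitelisted blood exchanges created), a bicarbonate
  buffer reaction for proton balancing, and biomass rescaling from
  mmol/h/gDW to mmol/h/body units.
* **simulate** — FBA (`max c'v` s.t. `S v = 0`, bounds), FVA with
  flux spans, zero/fixed/variable classification with internal-loop
  exclusion (closed-exchange FVA), lexicographic multi-objective
  optimization, and carbon-fate accounting over named sinks.
* **qc** — closed-system futile-cycle (energy) tests, dead-end metabolite
  detection, and YAML-configured media-based function tests.
* **context** — consensus presence calls (present iff present in every
  sample of a tissue/group), GIMME context extraction with a required
  metabolic functionality (RMF) guarantee, FVA-based differential
  reaction-activity comparison, and seeded call-stability analysis.
* **fixtures** — a deterministic, elementally and charge balanced
  three-tissue toy system (gluconeogenic liver, glycolytic muscle,
  lipogenic fat) with proton-explicit lactate transport and closed-form
  optima, used as the regression baseline everywhere.

## CLI

```sh
# emit the deterministic toy fixtures (models, scenarios, manifest)
mtfba toy --kind multitissue --seed 7 --out toys/

# merge tissue models through a blood compartment (+ bicarbonate buffer)
mtfba merge --tissue h=hep.xml --tissue m=myo.xml --tissue a=adipo.xml \
      --whitelist blood_mets.txt --out multi.xml

# run a scenario: lexicographic FBA, FVA report, carbon split
mtfba simulate --model toys/multi_tissue.tsv --scenario toys/cori.yaml \
      --report report.tsv

# quality control: balance, dead ends, futile cycles, function tests
mtfba qc --model toys/multi_tissue.tsv \
      --suite src/mtfba/data/qc/universal.yaml \
      --drains 'ATPM[h],ATPM[m],ATPM[a]' --report qc.tsv

# context-specific extraction + differential activity between two groups
mtfba gimme --model toys/multi_tissue.tsv --calls calls.tsv \
      --scenario toys/starvation.yaml --fraction 0.9 --out ctx/
```

Scenario YAML files mirror `mtfba.simulate.Scenario` (bound overrides,
ordered objective stages with fix fractions, carbon sources, named
sinks); defaults for the Cori, Alanine, absorptive, and starvation
states ship under `src/mtfba/data/scenarios/`.

## Conventions

* Metabolite ids are `base[compartment]`; tissue tags prefix the
  subcellular compartment (`glc[h_c]`), blood species are `base[bl]`.
* Negative exchange flux = uptake into the blood from the extra-system.
* Unspecified bounds default to ±1000; irreversible reactions have a
  zero lower bound.
* Genes missing from a state map count as present (absence of evidence
  is not evidence of absence); marginal calls break presence consensus.
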