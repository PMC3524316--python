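format_version: 1
name: synthetic-proteomics-core
store_uri: store.sqlite
mappings:
- class: Experiment Type
  column: experiment_type
- class: Organism
  column: organism
- class: Cell line
  column: cell_line
- class: Bait gene
  column: bait_gene
- class: Bait Type
  column: bait_type
- class: Run Group
  column: run_group
- class: Sample Type
  column: sample_type
- class: Perturbation
  column: perturbation
- class: Subcellular Fraction
  column: subcellular_fraction
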