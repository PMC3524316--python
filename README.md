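# provdash

Provenance-aware querying of proteomics experiment metadata.

Proteomics cores accumulate experiments across many projects and workflows —
affinity-purification mass spectrometry (AP-MS) pull-downs, shotgun
expression runs — and the contextual metadata that makes the data reusable
(organism, cell line, bait gene, perturbation, ...) usually ends up scattered
across lab notebooks and per-project silos. `provdash` is a small library and
CLI for researchers and data managers who want to query that metadata across
projects through a controlled vocabulary rather than raw SQL.

The design couples three pieces:

* **A provenance ontology** in the W3C PROV-O style: every facet class
  (e.g. *Bait Type*, *Cell line*) extends one of the three PROV-O core
  classes `prov:Activity`, `prov:Entity`, `prov:Agent`; each class carries
  its admissible instance values, and instances can be linked pairwise with
  PROV relations (`hadRole`, `used`, `wasAttributedTo`). Instance-level
  links encode experimental design facts, e.g. the bait gene *EPHB2* is
  only ever assayed in the *HCT116* cell line.
* **A class-to-column mapping** that declares which store column answers
  for which ontology class, so ontology-level query patterns translate to
  parameterized SQL over a relational metadata store.
* **A boolean query engine** over patterns of equality conditions joined by
  binary AND/OR connectives. Mixed chains have *no operator precedence*:
  a pattern `c1 op1 c2 op2 c3 ...` is evaluated as the left-to-right fold
  `((c1 op1 c2) op2 c3) ...`, and the translated SQL prints that
  parenthesization explicitly so the interpretation is always auditable.

On top of the engine sit two interactive aids modelled on faceted search:

* **Smart filtering** — given a partial pattern, which values of each facet
  can still lead to a non-empty result? Candidates are the values that
  co-occur with the current (conjunctively interpreted) selection in the
  store, intersected with the values the ontology's instance-level
  relations allow.
* **Constraint propagation** — when the user edits one condition, other
  selected conditions that became ontology-incompatible are updated: if the
  relations admit exactly one value, it is substituted (switching the bait
  gene from *CTNNB1* to *EPHB2* auto-updates the cell line to *HCT116*);
  if several values remain possible, the slot is cleared rather than
  guessed.

Results are grouped per project, each experiment carrying a deterministic
link-out URL stub toward the upstream LIMS. A saved-query catalog persists
named, dated patterns in YAML for later re-execution and sharing.

Because real LIMS contents are institutional, the package ships a seeded
synthetic store generator (`provdash.fixtures`) that emulates the AP-MS /
expression corpus with the packaged vocabularies and honors the ontology's
instance-level constraints; it drives the whole test suite.

## Worked example

```
$ provdash generate --seed 42 --n-experiments 1000 --n-projects 7
Generated 1000 experiments across 7 projects (seed 42) -> provdash_store

$ provdash query --explain "Organism='Homo sapiens' AND \"Cell Line\"='Embryonic stem' OR Perturbation='Dose = 0'"
translated: SELECT experiment_id, project_id FROM experiments WHERE ((organism = ? COLLATE NOCASE AND cell_line = ? COLLATE NOCASE) OR perturbation = ? COLLATE NOCASE)
parameters: ['Homo Sapiens', 'Embryonic stem', 'Dose = 0']
266 matching experiment(s) in 7 project(s)

[P1] DNMT1 interactome — 44 experiment(s)
  E00019  https://labkey.example/project/P1/experiment/E00019
  ...

$ provdash suggest "\"Bait gene\"='EPHB2'" --for "Cell line"
Cell line: HCT116
```

The first command materializes the synthetic store (TSV dumps plus a SQLite
database). The query shows the explicit left-fold parenthesization and the
bound parameters — note `'Homo sapiens'` was canonicalized to the declared
spelling `'Homo Sapiens'`; matching is case-insensitive throughout. The
total (266 of 1000 experiments here) is the number of records whose
per-condition truth values fold to true; matches are then grouped under
their project tabs. The `suggest` call demonstrates smart filtering: with
the bait gene fixed to EPHB2, the ontology relation and the store agree
that HCT116 is the only cell line that can still yield results.

`provdash saved save/list/run/delete` manage the catalog, and every executed
query is appended to a session log together with its translated SQL form.

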