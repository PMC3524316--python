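# Methods

## The data model

An ontology here is a rooted forest of classes over the three PROV-O cores
(`Activity`, `Entity`, `Agent`), plus flat instance vocabularies per class
and typed instance-level relations drawn from the controlled set
`{hadRole, used, wasAttributedTo}`. The model is deliberately closed-world:
every reference (parent, owning class, relation endpoint) must resolve
inside the file, multiple inheritance is rejected at load time, and every
class must reach exactly one PROV-O root through an acyclic parent chain.
No OWL reasoning is performed; the hierarchy is exactly what is declared.

Serialization is Turtle RDF with one fixed convention — classes as
`rdfs:Class` with `rdfs:subClassOf` chains, instances via `rdf:type` with
`rdfs:label` carrying the display form, relations as direct triples with
PROV predicates, alternate class names as `skos:altLabel`. A single dialect
keeps `load ∘ save` an exact identity, which is property-tested over
randomly generated valid ontologies (labels include quotes, backslashes and
non-ASCII characters to exercise literal escaping).

Names and labels compare case-insensitively after whitespace normalization,
with the first-declared spelling as canonical. This is a deliberate design
choice: experiment metadata entered by hand mixes spellings such as
`Homo Sapiens` / `Homo sapiens`, and a query environment that treats those
as different organisms silently loses records. The packaged miniature
ontology keeps the label `Epilast stem cell` as-is rather than "Epiblast",
so the fixture vocabulary remains traceable to the deployed system it
emulates. `Bait gene` additionally carries the alias `Bait Gene Symbol`,
under which the same facet is commonly written.

## Query semantics

Patterns are ordered equality conditions joined by binary AND/OR. Only `=`
is supported — every benchmark pattern is an equality, and the operator
field on `Condition` is the extension point if ranges or negation are ever
needed. Mixed chains are evaluated as a strict left-to-right fold with no
precedence, because a query builder that appends conditions one at a time
composes exactly that way; the translated SQL reproduces the fold's
parenthesization literally, so a user can always audit which reading was
applied. Values are passed to SQLite as bound parameters with
`COLLATE NOCASE` comparison; they are never interpolated into SQL text.

The in-memory evaluator and the SQL route are redundant by design: tests
and the acceptance script require `translate ∘ execute ≡ evaluate ≡ naive
fold oracle` on the benchmark patterns and hundreds of random ones.

## Smart filtering and propagation

Smart filtering answers: *which value of facet C can the user still pick?*
For each class the engine takes the experiments satisfying the conjunction
of the already-selected conditions — excluding any condition on C itself,
the standard faceted-search self-exclusion, so the currently selected value
always remains offered — and collects the values of C occurring there.
That data-driven set is then intersected with the ontology-admissible set:
for each selected value that has relation assertions toward C, only the
related values survive; values and classes without assertions are
unconstrained. The conjunctive interpretation is used regardless of the
connectives already chosen, because under OR no candidate could ever empty
the result and the filter would be vacuous; this is a documented decision,
not something the interface semantics force.

Propagation applies the relations when a condition is *edited*: any other
selected condition whose value became ontology-incompatible is replaced if
the relation admits exactly one value of its class, and cleared to a
pending slot otherwise. The engine never guesses among multiple compatible
values. Conditions with no relation to the edited instance are untouched.

Both features return values in case-folded lexicographic order and result
groups in project-id order, so outputs are reproducible byte for byte.

## The synthetic corpus

`GeneratorSpec` defaults model a mid-sized proteomics core: 7 projects,
1000 experiments, 3 acquisition files per experiment, seed 42, and the
packaged facet vocabularies (2 experiment types, 3 organisms, 5 cell lines,
5 bait genes, 5 bait types, 3 run groups, 4 perturbations, 1 sample type,
1 subcellular fraction). `Not Applicable` is an ordinary perturbation
value, not a null — filtering on it must work like any other equality.
Experiments are assigned to projects by a seeded uniform multinomial draw,
so project sizes are realistically uneven; attribute values are drawn
uniformly per facet.

The ontology's instance-level relations double as hard generation
constraints, interpreted directionally: a record whose subject value fires
a relation has its object facet forced into the related set (singleton sets
deterministically, larger sets by a seeded choice), iterated to a fixpoint
so chained rules are honored. Conflicting demands on the same facet raise a
generation error naming both sources. A deterministic post-pass then
patches records (only where the displaced value occurs at least twice) so
every vocabulary value appears in at least one record — without this,
smart-filter completeness checks could pass vacuously.

What the generator does *not* emulate: missing or free-text metadata,
multi-valued facets, attribute drift across projects, and any correlation
structure beyond the declared constraints. Passing tests therefore show the
engine's logic is correct under clean single-valued metadata, not that it
is robust to dirty real-world LIMS exports.

Generation is a pure function of (spec, ontology): the acceptance script
and tests assert bit-identical TSV exports for repeated runs at one seed.

## Persistence

The store exports as TSV dumps (canonical, human-diffable; class names as
column headers) plus a SQLite database with slugged column names for the
SQL route. The saved-query catalog is one YAML document; every save writes
a temp file and renames it over the old catalog, so a crash can lose at
most the in-flight save. Re-saving under an existing name preserves
`created_at` and strictly increases `updated_at` (timestamps are UTC at
one-second resolution; a same-second re-save bumps by one second). Sharing
is file-level — copy or merge catalog files — with no user accounts;
queries are re-parsed and re-executed on every run, never cached.

## Problem sizes and numerical choices

The default corpus is 1000 records; oracle-equivalence checks use the 7
benchmark patterns plus 200 random patterns of length 1–8; smart-filter
checks run exhaustively over all benchmark prefixes × 9 facets × every
store value; round-trip properties use 100 random ontologies and 500
random patterns; the large-store smoke run uses 50 000 records with full
oracle verification on a 5000-record subsample. These sizes keep the whole
suite under a minute on one CPU while leaving every check exhaustive at
its scale. There are no tolerances anywhere: every comparison is exact set
or byte equality, which the deterministic design makes possible.

## Known limitations

One active data source per session; federation across stores is not
implemented. Link-outs are URL stubs — no live LIMS connectivity or
authentication. No numeric ranges, negation or free-text search. No
inter-ontology mappings (GO, PRO, OBI, EFO); the ontology is only as
expressive as the classes and relations declared in it.
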