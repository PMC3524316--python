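"""Seeded synthetic experiment-metadata store.

Emulates the metadata corpus of a proteomics core running two workflows —
affinity-purification mass spectrometry (AP-MS) and shotgun expression
proteomics — as a set of projects, each holding experiments annotated with
one controlled-vocabulary value per facet class (organism, cell line, bait
gene, perturbation, ...). Generation is a pure function of the generator
spec and the ontology: the same seed always yields a bit-identical store.

Instance-level relations in the ontology act as hard design constraints on
the generated records: a bait gene that is ontology-linked to specific cell
lines only ever co-occurs with those cell lines (e.g. every EPHB2 pull-down
is performed in HCT116). After the main draw, a deterministic patching pass
guarantees that every vocabulary value occurs in at least one record, so the
store exercises every drop-down value the query layer can offer.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from random import Random

from .ontology import Ontology, RelationAssertion, _key, _slug

#: Facet vocabularies of the synthetic corpus (one value per facet per record).
DEFAULT_VOCABULARIES: dict[str, list[str]] = {
    "Experiment Type": ["AP-MS", "Protein Expression"],
    "Organism": ["Homo Sapiens", "Mus musculus", "Drosophila melanogaster"],
    "Cell line": ["Embryonic stem", "Epilast stem cell", "HCT116", "RKO", "T-cells (Boom)"],
    "Bait gene": ["DNMT1", "CTNNB1", "EPHB2", "POU5F1", "APC"],
    "Bait Type": ["Endogenous", "Exogenous", "KnockIn", "Tagged", "Untagged"],
    "Run Group": ["Bait", "Treated", "No Vector Control"],
    "Sample Type": ["Cell culture"],
    "Perturbation": ["Dose = 0", "WNT3A", "10 ng", "Not Applicable"],
    "Subcellular Fraction": ["Cytosol"],
}

#: The seven benchmark query patterns, in the package's pattern DSL.
#: Class spellings deliberately vary in case ("Cell Line", "Homo sapiens")
#: and use the "Bait Gene Symbol" alias: resolution is case-insensitive.
TABLE_QUERIES: dict[str, str] = {
    "Q1": "Organism='Homo Sapiens'",
    "Q2": "Organism='Homo Sapiens' OR \"Cell Line\"='Embryonic stem'",
    "Q3": (
        "Organism='Homo sapiens' AND \"Cell Line\"='Embryonic stem' "
        "OR Perturbation='Dose = 0' OR \"Subcellular Fraction\"='Cytosol'"
    ),
    "Q4": (
        "\"Bait Gene Symbol\"='DNMT1' AND \"Experiment Type\"='AP-MS' "
        "OR Perturbation='WNT3A' AND \"Run Group\"='Bait' OR \"Cell Line\"='RKO'"
    ),
    "Q5": (
        "\"Experiment Type\"='Protein Expression' OR \"Cell Line\"='T-cells (Boom)' "
        "AND Organism='Drosophila melanogaster' AND Perturbation='10 ng' "
        "OR \"Run Group\"='Treated' AND \"Sample Type\"='Cell culture'"
    ),
    "Q6": (
        "\"Bait Gene\"='POU5F1' OR \"Cell Line\"='Embryonic stem' "
        "AND \"Experiment Type\"='AP-MS' OR Organism='Mus musculus' "
        "AND Perturbation='Not Applicable' OR \"Sample Type\"='Cell culture' "
        "OR \"Bait Type\"='Endogenous'"
    ),
    "Q7": (
        "\"Experiment Type\"='Protein Expression' OR \"Cell Line\"='T-cells (Boom)' "
        "AND Organism='Drosophila melanogaster' AND \"Bait Type\"='Tagged' "
        "AND \"Sample Type\"='Cell culture' OR Perturbation='Not Applicable' "
        "AND \"Bait Gene\"='APC' AND \"Run Group\"='No Vector Control'"
    ),
}

_PROJECT_NAMES = [
    "DNMT1 interactome",
    "Wnt signaling AP-MS",
    "Colorectal cancer expression",
    "Stem cell pluripotency",
    "T-cell activation profiling",
    "Chromatin complexes",
    "Membrane receptor pull-downs",
    "Cytosolic fraction survey",
    "Mouse model expression",
    "Drosophila development",
]


class GenerationError(Exception):
    """The generator spec is invalid or its constraints are unsatisfiable."""


def column_for_class(class_name: str) -> str:
    """Store column identifier for a facet class, e.g. 'Bait gene' -> 'bait_gene'."""
    return _slug(class_name).lower()


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic corpus.

    Defaults model a mid-sized proteomics core: 7 projects, 1000 experiments,
    3 acquisition files per experiment, seed 42.
    """

    n_projects: int = 7
    n_experiments: int = 1000
    seed: int = 42
    vocabularies: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VOCABULARIES.items()}
    )
    hard_constraints: tuple[RelationAssertion, ...] | None = None
    files_per_experiment: int = 3

    def __post_init__(self):
        if self.n_projects < 1:
            raise GenerationError("n_projects must be positive")
        if self.n_experiments < 1:
            raise GenerationError("n_experiments must be positive")
        if self.files_per_experiment < 1:
            raise GenerationError("files_per_experiment must be positive")


@dataclass
class Experiment:
    experiment_id: str
    project_id: str
    attributes: dict[str, str]
    files: list[str]


@dataclass
class ExperimentStore:
    projects: list[tuple[str, str]]
    experiments: list[Experiment]

    @property
    def project_names(self) -> dict[str, str]:
        return dict(self.projects)

    def attribute_classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.experiments:
            for k in e.attributes:
                seen.setdefault(k, None)
        return sorted(seen)

    def values_of(self, class_name: str) -> set[str]:
        k = _key(class_name)
        out = set()
        for e in self.experiments:
            for c, v in e.attributes.items():
                if _key(c) == k:
                    out.add(v)
        return out


def _constraint_map(
    spec: GeneratorSpec, o: Ontology
) -> dict[tuple[str, str], dict[str, set[str]]]:
    """(subject class key, subject label key) -> {object class: allowed labels}."""
    assertions = (
        spec.hard_constraints if spec.hard_constraints is not None else o.relations
    )
    cmap: dict[tuple[str, str], dict[str, set[str]]] = {}
    for r in assertions:
        if not o.has_instance(r.subject.owning_class, r.subject.label):
            raise GenerationError(
                f"hard constraint subject {r.subject.label!r} is not a declared instance"
            )
        if not o.has_instance(r.object.owning_class, r.object.label):
            raise GenerationError(
                f"hard constraint object {r.object.label!r} is not a declared instance"
            )
        skey = (_key(r.subject.owning_class), _key(r.subject.label))
        obj_class = o.resolve_class(r.object.owning_class).name
        cmap.setdefault(skey, {}).setdefault(obj_class, set()).add(r.object.label)
    return cmap


def _enforce(
    attributes: dict[str, str],
    cmap: dict[tuple[str, str], dict[str, set[str]]],
    rng: Random,
) -> None:
    """Rewrite constrained attribute values in place until all constraints hold.

    Iterates to a fixpoint so that a rewrite which itself fires a constraint
    (a chained rule) is also honored. Raises when two fired constraints
    demand disjoint value sets for the same class.
    """
    for _ in range(len(attributes) + 1):
        demands: dict[str, tuple[set[str], list[str]]] = {}
        for cls, val in attributes.items():
            rules = cmap.get((_key(cls), _key(val)))
            if not rules:
                continue
            for obj_class, allowed in rules.items():
                if obj_class not in attributes:
                    continue
                prev = demands.get(obj_class)
                inter = set(allowed) if prev is None else prev[0] & set(allowed)
                srcs = ([] if prev is None else prev[1]) + [f"{cls}={val}"]
                if not inter:
                    raise GenerationError(
                        f"conflicting constraints on {obj_class!r} from " + " and ".join(srcs)
                    )
                demands[obj_class] = (inter, srcs)
        changed = False
        for obj_class, (allowed, _) in sorted(demands.items()):
            if attributes[obj_class] not in allowed:
                attributes[obj_class] = rng.choice(sorted(allowed))
                changed = True
        if not changed:
            return
    raise GenerationError("constraint enforcement did not converge (cyclic rules)")


def generate_store(spec: GeneratorSpec, o: Ontology) -> ExperimentStore:
    """Draw a synthetic store; deterministic in (spec, ontology)."""
    for cls, labels in spec.vocabularies.items():
        if not o.has_class(cls):
            raise GenerationError(f"vocabulary class {cls!r} not in ontology")
        for lbl in labels:
            if not o.has_instance(cls, lbl):
                raise GenerationError(
                    f"vocabulary value {lbl!r} is not a declared instance of {cls!r}"
                )
    cmap = _constraint_map(spec, o)
    rng = Random(spec.seed)
    width = max(5, len(str(spec.n_experiments)))

    projects = [
        (f"P{i + 1}", _PROJECT_NAMES[i % len(_PROJECT_NAMES)])
        for i in range(spec.n_projects)
    ]
    classes = sorted(spec.vocabularies)
    experiments: list[Experiment] = []
    for j in range(spec.n_experiments):
        eid = f"E{j + 1:0{width}d}"
        pid = projects[rng.randrange(spec.n_projects)][0]
        attrs = {cls: rng.choice(spec.vocabularies[cls]) for cls in classes}
        _enforce(attrs, cmap, rng)
        files = [f"{eid}_run{k + 1}.raw" for k in range(spec.files_per_experiment)]
        experiments.append(Experiment(eid, pid, attrs, files))

    _patch_coverage(experiments, spec, cmap)
    return ExperimentStore(projects=projects, experiments=experiments)


def _patch_coverage(
    experiments: list[Experiment],
    spec: GeneratorSpec,
    cmap: dict[tuple[str, str], dict[str, set[str]]],
) -> None:
    """Deterministically rewrite records so every vocabulary value occurs >= once.

    Only records whose current value for the class occurs at least twice are
    eligible, so patching one value in never patches another out. Values that
    cannot be placed without breaking a hard constraint are left uncovered
    (possible only in very small stores).
    """
    counts: dict[tuple[str, str], int] = {}
    for e in experiments:
        for cls, val in e.attributes.items():
            counts[(cls, val)] = counts.get((cls, val), 0) + 1
    for cls in sorted(spec.vocabularies):
        for val in spec.vocabularies[cls]:
            if counts.get((cls, val), 0) > 0:
                continue
            for e in experiments:
                cur = e.attributes[cls]
                if counts.get((cls, cur), 0) < 2:
                    continue
                trial = dict(e.attributes)
                trial[cls] = val
                try:
                    _enforce(trial, cmap, Random(0))
                except GenerationError:
                    continue
                # only accept records where the substitution stands on its own
                if trial != {**e.attributes, cls: val}:
                    continue
                counts[(cls, cur)] -= 1
                counts[(cls, val)] = counts.get((cls, val), 0) + 1
                e.attributes[cls] = val
                break


# -- persistence ------------------------------------------------------------

_EXPERIMENTS_TSV = "experiments.tsv"
_PROJECTS_TSV = "projects.tsv"
_FILES_TSV = "files.tsv"
_SQLITE = "store.sqlite"


def sqlite_path(store_dir: str | Path) -> Path:
    return Path(store_dir) / _SQLITE


def export_store(s: ExperimentStore, path: str | Path) -> None:
    """Write the store under directory ``path``: a SQLite database for the
    query translator plus tab-delimited dumps (the canonical text form).
    """
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    classes = s.attribute_classes()
    columns = [column_for_class(c) for c in classes]

    with open(d / _PROJECTS_TSV, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["project_id", "name"])
        for pid, name in s.projects:
            w.writerow([pid, name])
    with open(d / _EXPERIMENTS_TSV, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["experiment_id", "project_id", *classes])
        for e in s.experiments:
            w.writerow([e.experiment_id, e.project_id, *(e.attributes[c] for c in classes)])
    with open(d / _FILES_TSV, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["experiment_id", "file_name"])
        for e in s.experiments:
            for f in e.files:
                w.writerow([e.experiment_id, f])

    db = d / _SQLITE
    if db.exists():
        db.unlink()
    con = sqlite3.connect(db)
    try:
        con.execute("CREATE TABLE projects (project_id TEXT PRIMARY KEY, name TEXT)")
        col_ddl = ", ".join(f"{c} TEXT" for c in columns)
        con.execute(
            f"CREATE TABLE experiments (experiment_id TEXT PRIMARY KEY, project_id TEXT, {col_ddl})"
        )
        con.execute("CREATE TABLE files (experiment_id TEXT, file_name TEXT)")
        con.executemany("INSERT INTO projects VALUES (?, ?)", s.projects)
        ph = ", ".join("?" * (2 + len(columns)))
        con.executemany(
            f"INSERT INTO experiments VALUES ({ph})",
            [
                (e.experiment_id, e.project_id, *(e.attributes[c] for c in classes))
                for e in s.experiments
            ],
        )
        con.executemany(
            "INSERT INTO files VALUES (?, ?)",
            [(e.experiment_id, f) for e in s.experiments for f in e.files],
        )
        con.commit()
    finally:
        con.close()


def import_store(path: str | Path) -> ExperimentStore:
    """Rebuild a store from a directory written by :func:`export_store`.

    Reads the tab-delimited dumps (the text form is authoritative).
    """
    d = Path(path)
    with open(d / _PROJECTS_TSV, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    projects = [(pid, name) for pid, name in rows[1:]]
    with open(d / _FILES_TSV, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    files: dict[str, list[str]] = {}
    for eid, fname in rows[1:]:
        files.setdefault(eid, []).append(fname)
    with open(d / _EXPERIMENTS_TSV, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header = rows[0]
    classes = header[2:]
    experiments = [
        Experiment(
            experiment_id=r[0],
            project_id=r[1],
            attributes=dict(zip(classes, r[2:])),
            files=files.get(r[0], []),
        )
        for r in rows[1:]
    ]
    return ExperimentStore(projects=projects, experiments=experiments)
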