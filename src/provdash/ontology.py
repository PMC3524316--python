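"""Provenance ontology model: PROV-O core roots, domain classes, instances, relations.

The ontology follows the W3C PROV-O pattern: every domain class (e.g. "Bait
Type", "Cell line") transitively extends exactly one of the three PROV-O core
classes — ``prov:Activity``, ``prov:Entity``, ``prov:Agent``. Classes carry
flat controlled vocabularies as instances (e.g. the bait types "Endogenous",
"Exogenous", "KnockIn", "Tagged", "Untagged"), and instances may be linked
pairwise by the PROV relations ``hadRole``, ``used`` and ``wasAttributedTo``.
Instance-level relations encode experimental design constraints — e.g. the
bait gene EPHB2 is only ever assayed in the HCT116 cell line — and drive the
smart-filtering and constraint-propagation features of the query layer.

Ontologies are serialized as Turtle RDF: classes as ``rdfs:Class`` with
``rdfs:subClassOf`` chains rooted at the PROV core classes, instances via
``rdf:type``, and relations as direct triples with PROV predicates.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import SKOS

PROV = Namespace("http://www.w3.org/ns/prov#")
SYSPRO = Namespace("http://example.org/syspro#")

#: The three PROV-O core classes every domain class must extend.
PROV_CORE = ("Activity", "Entity", "Agent")

#: Controlled vocabulary of instance-level relation predicates.
PREDICATES = ("hadRole", "used", "wasAttributedTo")


class OntologyError(Exception):
    """Base class for ontology errors."""


class OntologyFormatError(OntologyError):
    """The file could not be parsed as Turtle RDF."""


class OntologyValidationError(OntologyError):
    """The parsed content violates a structural invariant."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("ontology validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems))


class UnknownClassError(OntologyError, LookupError):
    """A class name does not resolve; carries nearest lexical matches."""

    def __init__(self, name: str, candidates: Iterable[str]):
        self.name = name
        self.suggestions = difflib.get_close_matches(name, list(candidates), n=3, cutoff=0.4)
        hint = f" (did you mean: {', '.join(self.suggestions)}?)" if self.suggestions else ""
        super().__init__(f"unknown ontology class {name!r}{hint}")


class UnknownInstanceError(OntologyError, LookupError):
    pass


class VocabularyError(OntologyError):
    """A relation predicate is outside the controlled vocabulary."""

    def __init__(self, predicate: str):
        super().__init__(
            f"predicate {predicate!r} is not in the controlled vocabulary {set(PREDICATES)}"
        )


def _norm_ws(name: str) -> str:
    return " ".join(name.split())


def _key(name: str) -> str:
    return _norm_ws(name).casefold()


@dataclass(frozen=True)
class OntologyClass:
    """A named class. ``parent`` is None only for the three PROV-O roots."""

    name: str
    parent: str | None
    prov_core: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "name", _norm_ws(self.name))
        if self.parent is not None:
            object.__setattr__(self, "parent", _norm_ws(self.parent))
        object.__setattr__(self, "aliases", tuple(_norm_ws(a) for a in self.aliases))


@dataclass(frozen=True)
class InstanceValue:
    """A controlled-vocabulary value, e.g. label='HCT116' of class 'Cell line'."""

    label: str
    owning_class: str

    def __post_init__(self):
        object.__setattr__(self, "label", _norm_ws(self.label))
        object.__setattr__(self, "owning_class", _norm_ws(self.owning_class))


@dataclass(frozen=True)
class RelationAssertion:
    """A typed instance-level link, e.g. (EPHB2, hadRole, HCT116)."""

    subject: InstanceValue
    predicate: str
    object: InstanceValue


class Ontology:
    """Validated closed-world ontology: classes, instances, relations.

    Lookup is case-insensitive (after whitespace normalization) for both class
    names and instance labels; the canonical spelling is the declared one.
    Class aliases (``skos:altLabel``) resolve like names.
    """

    def __init__(
        self,
        classes: Iterable[OntologyClass],
        instances: Iterable[InstanceValue] = (),
        relations: Iterable[RelationAssertion] = (),
    ):
        self.classes: tuple[OntologyClass, ...] = tuple(classes)
        self.instances: tuple[InstanceValue, ...] = tuple(instances)
        self.relations: tuple[RelationAssertion, ...] = tuple(relations)
        self._by_key: dict[str, OntologyClass] = {}
        self._inst_by_key: dict[tuple[str, str], InstanceValue] = {}
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        problems: list[str] = []

        for c in self.classes:
            k = _key(c.name)
            if k in self._by_key:
                problems.append(f"duplicate class name {c.name!r}")
                continue
            self._by_key[k] = c
        alias_owner: dict[str, str] = {}
        for c in self.classes:
            for a in c.aliases:
                ak = _key(a)
                if ak in self._by_key and self._by_key[ak].name != c.name:
                    problems.append(f"alias {a!r} of {c.name!r} collides with class {self._by_key[ak].name!r}")
                elif ak in alias_owner and alias_owner[ak] != c.name:
                    problems.append(f"alias {a!r} claimed by both {alias_owner[ak]!r} and {c.name!r}")
                else:
                    alias_owner[ak] = c.name
        self._alias_to_class = {a: self._by_key[_key(n)] for a, n in alias_owner.items() if _key(n) in self._by_key}

        # every class must reach exactly one PROV-O root through an acyclic parent chain
        root_keys = {_key(r) for r in PROV_CORE}
        for c in self.classes:
            k = _key(c.name)
            if k in root_keys:
                if c.parent is not None:
                    problems.append(f"PROV-O root {c.name!r} must not have a parent")
                continue
            seen = {k}
            cur = c
            while True:
                if cur.parent is None:
                    problems.append(f"class {c.name!r} does not reach a PROV-O root")
                    break
                pk = _key(cur.parent)
                if pk in root_keys:
                    if pk not in self._by_key:
                        problems.append(
                            f"class {c.name!r} reaches root {cur.parent!r} which is not declared"
                        )
                    break
                if pk not in self._by_key:
                    problems.append(f"class {c.name!r}: undeclared parent {cur.parent!r}")
                    break
                if pk in seen:
                    problems.append(f"cycle in class hierarchy involving {c.name!r}")
                    break
                seen.add(pk)
                cur = self._by_key[pk]

        for c in self.classes:
            if _key(c.prov_core) not in root_keys:
                problems.append(f"class {c.name!r}: prov_core {c.prov_core!r} is not a PROV-O root")

        for i in self.instances:
            ck = _key(i.owning_class)
            if ck not in self._by_key:
                problems.append(f"instance {i.label!r}: undeclared owning class {i.owning_class!r}")
                continue
            ik = (ck, _key(i.label))
            if ik in self._inst_by_key:
                problems.append(f"duplicate instance {i.label!r} of class {i.owning_class!r}")
            else:
                self._inst_by_key[ik] = i

        for r in self.relations:
            if r.predicate not in PREDICATES:
                problems.append(f"relation predicate {r.predicate!r} outside controlled vocabulary")
            for end, which in ((r.subject, "subject"), (r.object, "object")):
                if (_key(end.owning_class), _key(end.label)) not in self._inst_by_key:
                    problems.append(
                        f"relation {which} {end.label!r} ({end.owning_class!r}) is not a declared instance"
                    )

        if problems:
            raise OntologyValidationError(problems)

    # -- lookup -------------------------------------------------------------

    def resolve_class(self, name: str) -> OntologyClass:
        """Resolve a class by name or alias, case-insensitively."""
        k = _key(name)
        c = self._by_key.get(k) or self._alias_to_class.get(k)
        if c is None:
            raise UnknownClassError(name, [cl.name for cl in self.classes])
        return c

    def has_class(self, name: str) -> bool:
        k = _key(name)
        return k in self._by_key or k in self._alias_to_class

    def resolve_instance(self, class_name: str, label: str) -> InstanceValue:
        c = self.resolve_class(class_name)
        inst = self._inst_by_key.get((_key(c.name), _key(label)))
        if inst is None:
            raise UnknownInstanceError(
                f"no instance {label!r} declared for class {c.name!r}"
            )
        return inst

    def has_instance(self, class_name: str, label: str) -> bool:
        try:
            self.resolve_instance(class_name, label)
            return True
        except (UnknownClassError, UnknownInstanceError):
            return False

    def descendants(self, class_name: str) -> set[str]:
        """Names of ``class_name`` and all transitive subclasses."""
        root = self.resolve_class(class_name)
        children: dict[str, list[OntologyClass]] = {}
        for c in self.classes:
            if c.parent is not None:
                children.setdefault(_key(c.parent), []).append(c)
        out, stack = set(), [root]
        while stack:
            c = stack.pop()
            out.add(c.name)
            stack.extend(children.get(_key(c.name), []))
        return out

    def instances_of(self, class_name: str) -> set[InstanceValue]:
        """All instances whose owning class is ``class_name`` or a descendant."""
        names = {_key(n) for n in self.descendants(class_name)}
        return {i for i in self.instances if _key(i.owning_class) in names}

    def related_instances(
        self, instance: InstanceValue, predicate: str, target_class: str
    ) -> set[InstanceValue]:
        """Instances of ``target_class`` linked to ``instance`` by ``predicate``.

        The lookup is symmetric: ``instance`` may appear as either end of the
        assertion.
        """
        if predicate not in PREDICATES:
            raise VocabularyError(predicate)
        inst = self.resolve_instance(instance.owning_class, instance.label)
        targets = {_key(n) for n in self.descendants(target_class)}
        out = set()
        for r in self.relations:
            if r.predicate != predicate:
                continue
            if r.subject == inst and _key(r.object.owning_class) in targets:
                out.add(r.object)
            if r.object == inst and _key(r.subject.owning_class) in targets:
                out.add(r.subject)
        return out

    def related(self, instance: InstanceValue, target_class: str) -> set[InstanceValue]:
        """Union of :meth:`related_instances` over all predicates."""
        out: set[InstanceValue] = set()
        for p in PREDICATES:
            out |= self.related_instances(instance, p, target_class)
        return out

    def has_relation_to_class(self, instance: InstanceValue, target_class: str) -> bool:
        """True if any assertion links ``instance`` to an instance of ``target_class``."""
        return bool(self.related(instance, target_class))

    # -- equality -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            set(self.classes) == set(other.classes)
            and set(self.instances) == set(other.instances)
            and set(self.relations) == set(other.relations)
        )

    def __hash__(self):  # pragma: no cover - containers of ontologies are rare
        return hash((frozenset(self.classes), frozenset(self.instances), frozenset(self.relations)))

    def __repr__(self) -> str:
        return (
            f"Ontology({len(self.classes)} classes, {len(self.instances)} instances, "
            f"{len(self.relations)} relations)"
        )


# -- serialization ----------------------------------------------------------

_SLUG_RE = re.compile(r"[^A-Za-z0-9]+")


def _slug(text: str) -> str:
    return _SLUG_RE.sub("_", text).strip("_")


def _class_uri(c: OntologyClass) -> URIRef:
    if c.parent is None:
        return PROV[c.name]
    return SYSPRO[_slug(c.name)]


def _instance_uri(i: InstanceValue) -> URIRef:
    return SYSPRO[f"i_{_slug(i.owning_class)}__{_slug(i.label)}"]


def save_ontology(o: Ontology, path: str | Path) -> None:
    """Serialize ``o`` as Turtle; ``load_ontology`` inverts this exactly."""
    g = Graph()
    g.bind("prov", PROV)
    g.bind("syspro", SYSPRO)
    g.bind("skos", SKOS)
    uris: dict[tuple[str, str], URIRef] = {}
    for c in sorted(o.classes, key=lambda c: c.name):
        u = _class_uri(c)
        g.add((u, RDF.type, RDFS.Class))
        g.add((u, RDFS.label, Literal(c.name)))
        if c.parent is not None:
            parent = o.resolve_class(c.parent)
            g.add((u, RDFS.subClassOf, _class_uri(parent)))
        for a in c.aliases:
            g.add((u, SKOS.altLabel, Literal(a)))
    for i in sorted(o.instances, key=lambda i: (i.owning_class, i.label)):
        u = _instance_uri(i)
        if u in uris.values():
            raise OntologyValidationError([f"instance URI collision for {i.label!r}"])
        uris[(_key(i.owning_class), _key(i.label))] = u
        g.add((u, RDF.type, _class_uri(o.resolve_class(i.owning_class))))
        g.add((u, RDFS.label, Literal(i.label)))
    for r in o.relations:
        s = uris[(_key(r.subject.owning_class), _key(r.subject.label))]
        t = uris[(_key(r.object.owning_class), _key(r.object.label))]
        g.add((s, PROV[r.predicate], t))
    Path(path).write_text(g.serialize(format="turtle"), encoding="utf-8")


def load_ontology(path: str | Path) -> Ontology:
    """Parse a Turtle ontology file and validate all structural invariants."""
    g = Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as exc:  # rdflib raises parser-specific exceptions
        raise OntologyFormatError(f"cannot parse {path} as Turtle: {exc}") from exc

    def label_of(u: URIRef) -> str:
        lbl = g.value(u, RDFS.label)
        if lbl is not None:
            return str(lbl)
        # fall back to the URI local name with underscores as spaces
        local = str(u).rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        return local.replace("_", " ")

    problems: list[str] = []
    class_uris = sorted(set(g.subjects(RDF.type, RDFS.Class)), key=str)
    classes: list[OntologyClass] = []
    uri_to_name: dict[URIRef, str] = {}
    root_uris = {PROV[r]: r for r in PROV_CORE}

    for u in class_uris:
        uri_to_name[u] = label_of(u)

    for u in class_uris:
        name = uri_to_name[u]
        parents = sorted(set(g.objects(u, RDFS.subClassOf)), key=str)
        aliases = tuple(sorted(str(a) for a in g.objects(u, SKOS.altLabel)))
        if u in root_uris:
            if parents:
                problems.append(f"PROV-O root {name!r} must not have a parent")
            classes.append(OntologyClass(name=root_uris[u], parent=None, prov_core=root_uris[u]))
            continue
        if len(parents) > 1:
            problems.append(f"class {name!r} has multiple parents (multiple inheritance rejected)")
            continue
        if not parents:
            problems.append(f"class {name!r} has no rdfs:subClassOf parent")
            continue
        p = parents[0]
        if p not in uri_to_name and p not in root_uris:
            problems.append(f"class {name!r}: parent {p} is not a declared class")
            continue
        parent_name = root_uris.get(p) or uri_to_name[p]
        classes.append(OntologyClass(name=name, parent=parent_name, prov_core="Entity", aliases=aliases))

    # recompute prov_core by walking the parent chain
    by_name = {_key(c.name): c for c in classes}
    resolved: list[OntologyClass] = []
    for c in classes:
        if c.parent is None:
            resolved.append(c)
            continue
        cur, core, seen = c, None, set()
        while True:
            pk = _key(cur.parent) if cur.parent else None
            if pk is None:
                break
            if pk in {_key(r) for r in PROV_CORE}:
                core = by_name[pk].name if pk in by_name else _norm_ws(cur.parent)
                break
            if pk in seen or pk not in by_name:
                break
            seen.add(pk)
            cur = by_name[pk]
        if core is None:
            problems.append(f"class {c.name!r} does not reach a PROV-O root")
            core = "Entity"
        resolved.append(OntologyClass(name=c.name, parent=c.parent, prov_core=core, aliases=c.aliases))

    known_class_uris = set(uri_to_name)
    inst_uri_to_value: dict[URIRef, InstanceValue] = {}
    instances: list[InstanceValue] = []
    for s, _, cls_uri in g.triples((None, RDF.type, None)):
        if cls_uri == RDFS.Class or s in known_class_uris:
            continue
        if cls_uri not in known_class_uris:
            # a typed node in our namespaces must belong to a declared class
            if str(cls_uri).startswith(str(SYSPRO)) or str(cls_uri).startswith(str(PROV)):
                problems.append(
                    f"instance {s} has undeclared owning class {cls_uri}"
                )
            continue
        iv = InstanceValue(label=label_of(s), owning_class=uri_to_name[cls_uri])
        inst_uri_to_value[s] = iv
        instances.append(iv)

    relations: list[RelationAssertion] = []
    for pred in PREDICATES:
        for s, _, t in g.triples((None, PROV[pred], None)):
            if s not in inst_uri_to_value or t not in inst_uri_to_value:
                problems.append(f"relation {pred} links undeclared node(s): {s} -> {t}")
                continue
            relations.append(
                RelationAssertion(inst_uri_to_value[s], pred, inst_uri_to_value[t])
            )

    if problems:
        raise OntologyValidationError(problems)
    resolved.sort(key=lambda c: c.name)
    instances.sort(key=lambda i: (i.owning_class, i.label))
    return Ontology(resolved, instances, sorted(set(relations), key=lambda r: (
        r.subject.owning_class, r.subject.label, r.predicate, r.object.owning_class, r.object.label)))


def instances_of(o: Ontology, class_name: str) -> set[InstanceValue]:
    return o.instances_of(class_name)


def related_instances(
    o: Ontology, instance: InstanceValue, predicate: str, target_class: str
) -> set[InstanceValue]:
    return o.related_instances(instance, predicate, target_class)


def syspro_lite() -> Ontology:
    """The packaged miniature SysPro-style ontology used throughout the tests."""
    with resources.as_file(resources.files("provdash.data") / "syspro_lite.ttl") as p:
        return load_ontology(p)


def syspro_lite_path() -> Path:
    """Filesystem path of the packaged ontology (valid while the package is installed)."""
    return Path(str(resources.files("provdash.data") / "syspro_lite.ttl"))
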