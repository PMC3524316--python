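"""Shared test utilities: independent oracles and random-object generators.

The oracles deliberately re-derive results by brute force (linear scans,
explicit left-to-right folds, relation-table scans) without going through
the query engine, so engine results can be checked against them.
"""

from __future__ import annotations

from random import Random

from provdash.ontology import (
    PREDICATES,
    InstanceValue,
    Ontology,
    OntologyClass,
    RelationAssertion,
)
from provdash.pattern import Condition, QueryPattern


def _cf(s: str) -> str:
    return " ".join(s.split()).casefold()


def attr_of(exp, class_name: str) -> str | None:
    for k, v in exp.attributes.items():
        if _cf(k) == _cf(class_name):
            return v
    return None


def fold_oracle_match(p: QueryPattern, exp) -> bool:
    """Left-to-right fold of per-condition truths, written out longhand."""
    truths = []
    for cond in p.conditions:
        got = attr_of(exp, cond.class_name)
        truths.append(got is not None and _cf(got) == _cf(cond.value))
    if not truths:
        return True
    acc = truths[0]
    for connective, t in zip(p.connectives, truths[1:]):
        if connective == "AND":
            acc = acc and t
        else:
            acc = acc or t
    return acc


def fold_oracle_ids(p: QueryPattern, store) -> set[str]:
    return {e.experiment_id for e in store.experiments if fold_oracle_match(p, e)}


def scan_count(store, class_name: str, value: str) -> int:
    n = 0
    for e in store.experiments:
        got = attr_of(e, class_name)
        if got is not None and _cf(got) == _cf(value):
            n += 1
    return n


def relation_scan(o: Ontology, inst: InstanceValue, target_class: str,
                  predicate: str | None = None) -> set[str]:
    """Labels of instances of ``target_class`` linked to ``inst``, by a
    linear scan over every relation assertion (symmetric)."""
    preds = PREDICATES if predicate is None else (predicate,)
    out = set()
    for r in o.relations:
        if r.predicate not in preds:
            continue
        if _cf(r.subject.label) == _cf(inst.label) and _cf(r.subject.owning_class) == _cf(inst.owning_class):
            if _cf(r.object.owning_class) == _cf(target_class):
                out.add(r.object.label)
        if _cf(r.object.label) == _cf(inst.label) and _cf(r.object.owning_class) == _cf(inst.owning_class):
            if _cf(r.subject.owning_class) == _cf(target_class):
                out.add(r.subject.label)
    return out


def candidate_oracle(o: Ontology, store, selected: list[tuple[str, str]],
                     target_class: str) -> set[str]:
    """Brute-force smart-filter expectation for one facet class.

    A value is expected iff (a) appending it conjunctively to the selected
    conditions (minus any on the target class) leaves >= 1 matching record,
    and (b) no selected value's relation assertions exclude it.
    """
    others = [(c, v) for c, v in selected if _cf(c) != _cf(target_class)]
    expected = set()
    for value in sorted({v for e in store.experiments
                         if (v := attr_of(e, target_class)) is not None}):
        conj = QueryPattern(
            tuple(Condition(c, v) for c, v in others) + (Condition(target_class, value),),
            tuple("AND" for _ in others),
        )
        if not any(fold_oracle_match(conj, e) for e in store.experiments):
            continue
        excluded = False
        for c, v in others:
            inst = o.resolve_instance(c, v)
            allowed = relation_scan(o, inst, target_class)
            if allowed and _cf(value) not in {_cf(a) for a in allowed}:
                excluded = True
        if not excluded:
            expected.add(value)
    return expected


def random_pattern(rng: Random, vocab: dict[str, list[str]],
                   min_len: int = 1, max_len: int = 8) -> QueryPattern:
    classes = sorted(vocab)
    n = rng.randint(min_len, max_len)
    conds = []
    for _ in range(n):
        cls = rng.choice(classes)
        conds.append(Condition(cls, rng.choice(vocab[cls])))
    conns = tuple(rng.choice(("AND", "OR")) for _ in range(n - 1))
    return QueryPattern(tuple(conds), conns)


_DECOR = ["", " µ", "'s", ' "q"', " (x)"]


def random_ontology(rng: Random) -> Ontology:
    """A random valid ontology: acyclic hierarchy, unique instances, relations."""
    roots = ["Activity", "Entity", "Agent"]
    classes = [OntologyClass(r, None, r) for r in roots]
    core_of = {r: r for r in roots}
    names: list[str] = []
    for i in range(rng.randint(1, 8)):
        name = f"Class{i}{rng.choice('ABCDEF')}"
        parent = rng.choice(roots + names)
        core_of[name] = core_of[parent]
        classes.append(OntologyClass(name, parent, core_of[parent]))
        names.append(name)
    instances: list[InstanceValue] = []
    counter = 0
    for name in names:
        for _ in range(rng.randint(0, 3)):
            counter += 1
            label = f"v{counter}{rng.choice(_DECOR)}"
            instances.append(InstanceValue(label, name))
    relations: list[RelationAssertion] = []
    if len(instances) >= 2:
        for _ in range(rng.randint(0, 4)):
            a, b = rng.sample(instances, 2)
            relations.append(RelationAssertion(a, rng.choice(PREDICATES), b))
    return Ontology(classes, instances, sorted(set(relations), key=lambda r: (
        r.subject.owning_class, r.subject.label, r.predicate,
        r.object.owning_class, r.object.label)))
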