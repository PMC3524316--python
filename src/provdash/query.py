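"""Query evaluation, SQL translation, smart filtering and constraint propagation.

Semantics
---------
A complete pattern matches an experiment iff the left-to-right boolean fold
of its per-condition truth values under the AND/OR connectives is true; there
is no operator precedence and the translated SQL parenthesizes the fold
explicitly, ``(((c1 op1 c2) op2 c3) ...)``, so the interpretation is auditable.
All value and class comparisons are case-insensitive.

Smart filtering answers "which values may the user still pick": for each
facet class the admissible values are those occurring in experiments that
satisfy the *conjunction* of the already-selected conditions (excluding any
condition on the class being edited), intersected with the values the
ontology's instance-level relations allow for the selected instances.
Constraint propagation applies those relations to an edited pattern: when a
changed value is ontology-linked to exactly one admissible value of another
selected class, that value is substituted; when several are possible the
slot is cleared rather than guessed.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path

from .fixtures import Experiment, ExperimentStore, column_for_class
from .mapping import DataSourceConfig
from .ontology import Ontology, _key
from .pattern import Condition, QueryPattern


class TranslationError(Exception):
    """A pattern references a class with no column mapping."""


@dataclass(frozen=True)
class ResultSet:
    """Matches grouped per project (ordered by project id), plus the total."""

    groups: tuple[tuple[str, str, tuple[Experiment, ...]], ...]
    total: int

    def match_ids(self) -> set[str]:
        return {e.experiment_id for _, _, exps in self.groups for e in exps}


@dataclass(frozen=True)
class CandidateSet:
    """Admissible next values per facet class, sorted case-insensitively."""

    per_class: dict[str, tuple[str, ...]]


def validate_pattern(
    p: QueryPattern, o: Ontology, cfg: DataSourceConfig | None = None
) -> QueryPattern:
    """Canonicalize class names and values against the ontology.

    Resolves aliases and case variants to the declared spellings and, when a
    config is given, checks every condition's class is mapped (raising
    :class:`TranslationError` before any store access otherwise).
    """
    conds = []
    for c in p.conditions:
        cls = o.resolve_class(c.class_name)
        if cfg is not None and cfg.column_for(cls.name) is None:
            raise TranslationError(f"class {cls.name!r} has no column mapping")
        value = c.value
        if value is not None:
            value = o.resolve_instance(cls.name, value).label
        conds.append(Condition(cls.name, value))
    return QueryPattern(tuple(conds), p.connectives)


def _attr(e: Experiment, class_name: str) -> str | None:
    v = e.attributes.get(class_name)
    if v is not None:
        return v
    k = _key(class_name)
    for cls, val in e.attributes.items():
        if _key(cls) == k:
            return val
    return None


def _cond_matches(c: Condition, e: Experiment) -> bool:
    if c.value is None:
        raise ValueError(f"condition on {c.class_name!r} has no value yet")
    v = _attr(e, c.class_name)
    return v is not None and _key(v) == _key(c.value)


def _fold_matches(p: QueryPattern, e: Experiment) -> bool:
    if not p.conditions:
        return True
    acc = _cond_matches(p.conditions[0], e)
    for conn, cond in zip(p.connectives, p.conditions[1:]):
        b = _cond_matches(cond, e)
        acc = (acc and b) if conn == "AND" else (acc or b)
    return acc


def evaluate(p: QueryPattern, s: ExperimentStore) -> ResultSet:
    """Run a pattern in memory and group the matches by project."""
    matches = [e for e in s.experiments if _fold_matches(p, e)]
    names = s.project_names
    by_project: dict[str, list[Experiment]] = {}
    for e in matches:
        by_project.setdefault(e.project_id, []).append(e)
    groups = tuple(
        (pid, names.get(pid, pid), tuple(sorted(exps, key=lambda e: e.experiment_id)))
        for pid, exps in sorted(by_project.items())
    )
    return ResultSet(groups=groups, total=len(matches))


@dataclass(frozen=True)
class TranslatedQuery:
    """A parameterized SQL statement; values are bound, never interpolated."""

    sql: str
    params: tuple[str, ...]
    where: str


def translate(p: QueryPattern, cfg: DataSourceConfig) -> TranslatedQuery:
    """Compile a pattern to SQL over the mapped experiments table."""
    clauses, params = [], []
    for c in p.conditions:
        col = cfg.column_for(c.class_name)
        if col is None:
            raise TranslationError(f"class {c.class_name!r} has no column mapping")
        if c.value is None:
            raise TranslationError(f"condition on {c.class_name!r} has no value")
        clauses.append(f"{col} = ? COLLATE NOCASE")
        params.append(c.value)
    if not clauses:
        where = ""
        sql = "SELECT experiment_id, project_id FROM experiments"
    else:
        where = clauses[0]
        for conn, clause in zip(p.connectives, clauses[1:]):
            where = f"({where} {conn} {clause})"
        sql = f"SELECT experiment_id, project_id FROM experiments WHERE {where}"
    return TranslatedQuery(sql=sql, params=tuple(params), where=where)


def execute_translated(tq: TranslatedQuery, db_path: str | Path) -> set[str]:
    """Run a translated query against the SQLite store; returns matching ids."""
    con = sqlite3.connect(str(db_path))
    try:
        rows = con.execute(tq.sql, tq.params).fetchall()
    finally:
        con.close()
    return {r[0] for r in rows}


def smart_filter(
    p_partial: QueryPattern,
    editing_class: str | None,
    s: ExperimentStore,
    o: Ontology,
) -> CandidateSet:
    """Candidate values per class given the already-selected conditions.

    Every offered value is guaranteed to keep the conjunctive extension of
    the current selection non-empty, and to be compatible with the
    instance-level relations of every selected value. Classes or values
    without relation assertions are unconstrained by the ontology.
    """
    store_classes = s.attribute_classes()
    if editing_class is None:
        targets = store_classes
    else:
        targets = [o.resolve_class(editing_class).name]
    selected = [
        validate_pattern(QueryPattern((c,), ()), o).conditions[0]
        for c in p_partial.conditions
        if c.value is not None
    ]
    per_class: dict[str, tuple[str, ...]] = {}
    for cls in targets:
        ck = _key(cls)
        others = [c for c in selected if _key(c.class_name) != ck]
        context = [e for e in s.experiments if all(_cond_matches(c, e) for c in others)]
        data_vals = {v for e in context if (v := _attr(e, cls)) is not None}
        allowed: set[str] | None = None
        for c in others:
            inst = o.resolve_instance(c.class_name, c.value)
            rel = o.related(inst, cls)
            if rel:
                labels = {_key(r.label) for r in rel}
                allowed = labels if allowed is None else allowed & labels
        if allowed is not None:
            data_vals = {v for v in data_vals if _key(v) in allowed}
        per_class[cls] = tuple(sorted(data_vals, key=str.casefold))
    return CandidateSet(per_class=per_class)


def propagate(p: QueryPattern, changed_index: int, o: Ontology) -> QueryPattern:
    """Reconcile other conditions with an edited one via ontology relations.

    For each other selected condition whose value is incompatible with the
    changed instance: substitute when the relation admits exactly one value
    of that class, otherwise clear the value and leave the slot pending.
    Conditions unrelated to the changed instance are untouched.
    """
    changed = p.conditions[changed_index]
    if changed.value is None:
        return p
    inst = o.resolve_instance(changed.class_name, changed.value)
    out = p
    for i, c in enumerate(p.conditions):
        if i == changed_index or c.value is None:
            continue
        rel = o.related(inst, c.class_name)
        if not rel:
            continue
        labels = {_key(r.label): r.label for r in rel}
        if _key(c.value) in labels:
            continue
        if len(labels) == 1:
            out = out.replace_value(i, next(iter(labels.values())))
        else:
            out = out.replace_value(i, None)
    return out


def link_out(e: Experiment, base_url: str) -> str:
    """Deterministic LIMS URL stub for an experiment (no network access)."""
    return f"{base_url.rstrip('/')}/project/{e.project_id}/experiment/{e.experiment_id}"
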