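"""Ontology-to-store mapping: which store column answers for which ontology class.

A data source is configured by declaring, for each queryable ontology class
(a "facet"), the column of the experiment-metadata store that holds its
values. The mapping is manually curated and may be partial: facet classes
left unmapped are reported as warnings, while references to unknown classes
or columns are errors that make the configuration unusable.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .ontology import Ontology, _key

FORMAT_VERSION = 1


class ConfigError(Exception):
    """The configuration document is malformed or violates an invariant."""


@dataclass(frozen=True)
class ColumnMapping:
    class_name: str
    column: str


@dataclass(frozen=True)
class DataSourceConfig:
    name: str
    store_uri: str
    mappings: tuple[ColumnMapping, ...]
    format_version: int = FORMAT_VERSION

    def __post_init__(self):
        if not self.mappings:
            raise ConfigError("data-source config must declare at least one mapping")
        cols: dict[str, str] = {}
        classes: set[str] = set()
        for m in self.mappings:
            ck = _key(m.class_name)
            if ck in classes:
                raise ConfigError(f"class {m.class_name!r} mapped more than once")
            classes.add(ck)
            if m.column in cols:
                raise ConfigError(
                    f"column {m.column!r} mapped by both {cols[m.column]!r} and {m.class_name!r}"
                )
            cols[m.column] = m.class_name

    def column_for(self, class_name: str) -> str | None:
        k = _key(class_name)
        for m in self.mappings:
            if _key(m.class_name) == k:
                return m.column
        return None

    def mapped_classes(self) -> tuple[str, ...]:
        return tuple(m.class_name for m in self.mappings)


@dataclass
class ValidationReport:
    """Outcome of checking a config against an ontology and a store schema."""

    missing_classes: list[str] = field(default_factory=list)
    missing_columns: list[str] = field(default_factory=list)
    unmapped_facets: list[str] = field(default_factory=list)

    @property
    def errors(self) -> list[str]:
        return self.missing_classes + self.missing_columns

    @property
    def usable(self) -> bool:
        """True when every mapped class and column resolves (warnings allowed)."""
        return not self.errors

    @property
    def empty(self) -> bool:
        return not (self.errors or self.unmapped_facets)

    def lines(self) -> list[str]:
        out = []
        for c in self.missing_classes:
            out.append(f"error: mapped class {c!r} is not in the ontology")
        for c in self.missing_columns:
            out.append(f"error: mapped column {c!r} is not in the store schema")
        for c in self.unmapped_facets:
            out.append(f"warning: ontology class {c!r} has instances but no mapping")
        return out


def load_config(path: str | Path) -> DataSourceConfig:
    """Parse a YAML data-source configuration (no live validation yet)."""
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping document")
    for key in ("name", "store_uri", "mappings"):
        if key not in doc:
            raise ConfigError(f"{path}: missing key {key!r}")
    raw = doc["mappings"]
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: 'mappings' must be a list")
    mappings = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "class" not in entry or "column" not in entry:
            raise ConfigError(f"{path}: mappings[{i}] must have 'class' and 'column' keys")
        mappings.append(ColumnMapping(str(entry["class"]), str(entry["column"])))
    return DataSourceConfig(
        name=str(doc["name"]),
        store_uri=str(doc["store_uri"]),
        mappings=tuple(mappings),
        format_version=int(doc.get("format_version", FORMAT_VERSION)),
    )


def save_config(cfg: DataSourceConfig, path: str | Path) -> None:
    doc = {
        "format_version": cfg.format_version,
        "name": cfg.name,
        "store_uri": cfg.store_uri,
        "mappings": [{"class": m.class_name, "column": m.column} for m in cfg.mappings],
    }
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def validate_mapping(
    cfg: DataSourceConfig, o: Ontology, schema: set[str]
) -> ValidationReport:
    """Cross-check a config against an ontology and a store column schema.

    Side-effect free and idempotent. Reports, in order: mapped classes absent
    from the ontology, mapped columns absent from the schema, and ontology
    classes that carry instances but have no mapping (unmapped facets, a
    warning only).
    """
    report = ValidationReport()
    for m in cfg.mappings:
        if not o.has_class(m.class_name):
            report.missing_classes.append(m.class_name)
        if m.column not in schema:
            report.missing_columns.append(m.column)
    mapped = {_key(m.class_name) for m in cfg.mappings}
    with_instances = {_key(i.owning_class) for i in o.instances}
    for c in sorted(o.classes, key=lambda c: c.name):
        ck = _key(c.name)
        if ck in with_instances and ck not in mapped and not any(
            _key(a) in mapped for a in c.aliases
        ):
            report.unmapped_facets.append(c.name)
    return report


def default_config() -> DataSourceConfig:
    """The packaged mapping for the synthetic proteomics-core store."""
    with resources.as_file(resources.files("provdash.data") / "default_mapping.yaml") as p:
        return load_config(p)


def default_config_path() -> Path:
    return Path(str(resources.files("provdash.data") / "default_mapping.yaml"))
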