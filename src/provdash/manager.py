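"""Saved-query catalog: persist, list, retrieve and re-execute named patterns.

The catalog is a single human-readable YAML document. Saves are atomic
(write-to-temp, then rename), so a crash can lose at most the save in
flight, never corrupt the catalog. Patterns are stored in their DSL text
form and re-parsed on execution — results are never cached, so a re-run
always reflects the store at call time. Timestamps are recorded in UTC.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import yaml

from .fixtures import ExperimentStore
from .pattern import QueryPattern, parse_pattern, render_pattern

FORMAT_VERSION = 1


class CatalogError(Exception):
    pass


class UnknownQueryError(CatalogError, LookupError):
    pass


def _now() -> datetime:
    return datetime.now(timezone.utc).replace(microsecond=0)


def _iso(dt: datetime) -> str:
    return dt.astimezone(timezone.utc).isoformat()


@dataclass(frozen=True)
class SavedQuery:
    name: str
    description: str
    creator: str
    created_at: datetime
    updated_at: datetime
    pattern_text: str

    @property
    def pattern(self) -> QueryPattern:
        return parse_pattern(self.pattern_text)


class QueryCatalog:
    """In-memory view of one catalog file; every mutation is persisted."""

    def __init__(self, storage_path: str | Path):
        self.storage_path = Path(storage_path)
        self._entries: dict[str, SavedQuery] = {}
        if self.storage_path.exists():
            self._load()

    def _load(self) -> None:
        try:
            doc = yaml.safe_load(self.storage_path.read_text(encoding="utf-8")) or {}
        except yaml.YAMLError as exc:
            raise CatalogError(f"cannot parse catalog {self.storage_path}: {exc}") from exc
        for entry in doc.get("queries", []):
            sq = SavedQuery(
                name=str(entry["name"]),
                description=str(entry.get("description", "")),
                creator=str(entry.get("creator", "")),
                created_at=datetime.fromisoformat(entry["created_at"]),
                updated_at=datetime.fromisoformat(entry["updated_at"]),
                pattern_text=str(entry["pattern"]),
            )
            self._entries[sq.name] = sq

    def _persist(self) -> None:
        doc = {
            "format_version": FORMAT_VERSION,
            "queries": [
                {
                    "name": sq.name,
                    "description": sq.description,
                    "creator": sq.creator,
                    "created_at": _iso(sq.created_at),
                    "updated_at": _iso(sq.updated_at),
                    "pattern": sq.pattern_text,
                }
                for sq in list_queries(self)
            ],
        }
        parent = self.storage_path.parent
        parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
            os.replace(tmp, self.storage_path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    def get(self, name: str) -> SavedQuery:
        try:
            return self._entries[name]
        except KeyError:
            raise UnknownQueryError(f"no saved query named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)


def save_query(
    cat: QueryCatalog,
    name: str,
    description: str,
    creator: str,
    pattern: QueryPattern | str,
) -> SavedQuery:
    """Persist a pattern under ``name``; re-saving updates in place.

    A re-save keeps ``created_at`` and strictly increases ``updated_at``.
    The pattern is parsed before anything is written, so an unparsable
    pattern never reaches the catalog.
    """
    if not name or not name.strip():
        raise CatalogError("query name must be non-empty")
    if isinstance(pattern, str):
        parsed = parse_pattern(pattern)  # reject before persistence
        text = render_pattern(parsed)
    else:
        text = render_pattern(pattern)
    now = _now()
    if name in cat:
        old = cat.get(name)
        updated = max(now, old.updated_at + timedelta(seconds=1))
        sq = replace(old, description=description, creator=creator,
                     updated_at=updated, pattern_text=text)
    else:
        sq = SavedQuery(name=name, description=description, creator=creator,
                        created_at=now, updated_at=now, pattern_text=text)
    cat._entries[name] = sq
    cat._persist()
    return sq


def list_queries(cat: QueryCatalog) -> list[SavedQuery]:
    """All entries, most recently updated first; ties broken by name."""
    return sorted(cat._entries.values(), key=lambda sq: (-sq.updated_at.timestamp(), sq.name))


def delete_query(cat: QueryCatalog, name: str) -> None:
    if name not in cat:
        raise UnknownQueryError(f"no saved query named {name!r}")
    del cat._entries[name]
    cat._persist()


def run_saved(cat: QueryCatalog, name: str, s: ExperimentStore):
    """Re-execute a saved pattern against the store as it is now."""
    from .query import evaluate

    sq = cat.get(name)
    return evaluate(sq.pattern, s)
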