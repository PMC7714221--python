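"""Timestamped <namespace, alias> → sequence-id associations.

Aliases are unique within a namespace *at any point in time*, but carry
full history: re-asserting an existing pair with a different sequence id
deprecates the old record (``is_current = 0``) and inserts a new current
one; records are never deleted, so the naming history of any sequence is
reconstructable from the timestamps.

Computed-identifier namespaces (MD5, SEGUID, SHA1, sha512t24u) are pure
functions of the sequence and therefore can never legitimately be
re-pointed; an attempt to do so is treated as data corruption and
rejected.

Namespace spellings follow identifiers.org prefixes where available
(lowercase ``refseq``, ``ensembl``); a small normalization table maps
common capitalized variants onto them. Digest namespaces keep their
conventional spellings.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

from .digests import COMPUTED_NAMESPACES
from .exceptions import NotFoundError, ReadOnlyError, ReferentialError
from .fastadir import utc_now_iso

__all__ = ["SeqAliasDb", "AliasRecord", "normalize_namespace"]

_SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS seqalias (
    alias_id   INTEGER PRIMARY KEY AUTOINCREMENT,
    seq_id     TEXT NOT NULL,
    namespace  TEXT NOT NULL,
    alias      TEXT NOT NULL,
    added      TEXT NOT NULL,
    is_current INTEGER NOT NULL DEFAULT 1
);
CREATE INDEX IF NOT EXISTS seqalias_ns_alias ON seqalias (namespace, alias);
CREATE INDEX IF NOT EXISTS seqalias_seq_id   ON seqalias (seq_id);
CREATE INDEX IF NOT EXISTS seqalias_alias    ON seqalias (alias);
"""

# Documented normalization of common capitalizations onto the canonical
# identifiers.org-style lowercase prefixes. Matching is otherwise
# case-sensitive and byte-exact (no version stripping).
_NAMESPACE_ALIASES = {
    "RefSeq": "refseq",
    "Ensembl": "ensembl",
    "ensembl-transcript": "ensembl",
    "NCBI": "refseq",
}


def normalize_namespace(namespace: str) -> str:
    return _NAMESPACE_ALIASES.get(namespace, namespace)


@dataclass(frozen=True)
class AliasRecord:
    alias_id: int
    seq_id: str
    namespace: str
    alias: str
    added: str  # UTC ISO-8601
    is_current: bool


class SeqAliasDb:
    """Alias store under ``<root>/aliases/db``.

    ``seq_id_exists`` is an optional referential-integrity hook: when
    provided (the repo facade wires it to the sequence store), storing an
    alias for an unknown sequence id raises :class:`ReferentialError`.
    """

    def __init__(
        self,
        root: str | os.PathLike,
        writeable: bool = False,
        seq_id_exists: Optional[Callable[[str], bool]] = None,
    ):
        self.root = Path(root)
        self.writeable = writeable
        self._seq_id_exists = seq_id_exists
        db_path = self.root / "aliases" / "db"
        if writeable:
            db_path.parent.mkdir(parents=True, exist_ok=True)
            self._db = sqlite3.connect(db_path, timeout=0.2, check_same_thread=False)
            self._db.executescript(_SCHEMA)
            self._db.execute(
                "INSERT OR IGNORE INTO meta (key, value) VALUES ('schema_version', ?)",
                (str(_SCHEMA_VERSION),),
            )
            self._db.commit()
        else:
            if not db_path.exists():
                raise NotFoundError(f"no alias database under {self.root}")
            self._db = sqlite3.connect(
                f"file:{db_path}?mode=ro", uri=True, timeout=0.2,
                check_same_thread=False,
            )

    def store_alias(self, seq_id: str, namespace: str, alias: str) -> int:
        """Associate ``namespace:alias`` with ``seq_id``; return alias_id.

        Idempotent when the pair already points at ``seq_id``; deprecates
        the old record and inserts a new current one when it points
        elsewhere.
        """
        if not self.writeable:
            raise ReadOnlyError("store_alias() on a read-only instance")
        if not namespace or not alias:
            raise ValueError("namespace and alias must be non-empty")
        namespace = normalize_namespace(namespace)
        if self._seq_id_exists is not None and not self._seq_id_exists(seq_id):
            raise ReferentialError(f"unknown sequence id: {seq_id}")
        row = self._db.execute(
            "SELECT alias_id, seq_id FROM seqalias"
            " WHERE namespace = ? AND alias = ? AND is_current = 1",
            (namespace, alias),
        ).fetchone()
        if row is not None:
            if row[1] == seq_id:
                return row[0]
            if namespace in COMPUTED_NAMESPACES:
                raise ValueError(
                    f"computed identifier {namespace}:{alias} cannot be re-pointed"
                )
            self._db.execute(
                "UPDATE seqalias SET is_current = 0 WHERE alias_id = ?", (row[0],)
            )
        cur = self._db.execute(
            "INSERT INTO seqalias (seq_id, namespace, alias, added, is_current)"
            " VALUES (?, ?, ?, ?, 1)",
            (seq_id, namespace, alias, utc_now_iso()),
        )
        self._db.commit()
        return cur.lastrowid

    def find_aliases(
        self,
        namespace: str | None = None,
        alias: str | None = None,
        seq_id: str | None = None,
        current_only: bool = True,
    ) -> list[AliasRecord]:
        """All records matching every provided filter.

        At least one filter is required. ``current_only=False`` exposes
        the full history, ordered by insertion.
        """
        clauses, params = [], []
        if namespace is not None:
            clauses.append("namespace = ?")
            params.append(normalize_namespace(namespace))
        if alias is not None:
            clauses.append("alias = ?")
            params.append(alias)
        if seq_id is not None:
            clauses.append("seq_id = ?")
            params.append(seq_id)
        if not clauses:
            raise ValueError("find_aliases requires at least one filter")
        if current_only:
            clauses.append("is_current = 1")
        sql = (
            "SELECT alias_id, seq_id, namespace, alias, added, is_current"
            " FROM seqalias WHERE " + " AND ".join(clauses) + " ORDER BY added, alias_id"
        )
        return [
            AliasRecord(r[0], r[1], r[2], r[3], r[4], bool(r[5]))
            for r in self._db.execute(sql, params)
        ]

    def translate(self, alias: str, namespace: str | None = None) -> list[str]:
        """Sequence ids of current records for ``alias``.

        With a namespace the result has 0 or 1 elements; without one,
        the distinct seq_ids across all namespaces are returned (the
        caller decides whether >1 is an error — see the repo facade's
        ambiguity handling).
        """
        if not alias:
            raise ValueError("alias must be non-empty")
        recs = self.find_aliases(namespace=namespace, alias=alias, current_only=True)
        seen: list[str] = []
        for r in recs:
            if r.seq_id not in seen:
                seen.append(r.seq_id)
        return seen

    def n_records(self, current_only: bool = False) -> int:
        sql = "SELECT COUNT(*) FROM seqalias"
        if current_only:
            sql += " WHERE is_current = 1"
        return self._db.execute(sql).fetchone()[0]

    def close(self) -> None:
        self._db.close()

    def __enter__(self) -> "SeqAliasDb":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
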