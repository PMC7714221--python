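"""User-level repository facade.

``SeqVault`` combines the sequence store (:mod:`seqvault.fastadir`) and
the alias database (:mod:`seqvault.seqaliasdb`) behind the interface a
client actually uses: store a sequence together with its identifiers,
fetch (slices) by any identifier, translate between identifiers, and
snapshot the instance with hard links.

Identifiers are W3C CURIEs, ``prefix:reference`` (namespace:alias). A
bare alias may be used when it is globally unique across namespaces;
otherwise resolution fails with an ambiguity error rather than applying
a priority list. The ``ga4gh`` namespace is a presentation of the
internal digest: ``ga4gh:SQ.<sha512t24u>`` and ``sha512t24u:<digest>``
resolve to the same record, and translation emits both spellings.
"""

from __future__ import annotations

import errno
import os
import shutil
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .digests import COMPUTED_NAMESPACES, compute_identifiers
from .exceptions import (
    AmbiguousIdentifierError,
    CrossDeviceError,
    CurieParseError,
    NotFoundError,
    ReadOnlyError,
)
from .fastadir import FastaDir, SequenceRecord
from .seqaliasdb import AliasRecord, SeqAliasDb, normalize_namespace

__all__ = ["SeqVault", "Curie", "SequenceProxy", "RepoStats", "SnapshotReport"]

#: Marker file present at the root of snapshot instances.
SNAPSHOT_MARKER = ".snapshot"


@dataclass(frozen=True, order=True)
class Curie:
    """Compact URI: ``prefix:reference`` (namespace:alias)."""

    prefix: str
    reference: str

    def __post_init__(self):
        if not self.prefix or not self.reference:
            raise CurieParseError(f"empty prefix or reference in {self!r}")
        if ":" in self.prefix:
            raise CurieParseError(f"prefix must not contain ':': {self.prefix!r}")

    @classmethod
    def parse(cls, text: str) -> "Curie":
        """Parse ``prefix:reference``; the reference may itself contain colons."""
        prefix, sep, reference = text.partition(":")
        if not sep or not prefix or not reference:
            raise CurieParseError(f"not a CURIE: {text!r}")
        return cls(prefix, reference)

    def __str__(self) -> str:
        return f"{self.prefix}:{self.reference}"


@dataclass(frozen=True)
class RepoStats:
    n_sequences: int
    n_aliases: int
    total_residues: int


@dataclass(frozen=True)
class SnapshotReport:
    dest: str
    n_files_linked: int
    n_files_copied: int


class SequenceProxy:
    """Lazily sliceable view of one stored sequence.

    ``repo[identifier]`` returns a proxy; ``proxy[a:b]`` fetches only
    that slice, ``str(proxy)`` the full sequence.
    """

    def __init__(self, repo: "SeqVault", seq_id: str, length: int):
        self._repo = repo
        self.seq_id = seq_id
        self._len = length

    def __len__(self) -> int:
        return self._len

    def __getitem__(self, key: slice | int) -> str:
        if isinstance(key, int):
            if key < 0:
                key += self._len
            return self._repo._fastadir.fetch(self.seq_id, key, key + 1)
        if key.step not in (None, 1):
            raise ValueError("stepped slices are not supported")
        start, end, _ = key.indices(self._len)
        return self._repo._fastadir.fetch(self.seq_id, start, end)

    def __str__(self) -> str:
        return self._repo._fastadir.fetch(self.seq_id)

    def __eq__(self, other) -> bool:
        if isinstance(other, str):
            return str(self) == other
        if isinstance(other, SequenceProxy):
            return self.seq_id == other.seq_id
        return NotImplemented


class SeqVault:
    """A repository instance rooted at ``root``.

    Open read-only (the default) for querying, or ``writeable=True`` to
    load sequences. Snapshot instances are permanently read-only.
    """

    def __init__(self, root: str | os.PathLike, writeable: bool = False):
        self.root = Path(root)
        if writeable and (self.root / SNAPSHOT_MARKER).exists():
            raise ReadOnlyError(f"{self.root} is a snapshot and cannot be written")
        self.writeable = writeable
        self._fastadir = FastaDir(self.root, writeable=writeable)
        self._aliases = SeqAliasDb(
            self.root, writeable=writeable, seq_id_exists=self._fastadir.__contains__
        )

    # -- storing -------------------------------------------------------

    def store(self, seq: str, identifiers: Iterable[str | Curie] = ()) -> tuple[int, int]:
        """Store a sequence plus its identifiers.

        Every supplied identifier (CURIE or ``Curie``) and the four
        computed digest identifiers are recorded. Returns
        ``(n_sequences_added, n_aliases_added)`` — both 0 when the call
        is fully redundant.
        """
        if not self.writeable:
            raise ReadOnlyError("store() on a read-only instance")
        curies = [c if isinstance(c, Curie) else Curie.parse(c) for c in identifiers]
        n_aliases_before = self._aliases.n_records()
        seq_id, created = self._fastadir.store(seq)
        for namespace, alias in compute_identifiers(seq).items():
            self._aliases.store_alias(seq_id, namespace, alias)
        for curie in curies:
            self._aliases.store_alias(seq_id, curie.prefix, curie.reference)
        n_aliases_added = self._aliases.n_records() - n_aliases_before
        return (1 if created else 0), n_aliases_added

    def commit(self) -> None:
        """Finalize the open write session's volume."""
        self._fastadir.commit()

    # -- resolution ----------------------------------------------------

    def _resolve(self, identifier: str | Curie) -> str:
        """Resolve any accepted identifier form to the internal seq_id."""
        if isinstance(identifier, Curie):
            namespace, alias = identifier.prefix, identifier.reference
        elif ":" in identifier:
            curie = Curie.parse(identifier)
            namespace, alias = curie.prefix, curie.reference
        else:
            namespace, alias = None, identifier
        if not alias:
            raise NotFoundError("empty identifier")
        if namespace == "ga4gh":
            if not alias.startswith("SQ."):
                raise NotFoundError(f"unknown identifier: ga4gh:{alias}")
            namespace, alias = "sha512t24u", alias[3:]
        seq_ids = self._aliases.translate(alias, namespace=namespace)
        if not seq_ids:
            shown = alias if namespace is None else f"{namespace}:{alias}"
            raise NotFoundError(f"unknown identifier: {shown}")
        if len(seq_ids) > 1:
            namespaces = sorted(
                {r.namespace for r in self._aliases.find_aliases(alias=alias)}
            )
            raise AmbiguousIdentifierError(alias, namespaces)
        return seq_ids[0]

    # -- fetching ------------------------------------------------------

    def fetch(
        self, identifier: str | Curie, start: int | None = None, end: int | None = None
    ) -> str:
        """Subsequence ``[start, end)`` of the sequence named by ``identifier``."""
        return self._fastadir.fetch(self._resolve(identifier), start, end)

    def __getitem__(self, identifier: str | Curie) -> SequenceProxy:
        seq_id = self._resolve(identifier)
        return SequenceProxy(self, seq_id, self._fastadir.info(seq_id).len)

    def __contains__(self, identifier: str | Curie) -> bool:
        try:
            self._resolve(identifier)
            return True
        except (NotFoundError, AmbiguousIdentifierError, CurieParseError):
            return False

    def info(self, identifier: str | Curie) -> SequenceRecord:
        """Storage metadata (length, alphabet, timestamp) for a sequence."""
        return self._fastadir.info(self._resolve(identifier))

    # -- translation ---------------------------------------------------

    def aliases(self, identifier: str | Curie, current_only: bool = True) -> list[AliasRecord]:
        return self._aliases.find_aliases(
            seq_id=self._resolve(identifier), current_only=current_only
        )

    def translate_identifier(
        self,
        identifier: str | Curie,
        target_namespaces: Sequence[str] | None = None,
    ) -> list[Curie]:
        """All current identifiers of the sequence named by ``identifier``.

        The ``ga4gh:SQ.<digest>`` spelling is synthesized alongside the
        stored ``sha512t24u`` record. Output is sorted by (namespace,
        alias); an explicit empty filter yields an empty list.
        """
        seq_id = self._resolve(identifier)
        curies = {
            Curie(r.namespace, r.alias)
            for r in self._aliases.find_aliases(seq_id=seq_id, current_only=True)
        }
        curies |= {
            Curie("ga4gh", f"SQ.{c.reference}")
            for c in curies
            if c.prefix == "sha512t24u"
        }
        if target_namespaces is not None:
            wanted = {normalize_namespace(ns) for ns in target_namespaces}
            curies = {c for c in curies if c.prefix in wanted}
        return sorted(curies)

    # -- inventory -----------------------------------------------------

    def list_ids(self) -> Iterator[str]:
        """Iterate every internal sequence id exactly once."""
        return self._fastadir.keys()

    def stats(self) -> RepoStats:
        return RepoStats(
            n_sequences=len(self._fastadir),
            n_aliases=self._aliases.n_records(current_only=True),
            total_residues=self._fastadir.total_residues(),
        )

    # -- snapshots -----------------------------------------------------

    def snapshot(self, dest_path: str | os.PathLike) -> SnapshotReport:
        """Create a read-only snapshot at ``dest_path`` using hard links.

        Finalized volumes and their indexes are hard-linked (no sequence
        data is copied); only the two small database files are copied.
        Snapshots taken after incremental loads therefore consume disk
        space only for content added since the previous snapshot.
        """
        dest = Path(dest_path)
        if dest.exists() and any(dest.iterdir()):
            raise FileExistsError(f"snapshot destination {dest} is not empty")
        if self.writeable:
            self._fastadir.commit()
        src_seq = self.root / "sequences"
        dst_seq = dest / "sequences"
        n_linked = 0
        try:
            for vol in self._fastadir.volumes():
                if not vol.finalized:
                    continue
                for suffix in ("", ".fai", ".gzi"):
                    src = src_seq / (vol.relpath + suffix)
                    dst = dst_seq / (vol.relpath + suffix)
                    dst.parent.mkdir(parents=True, exist_ok=True)
                    os.link(src, dst)
                    n_linked += 1
        except OSError as exc:
            if exc.errno == errno.EXDEV:
                shutil.rmtree(dest, ignore_errors=True)
                raise CrossDeviceError(
                    f"{dest} is on a different filesystem than {self.root}; "
                    "hard links cannot cross devices — choose a destination on "
                    "the same device or copy the repository instead"
                ) from exc
            raise
        dst_seq.mkdir(parents=True, exist_ok=True)
        (dest / "aliases").mkdir(parents=True, exist_ok=True)
        n_copied = 0
        for rel in ("sequences/db", "aliases/db"):
            self._copy_db(self.root / rel, dest / rel)
            n_copied += 1
        (dest / SNAPSHOT_MARKER).write_text("read-only snapshot\n")
        return SnapshotReport(str(dest), n_linked, n_copied)

    @staticmethod
    def _copy_db(src: Path, dst: Path) -> None:
        # sqlite backup API: consistent even if a reader holds the source
        s = sqlite3.connect(f"file:{src}?mode=ro", uri=True)
        d = sqlite3.connect(dst)
        try:
            s.backup(d)
        finally:
            s.close()
            d.close()

    # -- lifecycle -----------------------------------------------------

    def close(self) -> None:
        self._fastadir.close()
        self._aliases.close()

    def __enter__(self) -> "SeqVault":
        return self

    def __exit__(self, *exc) -> None:
        if self.writeable and exc[0] is None:
            self.commit()
        self.close()

    def __iter__(self) -> Iterator[str]:
        return self.list_ids()

    def __len__(self) -> int:
        return len(self._fastadir)
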