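"""Non-redundant, append-only sequence storage in BGZF FASTA volumes.

Layout under the repository root::

    <root>/sequences/db                    sqlite manifest (records + volumes)
    <root>/sequences/YYYY/MMDD/HHMMSS.fa.bgz       one volume per write session
    <root>/sequences/YYYY/MMDD/HHMMSS.fa.bgz.fai   faidx index
    <root>/sequences/YYYY/MMDD/HHMMSS.fa.bgz.gzi   BGZF virtual-offset index

Sequences are keyed by their sha512t24u digest, which is also the FASTA
record id inside the volume. Volumes are immutable once finalized:
``store`` buffers new sequences in the open session and ``commit`` writes
them as a single BGZF-compressed, faidx-indexed FASTA file with a
timestamped name. Random access to slices goes through pysam's
``FastaFile`` (faidx + BGZF virtual offsets), so fetching a slice never
decompresses the whole sequence.

Concurrency contract: exactly one writer at a time (enforced with a
held RESERVED lock on the manifest db), any number of readers; readers
only ever observe finalized volumes plus fully committed manifest rows.
"""

from __future__ import annotations

import datetime
import os
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pysam

from .digests import normalize_sequence, sha512t24u
from .exceptions import (
    NotFoundError,
    RangeError,
    ReadOnlyError,
    WriterLockError,
)

__all__ = ["FastaDir", "SequenceRecord", "VolumeEntry", "LINE_WIDTH"]

#: Fixed FASTA line width inside volumes; constant line length is what
#: makes faidx offset arithmetic valid.
LINE_WIDTH = 100

_SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS seqinfo (
    seq_id  TEXT PRIMARY KEY,
    len     INTEGER NOT NULL CHECK (len >= 1),
    alpha   TEXT NOT NULL,
    added   TEXT NOT NULL,
    relpath TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS volume (
    relpath   TEXT PRIMARY KEY,
    created   TEXT NOT NULL,
    finalized INTEGER NOT NULL DEFAULT 0
);
"""


def utc_now_iso() -> str:
    """UTC timestamp, ISO-8601, second precision."""
    return datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    len: int
    alpha: str  # sorted distinct residue characters observed
    added: str  # UTC ISO-8601
    relpath: str  # volume path relative to <root>/sequences


@dataclass(frozen=True)
class VolumeEntry:
    relpath: str
    created: str
    finalized: bool


class FastaDir:
    """Content-addressed FASTA storage under ``<root>/sequences``."""

    def __init__(self, root: str | os.PathLike, writeable: bool = False):
        self.root = Path(root)
        self._dir = self.root / "sequences"
        self.writeable = writeable
        db_path = self._dir / "db"
        if writeable:
            self._dir.mkdir(parents=True, exist_ok=True)
            # check_same_thread off: the HTTP layer serves reads from a
            # worker thread; wsgiref is single-threaded so no races
            self._db = sqlite3.connect(db_path, timeout=0.2, check_same_thread=False)
            self._db.executescript(_SCHEMA)
            self._db.execute(
                "INSERT OR IGNORE INTO meta (key, value) VALUES ('schema_version', ?)",
                (str(_SCHEMA_VERSION),),
            )
            self._db.commit()
        else:
            if not db_path.exists():
                raise NotFoundError(f"no repository at {self.root}")
            self._db = sqlite3.connect(
                f"file:{db_path}?mode=ro", uri=True, timeout=0.2,
                check_same_thread=False,
            )
        # pending, not-yet-finalized sequences of the open write session
        self._pending: dict[str, str] = {}
        self._pending_volume: str | None = None
        self._fasta_handles: dict[str, pysam.FastaFile] = {}
        self._in_txn = False

    # -- write path ---------------------------------------------------

    def store(self, seq: str) -> tuple[str, bool]:
        """Store ``seq`` if new; return ``(seq_id, created)``.

        Idempotent: re-storing known content writes nothing.
        """
        if not self.writeable:
            raise ReadOnlyError("store() on a read-only instance")
        norm = normalize_sequence(seq)
        seq_id = sha512t24u(norm.encode("ascii"))
        if seq_id in self._pending or self._seqinfo_row(seq_id) is not None:
            return seq_id, False
        self._begin_write()
        if self._pending_volume is None:
            self._pending_volume = self._new_volume_name()
        self._pending[seq_id] = norm
        self._db.execute(
            "INSERT INTO seqinfo (seq_id, len, alpha, added, relpath) VALUES (?,?,?,?,?)",
            (seq_id, len(norm), "".join(sorted(set(norm))), utc_now_iso(), self._pending_volume),
        )
        return seq_id, True

    def commit(self) -> None:
        """Finalize the open volume; no-op when nothing is pending.

        Writes the pending sequences as one BGZF FASTA volume, builds its
        faidx/gzi indexes, and commits the manifest rows atomically with
        the volume registration. Subsequent stores open a new volume.
        """
        if not self.writeable:
            raise ReadOnlyError("commit() on a read-only instance")
        if not self._pending:
            return
        relpath = self._pending_volume
        assert relpath is not None
        final = self._dir / relpath
        final.parent.mkdir(parents=True, exist_ok=True)
        tmp = final.with_suffix(".tmp")  # plain FASTA staging file
        with open(tmp, "w") as fh:
            for seq_id, seq in self._pending.items():
                fh.write(f">{seq_id}\n")
                for i in range(0, len(seq), LINE_WIDTH):
                    fh.write(seq[i : i + LINE_WIDTH])
                    fh.write("\n")
        pysam.tabix_compress(str(tmp), str(final), force=True)
        os.unlink(tmp)
        pysam.faidx(str(final))  # writes .fai and .gzi
        self._db.execute(
            "INSERT INTO volume (relpath, created, finalized) VALUES (?, ?, 1)",
            (relpath, utc_now_iso()),
        )
        self._db.commit()
        self._in_txn = False
        self._pending.clear()
        self._pending_volume = None

    def _begin_write(self) -> None:
        # Holding RESERVED between first store and commit keeps the
        # single-writer contract without blocking readers.
        if self._in_txn:
            return
        try:
            self._db.execute("BEGIN IMMEDIATE")
        except sqlite3.OperationalError as exc:
            raise WriterLockError(
                f"another writer holds the repository at {self.root}"
            ) from exc
        self._in_txn = True

    def _new_volume_name(self) -> str:
        now = datetime.datetime.now(datetime.timezone.utc)
        base = now.strftime("%Y/%m%d/%H%M%S")
        existing = {r[0] for r in self._db.execute("SELECT relpath FROM volume")}
        name = f"{base}.fa.bgz"
        i = 0
        while name in existing or (self._dir / name).exists():
            i += 1
            name = f"{base}.{i}.fa.bgz"
        return name

    # -- read path ----------------------------------------------------

    def _seqinfo_row(self, seq_id: str):
        cur = self._db.execute(
            "SELECT seq_id, len, alpha, added, relpath FROM seqinfo WHERE seq_id = ?",
            (seq_id,),
        )
        return cur.fetchone()

    def info(self, seq_id: str) -> SequenceRecord:
        row = self._seqinfo_row(seq_id)
        if row is None:
            raise NotFoundError(f"unknown sequence id: {seq_id}")
        return SequenceRecord(*row)

    def __contains__(self, seq_id: str) -> bool:
        return self._seqinfo_row(seq_id) is not None

    def __len__(self) -> int:
        return self._db.execute("SELECT COUNT(*) FROM seqinfo").fetchone()[0]

    def total_residues(self) -> int:
        return self._db.execute("SELECT COALESCE(SUM(len), 0) FROM seqinfo").fetchone()[0]

    def keys(self) -> Iterator[str]:
        for (seq_id,) in self._db.execute("SELECT seq_id FROM seqinfo ORDER BY seq_id"):
            yield seq_id

    def volumes(self) -> list[VolumeEntry]:
        return [
            VolumeEntry(r, c, bool(f))
            for r, c, f in self._db.execute(
                "SELECT relpath, created, finalized FROM volume ORDER BY rowid"
            )
        ]

    def fetch(self, seq_id: str, start: int | None = None, end: int | None = None) -> str:
        """Return the subsequence ``[start, end)`` of a stored sequence.

        Defaults cover the whole sequence. Slices of finalized volumes
        are read through the BGZF/faidx indexes without loading the full
        record.
        """
        row = self._seqinfo_row(seq_id)
        if row is None:
            raise NotFoundError(f"unknown sequence id: {seq_id}")
        seq_len, relpath = row[1], row[4]
        if start is None:
            start = 0
        if end is None:
            end = seq_len
        if start < 0 or end < 0:
            raise RangeError("start and end must be non-negative")
        if start > end:
            raise RangeError(f"start ({start}) > end ({end})")
        if end > seq_len:
            raise RangeError(f"end ({end}) beyond sequence length ({seq_len})")
        if seq_id in self._pending:
            return self._pending[seq_id][start:end]
        if start == end:
            return ""
        return self._open_volume(relpath).fetch(reference=seq_id, start=start, end=end)

    def _open_volume(self, relpath: str) -> pysam.FastaFile:
        fh = self._fasta_handles.get(relpath)
        if fh is None:
            fh = pysam.FastaFile(str(self._dir / relpath))
            self._fasta_handles[relpath] = fh
        return fh

    # -- lifecycle ----------------------------------------------------

    def close(self) -> None:
        for fh in self._fasta_handles.values():
            fh.close()
        self._fasta_handles.clear()
        self._db.close()

    def __enter__(self) -> "FastaDir":
        return self

    def __exit__(self, *exc) -> None:
        if self.writeable and self._pending and exc[0] is None:
            self.commit()
        self.close()
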