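"""Seeded synthetic FASTA generation.

Every test and example in this package runs on synthetic sequences so
that nothing is downloaded. Generation is a pure function of a
:class:`SyntheticSpec`: the same spec (including seed) yields
byte-identical FASTA on every platform. The PRNG is Python's Mersenne
Twister (``random.Random``), whose output for a given seed is fixed by
the language specification.

The generator emulates only what the storage layer cares about:
record identity, sequence content over a chosen alphabet, duplicated
content under distinct ids (to exercise deduplication), the same id
carried by two namespaces (to exercise bare-alias ambiguity), and pairs
of files that reuse ids with divergent sequences (to exercise alias
deprecation). It makes no attempt at realistic genome composition — no
GC skew, repeats, or length distributions beyond uniform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "SyntheticSpec",
    "FastaRecord",
    "ConflictSet",
    "generate_records",
    "generate_fasta",
    "write_fasta",
    "generate_conflict_set",
    "DNA",
    "PROTEIN",
]

DNA = "ACGT"
PROTEIN = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str
    #: additional namespaced identifiers (used when cross_namespace is set)
    extra_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic FASTA file.

    ``duplicate_fraction`` of the records (rounded down, never the
    first) repeat the sequence of an earlier record under a new id, so a
    loader that deduplicates correctly stores
    ``n_records - n_duplicates`` distinct sequences.
    """

    n_records: int = 10
    length_range: tuple[int, int] = (50, 200)
    alphabet: str = DNA
    seed: int = 0
    duplicate_fraction: float = 0.0
    cross_namespace: bool = False

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")

    @property
    def n_duplicates(self) -> int:
        return min(int(self.duplicate_fraction * self.n_records), self.n_records - 1)


def _random_seq(rng: random.Random, spec: SyntheticSpec) -> str:
    length = rng.randint(*spec.length_range)
    return "".join(rng.choices(spec.alphabet, k=length))


def generate_records(spec: SyntheticSpec) -> list[FastaRecord]:
    """Deterministically generate the records described by ``spec``."""
    rng = random.Random(spec.seed)
    n_dup = spec.n_duplicates
    # duplicate slots: chosen among indexes 1..n-1, reproducibly
    dup_slots = set(rng.sample(range(1, spec.n_records), n_dup)) if n_dup else set()
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for i in range(spec.n_records):
        rid = f"SYN{spec.seed:04d}.{i:05d}"
        if i in dup_slots:
            seq = rng.choice([r.seq for j, r in enumerate(records) if j not in dup_slots])
        else:
            seq = _random_seq(rng, spec)
            # distinct base sequences make the dedup arithmetic exact;
            # infeasible only for tiny alphabet^length spaces
            for _ in range(1000):
                if seq not in seen:
                    break
                seq = _random_seq(rng, spec)
            else:
                raise ValueError(
                    "cannot generate distinct sequences; enlarge length_range or alphabet"
                )
            seen.add(seq)
        extra = (f"alt:{rid}",) if spec.cross_namespace else ()
        records.append(FastaRecord(rid, seq, extra))
    return records


def _format_fasta(records: Iterable[FastaRecord], width: int = 70) -> str:
    out: list[str] = []
    for rec in records:
        out.append(f">{rec.id}\n")
        for i in range(0, len(rec.seq), width):
            out.append(rec.seq[i : i + width] + "\n")
    return "".join(out)


def generate_fasta(spec: SyntheticSpec) -> str:
    """FASTA text for ``spec`` (byte-identical for identical specs)."""
    return _format_fasta(generate_records(spec))


def write_fasta(spec: SyntheticSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(generate_fasta(spec))
    return path


@dataclass(frozen=True)
class ConflictSet:
    """Two FASTA files sharing ids but with divergent sequences.

    Loading ``fasta_a`` then ``fasta_b`` into the same namespace must
    deprecate exactly ``len(shared_ids)`` alias records.
    """

    fasta_a: str
    fasta_b: str
    shared_ids: tuple[str, ...]
    only_a_ids: tuple[str, ...]
    only_b_ids: tuple[str, ...]


def generate_conflict_set(
    seed: int,
    n_shared: int = 3,
    n_private: int = 2,
    length_range: tuple[int, int] = (60, 120),
    alphabet: str = DNA,
) -> ConflictSet:
    """Build the alias-deprecation fixture.

    Both files contain ``n_shared`` records under the same ids but with
    different sequences, plus ``n_private`` records each under ids of
    their own.
    """
    rng = random.Random(seed)
    spec = SyntheticSpec(
        n_records=1, length_range=length_range, alphabet=alphabet, seed=seed
    )
    seqs: set[str] = set()

    def fresh_seq() -> str:
        while True:
            s = _random_seq(rng, spec)
            if s not in seqs:
                seqs.add(s)
                return s

    shared = tuple(f"CONF{seed:04d}.S{i}" for i in range(n_shared))
    only_a = tuple(f"CONF{seed:04d}.A{i}" for i in range(n_private))
    only_b = tuple(f"CONF{seed:04d}.B{i}" for i in range(n_private))
    recs_a = [FastaRecord(rid, fresh_seq()) for rid in shared + only_a]
    recs_b = [FastaRecord(rid, fresh_seq()) for rid in shared + only_b]
    return ConflictSet(
        fasta_a=_format_fasta(recs_a),
        fasta_b=_format_fasta(recs_b),
        shared_ids=shared,
        only_a_ids=only_a,
        only_b_ids=only_b,
    )
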