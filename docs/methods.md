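# Methods

## The digest convention

The internal key of a sequence is **sha512t24u**: SHA-512 of the
normalized sequence bytes, truncated to the first 24 bytes (192 bits),
encoded with unpadded URL-safe base64 (32 characters, alphabet
`A–Z a–z 0–9 - _`). Two properties matter:

- *Prefix truncation.* The 24-byte raw digest is a prefix of the full
  64-byte SHA-512 output computed with the standard SHA-512
  initialization vector — deliberately not the SHA-512/t variants,
  whose distinct IVs would break the prefix relationship. Identifiers
  of different lengths over the same data therefore agree on their
  common prefix.
- *Truncation length.* base64 emits 4 output characters per 3 input
  bytes, so truncation lengths that are multiples of 3 avoid padding.
  Under the birthday bound `P ≈ 1 − exp(−n(n−1)/2^(b+1))`, 24 bytes
  (b = 192) keeps the collision probability of even a 10^18-sequence
  corpus below 10⁻²¹, while 32 characters stay short enough for URLs,
  FASTA deflines, and filenames.

`collision_probability(n, bits)` evaluates the exact birthday product
`1 − ∏ₖ(1 − k/2^b)` for n ≤ 2^20 and the Poisson approximation above
otherwise, computed in log space (`log`, `expm1`) so the result remains
finite and non-zero where representable for extreme arguments such as
n = 10^18, b = 192. The exact branch is what makes tiny cases like
(n=2, b=1) → 0.5 come out exactly; the approximation branch is monotone
in both arguments by construction.

Alongside sha512t24u, each sequence receives the conventional computed
identifiers: MD5 and SHA-1 as lowercase hex, and SEGUID (unpadded
*standard* base64 of SHA-1 of the uppercased sequence — it may contain
`+` and `/`, which is exactly why it cannot be embedded in URLs and why
a URL-safe successor was needed).

**Normalization.** Sequences are uppercased and validated as non-empty
printable ASCII at a single point before hashing and storage, so
`"acgt"` and `"ACGT"` deduplicate to one record. This is a declared
convention of this package: digest identity should not depend on FASTA
case styling, and SEGUID already requires uppercasing. Users who need
case-sensitive storage (e.g. soft-masked genomes) must encode masking
elsewhere.

## Storage model

- **Volumes.** Each write session's new sequences are appended to one
  BGZF-compressed FASTA volume named by its UTC creation time,
  `YYYY/MMDD/HHMMSS.fa.bgz` (numeric suffix on same-second collisions),
  with the sha512t24u digest as the FASTA id and a fixed 100-character
  line width (constant line length is what makes faidx offset
  arithmetic valid). `commit()` finalizes the volume, builds the `.fai`
  and `.gzi` indexes (via pysam/htslib), and atomically commits the
  manifest rows. Finalized volumes are immutable: no later operation
  rewrites or deletes their bytes, which the immutability tests verify
  by checksumming volumes across subsequent operations.
- **Pending reads.** Within a write session, sequences stored but not
  yet committed are served from memory; durability begins at
  `commit()`. A session's working set must therefore fit in memory —
  acceptable for the load sizes this package targets, and bounded by
  committing between files.
- **Manifest.** A single-file SQLite database per instance
  (`<root>/sequences/db`) stores per-sequence length, alphabet (the
  sorted set of residue characters actually observed), UTC timestamp,
  and volume path, plus the volume registry and a schema version.
- **Concurrency.** Exactly one writer at a time — enforced by holding a
  RESERVED SQLite lock between the first uncommitted store and
  `commit()`, so a second writer fails fast with `WriterLockError` —
  and any number of readers, which only ever observe finalized volumes
  plus committed manifest rows.
- **Coordinates.** 0-based, half-open everywhere (Python slices, REST
  and refget `start`/`end` query parameters). `start == end` is the
  empty string; `start > end` and `end > length` are distinct range
  errors, separate from not-found.

## Alias model

`<namespace, alias> → seq_id` associations are timestamped rows in
`<root>/aliases/db`. At most one row per pair is *current*; storing a
pair that exists with a different seq_id marks the old row
`is_current = 0` and inserts a new current row — records are never
deleted or resurrected (append-only history; a pair re-asserted with
its original sequence after deprecation gets a fresh row). Computed
namespaces (MD5, SEGUID, SHA1, sha512t24u) are pure functions of the
sequence, so an attempt to re-point one is rejected as corruption
rather than deprecated.

Namespace spellings follow identifiers.org prefixes where available; a
small documented table maps common capitalizations (`RefSeq`→`refseq`,
`Ensembl`→`ensembl`). Alias matching is otherwise case-sensitive and
byte-exact — no version stripping. Bare (namespace-less) lookup
succeeds only when the alias resolves to a single sequence across all
namespaces; otherwise it raises an ambiguity error naming the candidate
namespaces, an explicit choice over any priority ordering. The `ga4gh`
prefix is a presentation of the internal digest: `ga4gh:SQ.<digest>`
and `sha512t24u:<digest>` resolve identically, translation emits both
spellings, and only the `sha512t24u` row is stored (hence “4 computed +
k supplied” alias counts from `store`).

## Snapshots

`snapshot(dest)` hard-links every finalized volume and its two index
files into an empty destination on the same filesystem (cross-device
destinations fail with an explicit error suggesting a copy) and copies
the two SQLite files with the backup API — they are the only mutable
artifacts. Because volumes are immutable and shared by inode,
successive snapshots cost only the space of content added in between.
A `.snapshot` marker makes the destination permanently read-only:
opening it writeable, or calling `store` on it, raises `ReadOnlyError`,
while all reads serve byte-identical content.

## HTTP surfaces

One stdlib WSGI application serves both interfaces from one repository
instance, so their bodies are byte-identical by construction; it is
strictly read-only (anything but GET → 405) and streams sequence bodies
in 64 KiB chunks fetched slice-by-slice, keeping peak memory
independent of slice length.

- Native: `/v1/ping`, `/v1/sequence/{identifier}?start&end`
  (text/plain), `/v1/metadata/{identifier}`. Errors: 400 malformed
  parameters, 404 unknown identifier, 422 bad range or ambiguous bare
  alias (candidates listed in the body).
- refget-style: `/sequence/service-info`, `/sequence/{digest}?start&end`
  (`text/vnd.ga4gh.refget…+plain`), `/sequence/{digest}/metadata`.
  Queries are digest-only (namespaced identifiers are 404); both
  base64url and 48-hex (`trunc512`) spellings of the truncated SHA-512
  are accepted, as are `SQ.`-prefixed forms and MD5 hex, covering both
  protocol generations' digest naming. Errors follow refget
  conventions: 416 for out-of-bounds ranges, 501 for `start > end`
  (circular semantics — circular sequences are not supported anywhere
  in this package; they can only be stored linearized). Range *headers*
  are not implemented — query parameters only — a documented deviation
  from full refget compliance.

## Synthetic data

All tests and the acceptance script run on seeded synthetic FASTA from
`seqvault.fixtures`, generated with Python's Mersenne Twister so a spec
(seed included) yields byte-identical output on any platform. The
generator emulates exactly the features the storage layer is sensitive
to: distinct records over a chosen alphabet with uniform lengths, a
`duplicate_fraction` of records repeating earlier content under new ids
(dedup arithmetic becomes exact: distinct = n − duplicates), and
conflict pairs of files that reuse ids with divergent sequences (alias
deprecation). It does not emulate genome composition — no GC skew,
repeat structure, masking, N-runs, or realistic length distributions —
so passing tests demonstrate correctness of storage, addressing, and
serving, not robustness to every real-world FASTA quirk (though any
printable-ASCII sequence is accepted).

## Problem sizes and numerical choices

- Digest oracle comparisons: frozen vectors plus 100–200 seeded random
  byte-strings per check; 10^4 distinct random inputs for the
  no-collision property.
- Storage round trip: 200 seeded sequences with lengths 1–10^5 (edge
  cases at the 100-character line width included); slice consistency:
  1,000 random (start, end) pairs against in-memory slicing.
- Dedup/immutability: one 1,000-record FASTA (lengths 20–150, 10%
  duplicates) loaded twice.
- Four-way interface equivalence: 20 sequences of 100–5,000 residues,
  1,000 random slice triples, compared byte-for-byte across the Python
  call, dict-style access, and both HTTP endpoints of a live local
  server.
- The micro-benchmark (median wall time of 200–500 warm 1–30-residue
  fetches, asserted < 10 ms) is informational: it guards the BGZF
  random-access path against gross regressions, not a throughput claim.
  Remote-vs-local throughput comparisons are inherently
  hardware/network-bound and are out of scope.

## Known limitations

- Circular sequences are unsupported (store linearized forms).
- One volume per write session; no size-based rollover.
- Within-session working set is held in memory until `commit()`.
- No authentication, TLS, caching layers, or alternative storage
  backends; no rsync mirroring orchestration.
- Bare-alias lookup is exact-match only; versionless accession lookup
  is out of scope.
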