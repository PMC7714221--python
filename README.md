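# seqvault

A local, non-redundant, content-addressed repository of biological
sequences — genome, transcript, or protein, any species — for
bioinformatics pipelines that need fast, private, reproducible random
access to sequence slices without round trips to NCBI/Ensembl-style
network services.

## How it works

**Content addressing.** Every sequence is keyed by its *sha512t24u*
digest: the SHA-512 digest of the uppercased ASCII sequence, truncated
to its first 24 bytes (192 bits) and encoded with unpadded URL-safe
base64 — a fixed 32-character identifier usable directly in URLs and
filenames. The truncation is a plain prefix of standard SHA-512 (the
standard initialization vector, not SHA-512/t), so identifiers can be
abbreviated or extended without re-hashing. By the birthday bound
`P ≈ 1 − exp(−n(n−1)/2^(b+1))`, a corpus of 10^18 sequences collides
with probability below 10⁻²¹ at b = 192 bits. Identical sequences —
regardless of FASTA case or which database they came from — are stored
exactly once.

**Storage.** Sequences live in immutable, timestamped BGZF-compressed
FASTA volumes under `<root>/sequences/`, indexed with faidx/gzi so a
slice of a chromosome-sized record is read via BGZF virtual offsets
without decompressing the rest. A SQLite manifest records length,
alphabet, timestamp, and volume path per sequence. Finalized volumes
are never rewritten, which makes snapshots trivially incremental:
`snapshot` hard-links all volumes (no data copied) and copies only the
two small database files.

**Identifiers.** A second SQLite database stores timestamped
`<namespace, alias>` pairs (as W3C CURIEs, `prefix:reference`) mapping
public identifiers — `refseq:NM_000551.3`, `ensembl:ENST00000256474` —
and the computed digests (MD5, SHA-1, SEGUID, sha512t24u, with
`ga4gh:SQ.<digest>` as an equivalent spelling) onto stored sequences.
Aliases are unique within a namespace at any point in time; re-asserting
an alias with different content deprecates the old association but keeps
it, so the naming history of every sequence is queryable.

**Access surfaces.** The native Python API (`fetch`, dict-style
slicing, `translate_identifier`), a read-only REST interface
(`/v1/sequence/{id}`, `/v1/metadata/{id}`, `/v1/ping`), a refget-style
digest-addressed interface (`/sequence/{digest}`), and the `seqvault`
command line (`init`, `load`, `export`, `status`, `snapshot`, `serve`,
`fixtures`).

## Worked example

```python
>>> from seqvault import SeqVault, sha512t24u
>>> repo = SeqVault("myrepo", writeable=True)
>>> repo.store("ACGTACGT", ["refseq:TEST0"])
(1, 5)                          # 1 new sequence, 4 computed + 1 supplied alias
>>> repo.store("acgtacgt", ["ensembl:DEMO1"])
(0, 1)                          # same content: deduplicated, one new alias
>>> repo.commit()               # finalize the BGZF volume
>>> repo.fetch("refseq:TEST0", 2, 4)
'GT'
>>> repo["ensembl:DEMO1"][2:4]  # dict-style access, same bytes
'GT'
>>> sha512t24u(b"ACGTACGT")
'mZaH9yJZKglZq7R1h5zLOyAGTQrXu72F'
>>> [str(c) for c in repo.translate_identifier("refseq:TEST0", ["ga4gh"])]
['ga4gh:SQ.mZaH9yJZKglZq7R1h5zLOyAGTQrXu72F']
>>> repo.fetch("ga4gh:SQ.mZaH9yJZKglZq7R1h5zLOyAGTQrXu72F")
'ACGTACGT'
```

The store counts say a new sequence was written once and addressed five
ways; the digest CURIE resolves to the same bytes as the conventional
identifiers, which is what lets pipelines translate between public
accessions and digest identifiers in either direction.

From the shell:

```sh
seqvault fixtures fasta --n-records 3 --seed 1 -o demo.fa
seqvault -r myrepo init
seqvault -r myrepo load -n test demo.fa
# loaded 1 file(s): 3 sequences seen, 3 sequences added, 15 aliases added
seqvault -r myrepo snapshot /path/on/same/fs/snap   # hard-linked, read-only
seqvault -r myrepo serve --port 5000
curl 'http://127.0.0.1:5000/v1/sequence/test:SYN0001.00000?start=0&end=10'
```

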