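"""Sequence digests and computed identifiers.

The internal key of the repository is *sha512t24u*: the SHA-512 digest of
the (normalized) sequence, truncated to its first 24 bytes (192 bits) and
encoded with unpadded URL-safe base64, giving a fixed 32-character
identifier that is safe to embed in URLs and filenames. The truncation is
a plain prefix of the standard SHA-512 output (standard initialization
vector, not the SHA-512/t variants), so longer digests of the same data
share the 24-byte prefix and identifiers can be abbreviated or extended
without re-hashing.

Alongside sha512t24u, each stored sequence receives the conventional
computed identifiers used by public sequence databases: MD5 and SHA-1 as
lowercase hex, and SEGUID (base64-encoded SHA-1 of the uppercased
sequence, padding stripped — note SEGUID may contain ``+`` and ``/``,
which is precisely why it is unsuitable for URLs).

Normalization convention: sequences are uppercased and ASCII-encoded
before hashing (and before storage), so ``"acgt"`` and ``"ACGT"``
deduplicate to a single record. IUPAC alphabets are ASCII; non-ASCII
input is rejected.
"""

from __future__ import annotations

import base64
import hashlib
import math

import numpy as np

__all__ = [
    "sha512t24u",
    "seguid",
    "normalize_sequence",
    "compute_identifiers",
    "collision_probability",
    "COMPUTED_NAMESPACES",
]

#: Namespaces whose alias value is a pure function of the sequence.
COMPUTED_NAMESPACES = ("MD5", "SEGUID", "SHA1", "sha512t24u")

#: Truncation length in bytes (192 bits); base64 needs len % 3 == 0 to
#: avoid padding, and 24 bytes -> exactly 32 encoded characters.
TRUNCATION_BYTES = 24

# Exact birthday-product evaluation is used up to this many messages;
# beyond it the log-space Poisson approximation takes over.
_EXACT_LIMIT = 2**20


def sha512t24u(blob: bytes) -> str:
    """Return the 32-character URL-safe digest of ``blob``.

    Total on byte-strings (the empty string is a valid input). The raw
    digest is the first :data:`TRUNCATION_BYTES` bytes of SHA-512.
    """
    raw = hashlib.sha512(blob).digest()[:TRUNCATION_BYTES]
    return base64.urlsafe_b64encode(raw).decode("ascii")


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and validate it as non-empty printable ASCII.

    This is the single normalization point for both digest computation
    and storage, so identity is insensitive to FASTA case conventions.
    """
    if not isinstance(seq, str):
        raise TypeError("sequence must be a str")
    if not seq:
        raise ValueError("empty sequences are not storable")
    norm = seq.upper()
    try:
        norm.encode("ascii")
    except UnicodeEncodeError as exc:
        raise ValueError("sequence must be ASCII") from exc
    if any(c.isspace() or not c.isprintable() for c in norm):
        raise ValueError("sequence must not contain whitespace or control characters")
    return norm


def seguid(seq: str) -> str:
    """SEGUID of ``seq``: unpadded standard base64 of SHA-1(uppercase(seq))."""
    norm = normalize_sequence(seq)
    b64 = base64.b64encode(hashlib.sha1(norm.encode("ascii")).digest())
    return b64.decode("ascii").rstrip("=")


def compute_identifiers(seq: str) -> dict[str, str]:
    """All computed <namespace, alias> identifiers of a sequence.

    Returns exactly four pairs: MD5 and SHA1 (lowercase hex), SEGUID,
    and sha512t24u, keyed by namespace. Deterministic in ``seq`` after
    normalization.
    """
    data = normalize_sequence(seq).encode("ascii")
    return {
        "MD5": hashlib.md5(data).hexdigest(),
        "SEGUID": base64.b64encode(hashlib.sha1(data).digest()).decode("ascii").rstrip("="),
        "SHA1": hashlib.sha1(data).hexdigest(),
        "sha512t24u": sha512t24u(data),
    }


def collision_probability(n_messages: float, digest_bits: int) -> float:
    """Probability that ``n_messages`` random digests of ``digest_bits``
    bits contain at least one collision (birthday bound).

    For small corpora the exact product ``1 - prod_k (1 - k/2^b)`` is
    evaluated; for large ``n`` the Poisson approximation
    ``1 - exp(-n(n-1)/2^(b+1))`` is computed in log space, so the result
    stays finite (and nonzero where representable) even for
    ``n = 1e18, digest_bits = 192``. Monotone increasing in ``n_messages``
    and decreasing in ``digest_bits``.
    """
    if n_messages < 1:
        raise ValueError("n_messages must be >= 1")
    if digest_bits < 1:
        raise ValueError("digest_bits must be >= 1")
    if n_messages < 2:
        return 0.0
    # Pigeonhole: more messages than digest values forces a collision.
    if digest_bits <= 64 and n_messages > 2**digest_bits:
        return 1.0
    if n_messages <= _EXACT_LIMIT and float(n_messages).is_integer():
        k = np.arange(1, int(n_messages), dtype=np.float64)
        log_surv = np.sum(np.log1p(-k * 2.0 ** -digest_bits))
        if not np.isfinite(log_surv):
            return 1.0
        return float(-np.expm1(log_surv))
    n = float(n_messages)
    log_lam = math.log(n) + math.log(n - 1.0) - (digest_bits + 1) * math.log(2.0)
    if log_lam > 50.0:  # exp(-lam) underflows; probability is 1 to machine precision
        return 1.0
    return -math.expm1(-math.exp(log_lam))
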