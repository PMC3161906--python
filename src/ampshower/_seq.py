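"""Low-level DNA helpers shared across modules.

Sequences are held as ``bytearray`` of ASCII upper-case bases internally
(mutable, cheap to slice) and exposed as ``str`` at module boundaries.
All coordinates are 0-based half-open; replicons are circular, so index
arithmetic wraps modulo the replicon length.
"""

from __future__ import annotations

import hashlib

import numpy as np

BASES = b"ACGT"

_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def comp_base(b: int) -> int:
    """Complement of a single base given as an ASCII code."""
    return _COMP[b]


def revcomp(seq: str | bytes | bytearray) -> str | bytes | bytearray:
    """Reverse complement, preserving the input type."""
    if isinstance(seq, str):
        return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]
    out = bytes(seq).translate(_COMP)[::-1]
    return bytearray(out) if isinstance(seq, bytearray) else out


def random_dna(n: int, rng: np.random.Generator) -> bytearray:
    """i.i.d. uniform A/C/G/T sequence of length n."""
    idx = rng.integers(0, 4, size=n, dtype=np.uint8)
    return bytearray(np.frombuffer(BASES, dtype=np.uint8)[idx].tobytes())


def sha256_of(data: bytes | str) -> str:
    if isinstance(data, str):
        data = data.encode()
    return hashlib.sha256(data).hexdigest()
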