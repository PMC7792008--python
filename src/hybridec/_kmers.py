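"""2-bit k-mer arithmetic.

k-mers over {A,C,G,T} are packed into ``uint64`` values, two bits per base
(A=0, C=1, G=2, T=3), with the first base in the highest-order bit pair.
Every routine is vectorised over numpy arrays so that all windows of a read
can be encoded, canonicalised and looked up with a handful of array
operations.  k is limited to 31 so a k-mer always fits one word; the graph
layer additionally requires k odd so that no k-mer equals its own reverse
complement.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)

MAX_K = 31


def revcomp_str(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters beyond ACGT not supported)."""
    return seq.translate(_COMP_TABLE)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array; reject anything else."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        pos = int(np.argmax(codes > 3))
        raise ValueError(f"non-ACGT symbol {seq[pos]!r} at position {pos}")
    return codes


def split_acgt(seq: str):
    """Yield ``(offset, run)`` for each maximal run of A/C/G/T symbols in seq.

    Reads containing other symbols (N, IUPAC codes) are split at those
    symbols before k-merisation; the symbols themselves never enter a graph.
    """
    start = None
    for i, ch in enumerate(seq):
        if ch in "ACGTacgt":
            if start is None:
                start = i
        elif start is not None:
            yield start, seq[start:i]
            start = None
    if start is not None:
        yield start, seq[start:]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode a uint8/int code array back to an A/C/G/T string."""
    return _BASE_BYTES[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def kmer_mask(k: int) -> np.uint64:
    return np.uint64((1 << (2 * k)) - 1)


def windows_u64(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer windows of a code array as packed uint64 values."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    w = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for i in range(k):
        w = (w << two) | codes[i : i + n].astype(np.uint64)
    return w


def revcomp_u64(vals: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed k-mers."""
    x = ~np.asarray(vals, dtype=np.uint64)
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_u64(vals: np.ndarray, k: int):
    """Return ``(canonical values, forward mask)``.

    ``forward[i]`` is True when ``vals[i]`` is already canonical, i.e. it is
    lexicographically <= its reverse complement.
    """
    vals = np.asarray(vals, dtype=np.uint64)
    rc = revcomp_u64(vals, k)
    fwd = vals <= rc
    return np.where(fwd, vals, rc), fwd


def encode_u64(seq: str) -> int:
    """Pack a short A/C/G/T string (len <= 31) into an int."""
    v = 0
    for ch in seq:
        c = _CODE[ord(ch)]
        if c > 3:
            raise ValueError(f"non-ACGT symbol {ch!r}")
        v = (v << 2) | int(c)
    return v


def decode_u64(val: int, k: int) -> str:
    val = int(val)
    return "".join(BASES[(val >> (2 * (k - 1 - i))) & 3] for i in range(k))


def rc_int(val: int, k: int) -> int:
    """Scalar reverse complement on python ints (graph walks use this)."""
    x = ~val & 0xFFFFFFFFFFFFFFFF
    x = ((x & 0x3333333333333333) << 2) | ((x >> 2) & 0x3333333333333333)
    x = ((x & 0x0F0F0F0F0F0F0F0F) << 4) | ((x >> 4) & 0x0F0F0F0F0F0F0F0F)
    x = int.from_bytes(x.to_bytes(8, "little"), "big")
    return x >> (64 - 2 * k)


def canon_int(val: int, k: int) -> int:
    rc = rc_int(val, k)
    return val if val <= rc else rc
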