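"""Low-level DNA sequence utilities.

Sequences are plain Python strings over {A,C,G,T} at the API surface and
numpy uint8 code arrays (A=0, C=1, G=2, T=3) internally.  k-mers are packed
into uint64 integers (2 bits per base), which caps k at 31 -- enough for every
k used in this package.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A=0, C=1, G=2, T=3)."""
    a = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if a.size and a.max() > 3:
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[np.argmax(a > 3)])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return a


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed forward k-mer integers for every window of ``codes``.

    Returns an empty array when the sequence is shorter than k.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    out = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        out = (out << np.uint64(2)) | c[i : n - k + 1 + i]
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of forward and reverse-complement) packed k-mers."""
    fwd = kmer_codes(codes, k)
    rev = kmer_codes(revcomp_codes(codes), k)[::-1]
    return np.minimum(fwd, rev)


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k - 1, -1, -1):
        out.append(BASES[(code >> (2 * i)) & 3])
    return "".join(out)


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def min_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm, O(n))."""
    if not seq:
        return seq
    s = seq + seq
    n = len(s)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    k %= len(seq)
    return seq[k:] + seq[:k]


def normalize_rotation(seq: str) -> str:
    """Canonical representation of a circular sequence.

    The strand whose minimal rotation is lexicographically smaller is chosen,
    then the sequence is rotated to start at that minimal rotation.  Two
    circular sequences are equal as circles iff their normalizations are
    string-equal.
    """
    a = min_rotation(seq)
    b = min_rotation(revcomp(seq))
    return a if a <= b else b
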