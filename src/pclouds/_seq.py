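"""Low-level nucleotide encoding helpers.

Sequences are mapped onto 2-bit codes (A=0, C=1, G=2, T=3); any other
symbol — IUPAC ambiguity codes, gaps, N runs — receives the sentinel 4 and
invalidates every k-mer window that touches it.  Oligos short enough to fit
in 64 bits (k <= 32) are packed big-endian so that lexicographic order of
the string equals numeric order of the packed integer.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

_BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase (soft-masked) counts identically


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence string; non-ACGT symbols become 4."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_scan(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mers at every start position plus a validity mask.

    Returns ``(valid, kmers)`` of length ``len(codes) - k + 1``; ``kmers[i]``
    is meaningful only where ``valid[i]`` (windows containing a non-ACGT
    symbol are invalid and their packed value is garbage).
    """
    n = codes.size
    if n < k:
        return np.zeros(0, dtype=bool), np.zeros(0, dtype=np.uint64)
    m = n - k + 1
    km = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        km = (km << np.uint64(2)) | codes[j : j + m].astype(np.uint64)
    bad = np.concatenate(([0], np.cumsum(codes >= 4)))
    valid = (bad[k:] - bad[:-k]) == 0
    return valid, km


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_kmers(km: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of packed k-mers, vectorised."""
    km = km.astype(np.uint64, copy=True)
    out = np.zeros_like(km)
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        out = (out << two) | (three - (km & three))
        km >>= two
    return out


def encode_oligo(oligo: str) -> int:
    """Pack a single ACGT string into an integer."""
    v = 0
    for ch in oligo.upper():
        c = _BASES.find(ch)
        if c < 0:
            raise ValueError(f"non-ACGT symbol {ch!r} in oligo {oligo!r}")
        v = (v << 2) | c
    return v


def decode_kmer(value: int, k: int) -> str:
    return "".join(_BASES[(value >> (2 * (k - 1 - i))) & 3] for i in range(k))


def kmers_to_strings(km: np.ndarray, k: int) -> list[str]:
    """Decode an array of packed k-mers to python strings (vectorised)."""
    if km.size == 0:
        return []
    shifts = (2 * np.arange(k - 1, -1, -1)).astype(np.uint64)
    codes = ((km[:, None] >> shifts) & np.uint64(3)).astype(np.uint8)
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    return np.ascontiguousarray(chars).reshape(-1).view(f"S{k}").astype(str).tolist()


def oligos_to_kmers(oligos: Sequence[str], k: int) -> np.ndarray:
    """Pack a collection of equal-length ACGT strings (vectorised)."""
    if len(oligos) == 0:
        return np.zeros(0, dtype=np.uint64)
    raw = np.array(list(oligos), dtype=f"S{k}")
    codes = _LUT[raw.view(np.uint8).reshape(len(oligos), k)]
    if (codes >= 4).any():
        raise ValueError("non-ACGT symbol in oligo collection")
    km = np.zeros(len(oligos), dtype=np.uint64)
    for j in range(k):
        km = (km << np.uint64(2)) | codes[:, j].astype(np.uint64)
    return km


def as_records(seqs) -> list[tuple[str, str]]:
    """Normalise heterogeneous sequence input to ``[(id, sequence), ...]``.

    Accepts a bare string, an iterable of strings, ``(id, seq)`` pairs,
    Biopython ``SeqRecord`` objects, or a mapping id -> sequence.
    """
    if isinstance(seqs, str):
        return [("seq1", seqs)]
    if isinstance(seqs, dict):
        return [(str(k), str(v)) for k, v in seqs.items()]
    out: list[tuple[str, str]] = []
    for i, item in enumerate(seqs):
        if isinstance(item, str):
            out.append((f"seq{i + 1}", item))
        elif isinstance(item, tuple) and len(item) == 2:
            out.append((str(item[0]), str(item[1])))
        elif hasattr(item, "seq") and hasattr(item, "id"):
            out.append((str(item.id), str(item.seq)))
        else:
            raise TypeError(f"cannot interpret sequence item of type {type(item)!r}")
    return out
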