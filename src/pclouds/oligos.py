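"""Oligo counting, Hamming neighborhoods, and copy-number expectations.

The repeat-detection pipeline starts from a table of exact occurrence
counts of every length-k oligonucleotide in the scanned sequence set.
Counting is strand-asymmetric (oligos are counted as written); strand
symmetry is restored later, at cloud-membership lookup time, by querying
both an oligo and its reverse complement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import as_records, kmer_scan, encode, kmers_to_strings

log = logging.getLogger(__name__)

_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass
class OligoCountTable:
    """Occurrence counts of every distinct k-mer in a sequence set.

    ``total_positions`` is the number of countable window start positions
    (windows containing a non-ACGT symbol are skipped and not counted), so
    ``sum(counts.values()) == total_positions`` until the table is pruned.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    total_positions: int = 0

    def __getitem__(self, oligo: str) -> int:
        return self.counts.get(oligo, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def prune(self, min_count: int) -> int:
        """Drop oligos with count < ``min_count``; returns how many were removed.

        Useful to bound memory before cloud construction (a cutoff scheme
        with lower cutoff >= 2 never consults singletons).  Pruning breaks
        the sum-equals-total invariant by design; ``total_positions`` keeps
        the original value.
        """
        drop = [o for o, c in self.counts.items() if c < min_count]
        for o in drop:
            del self.counts[o]
        if drop:
            log.info("pruned %d oligos with count < %d", len(drop), min_count)
        return len(drop)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\ttotal_positions={self.total_positions}\n")
            for o in sorted(self.counts):
                fh.write(f"{o}\t{self.counts[o]}\n")

    @classmethod
    def from_tsv(cls, path) -> "OligoCountTable":
        counts: dict[str, int] = {}
        k = 0
        total = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "total_positions":
                            total = int(val)
                    continue
                o, c = line.split("\t")
                counts[o] = int(c)
        return cls(k=k, counts=counts, total_positions=total)


def count_oligos(seqs, k: int) -> OligoCountTable:
    """Count every window of k consecutive ACGT symbols, per record.

    Windows never cross record boundaries; any window containing a
    non-ACGT symbol (N, ambiguity codes, gaps) is skipped entirely.
    Counting is case-insensitive so soft-masked repeats are seen.
    """
    if k <= 0:
        raise ValueError(f"word length k must be >= 1, got {k}")
    chunks = []
    total = 0
    for _rid, seq in as_records(seqs):
        valid, km = kmer_scan(encode(seq), k)
        good = km[valid]
        total += good.size
        if good.size:
            chunks.append(good)
    if not chunks:
        return OligoCountTable(k=k, counts={}, total_positions=0)
    uniq, cnt = np.unique(np.concatenate(chunks), return_counts=True)
    counts = dict(zip(kmers_to_strings(uniq, k), cnt.tolist()))
    return OligoCountTable(k=k, counts=counts, total_positions=total)


def hamming_neighbors(oligo: str, d: int) -> set[str]:
    """All oligos at Hamming distance exactly ``d`` from ``oligo``.

    Substitution-only sequence space over {A,C,G,T}; the result has
    C(k,d) * 3^d elements.
    """
    if d < 0 or d > 3:
        raise ValueError(f"distance must be in 0..3, got {d}")
    oligo = oligo.upper()
    if any(ch not in _ALT for ch in oligo):
        raise ValueError(f"non-ACGT symbol in oligo {oligo!r}")
    if d == 0:
        return {oligo}
    out: set[str] = set()
    chars = list(oligo)
    for positions in itertools.combinations(range(len(chars)), d):
        for subs in itertools.product(*(_ALT[chars[p]] for p in positions)):
            w = chars.copy()
            for p, b in zip(positions, subs):
                w[p] = b
            out.add("".join(w))
    return out


def recommended_oligo_length(genome_size: float) -> int:
    """Smallest word length l such that a random oligo is expected < once.

    Under equal nucleotide frequencies a random l-mer occurs N/4^l times in
    a genome of N bp; the smallest l with N/4^l < 1 (16 for mammalian-scale
    genomes) balances specificity against cloud sparsity.
    """
    if genome_size < 1:
        raise ValueError(f"genome size must be >= 1, got {genome_size}")
    l = 1
    while genome_size / (4.0**l) >= 1.0:
        l += 1
    return l


def poisson_expected_oligo_histogram(
    n_positions: int, k: int, cmax: int
) -> dict[int, float]:
    """Expected number of distinct k-mers at each copy number 0..cmax.

    Under a uniform i.i.d. null, each of the 4^k possible oligos has copy
    number ~ Poisson(N / 4^k); entry c is 4^k * pmf(c).  Observed copy-number
    histograms exceeding this expectation at high c are the signature of
    repetitive sequence.
    """
    if n_positions < 0:
        raise ValueError("scanned position count must be >= 0")
    if k < 1:
        raise ValueError("word length must be >= 1")
    if cmax < 0:
        raise ValueError("cmax must be >= 0")
    total = 4.0**k
    lam = n_positions / total
    cs = np.arange(cmax + 1)
    return dict(zip(cs.tolist(), (total * stats.poisson.pmf(cs, lam)).tolist()))


def observed_copy_number_histogram(table: OligoCountTable, cmax: int) -> dict[int, int]:
    """Observed number of distinct oligos per copy number, 0..cmax.

    Copy number 0 is the number of possible oligos never seen; computed as
    4^k - len(table) (exact only if the table is unpruned).
    """
    hist = {c: 0 for c in range(cmax + 1)}
    hist[0] = int(4**table.k) - len(table)
    for c in table.counts.values():
        if c <= cmax:
            hist[c] += 1
    return hist
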