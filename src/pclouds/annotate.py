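"""Demarcation of cloud-dense genomic regions.

A genome is scanned one oligo start position at a time; a position is a
"member" position when its k-mer (or the reverse complement) belongs to a
cloud.  The demarcation criterion annotates every window of `window`
consecutive oligo positions in which at least ceil(min_frac * window)
positions are members (80% of every 10 consecutive oligos at the standard
setting).  Maximal runs of annotated positions become nucleotide
intervals; the shortest possible annotation is window + k - 1 nt
(25 nt at the defaults k=16, window=10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from ._seq import as_records, encode, kmer_scan
from .clouds import CloudSet

log = logging.getLogger(__name__)


@dataclass
class AnnotatedRegion:
    """A putatively repetitive interval (0-based, half-open).

    ``posterior`` is the probability the region is truly repetitive;
    it stays 1.0 until length-dependent false-positive calibration
    assigns 1 - FP(length).
    """

    chrom: str
    start: int
    end: int
    posterior: float = 1.0
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def annotate(
    genome,
    cloudset: CloudSet,
    window: int = 10,
    min_frac: float = 0.8,
) -> list[AnnotatedRegion]:
    """Annotate cloud-dense regions of a genome.

    Windows are evaluated only over runs of contiguous valid oligo
    positions, so they never span record boundaries or windows containing
    non-ACGT symbols (assembly gaps are never annotated across).  Records
    shorter than k + window - 1 are skipped with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    k = cloudset.k
    need = math.ceil(min_frac * window)
    members = cloudset.member_kmer_array()
    regions: list[AnnotatedRegion] = []
    for rid, seq in as_records(genome):
        if len(seq) < k + window - 1:
            log.warning(
                "record %s (%d nt) shorter than k+window-1=%d; skipped",
                rid,
                len(seq),
                k + window - 1,
            )
            continue
        valid, km = kmer_scan(encode(seq), k)
        m = valid.size
        mem = np.zeros(m, dtype=bool)
        vidx = np.nonzero(valid)[0]
        if vidx.size and members.size:
            mem[vidx] = np.isin(km[vidx], members)
        annotated = np.zeros(m, dtype=bool)
        # maximal runs of contiguous valid positions
        edges = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s < window:
                continue
            x = mem[s:e].astype(np.int32)
            sums = np.convolve(x, np.ones(window, dtype=np.int32), mode="valid")
            dense = np.flatnonzero(sums >= need)
            if dense.size == 0:
                continue
            diff = np.zeros(e - s + 1, dtype=np.int32)
            diff[dense] += 1
            diff[dense + window] -= 1
            annotated[s:e] = np.cumsum(diff[:-1]) > 0
        ridx = np.flatnonzero(
            np.diff(np.concatenate(([0], annotated.view(np.int8), [0])))
        )
        # the +k nucleotide extension can make runs separated by < k oligo
        # positions overlap or touch; coalesce those into one region
        for a, b in zip(ridx[::2], ridx[1::2]):
            start, end = int(a), int(b - 1 + k)
            if regions and regions[-1].chrom == rid and start <= regions[-1].end:
                regions[-1].end = max(regions[-1].end, end)
            else:
                regions.append(AnnotatedRegion(chrom=rid, start=start, end=end))
    for i, r in enumerate(regions):
        r.name = f"pc{i + 1}"
    return regions


def merge_regions(
    regions: list[AnnotatedRegion],
    gap: int = 0,
    fp_table=None,
) -> list[AnnotatedRegion]:
    """Merge same-record regions separated by at most ``gap`` bp.

    The merged posterior is recomputed from the merged length when an FP
    table is supplied, otherwise it is the maximum of the inputs.
    """
    out: list[AnnotatedRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and r.chrom == out[-1].chrom and r.start - out[-1].end <= gap:
            prev = out[-1]
            merged = replace(prev, end=max(prev.end, r.end))
            if fp_table is not None:
                merged.posterior = 1.0 - fp_table.lookup(merged.length)
            else:
                merged.posterior = max(prev.posterior, r.posterior)
            out[-1] = merged
        else:
            out.append(replace(r))
    return out


def _bed_score(posterior: float) -> int:
    """BED score 0-1000 from a posterior, round-half-up (bit-exact rule)."""
    return int(math.floor(1000.0 * posterior + 0.5))


def write_bed(regions: list[AnnotatedRegion], path, header: str | None = None) -> None:
    """Write regions as BED6 (0-based half-open; score = round(1000*posterior))."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for r in regions:
            name = r.name or "."
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{_bed_score(r.posterior)}\t.\n"
            )


def total_bp(regions: list[AnnotatedRegion]) -> int:
    return sum(r.length for r in regions)
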