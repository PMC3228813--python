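"""Synthetic genomes with planted repeat families and matching truth.

The generator emulates the master-element model of transposable-element
evolution: a family is a master sequence plus copies that each diverge
from it by independent per-site substitutions, optionally truncated
(fragmented), inserted at non-overlapping positions on either strand of a
first-order-Markov background.  Every other module is testable against
the returned truth intervals without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp

_BASES = np.array(list("ACGT"))
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(n: int, seed) -> str:
    """Uniform i.i.d. ACGT sequence of length n (fast null spacer pool)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass
class RepeatFamilySpec:
    """One planted repeat family.

    master_length: length of the master element (bp).
    copies: number of planted copies.
    divergence: expected per-site substitution fraction of each copy from
        the master (0 <= d < 0.75; 0.75 is the saturation point of a
        uniform substitution model).
    fragmentation: "full" for full-length copies, or ("uniform", lo, hi)
        for copy lengths drawn uniformly in [lo, hi] bp and excised at a
        random offset of the master.
    name: family identifier carried into truth intervals and FASTA ids.
    """

    master_length: int
    copies: int
    divergence: float
    fragmentation: object = "full"
    name: str = "fam1"

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 0.75:
            raise ValueError("divergence must be in [0, 0.75)")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class TruthInterval:
    chrom: str
    start: int
    end: int
    family: str
    copy_id: int
    divergence: float  # realised per-site divergence of this copy
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlantedGenome:
    records: list[tuple[str, str]]
    truth: list[TruthInterval]
    families: dict[str, dict]  # name -> {"master": str, "copies": [str, ...]}

    @property
    def planted_bp(self) -> int:
        return sum(t.length for t in self.truth)


def _markov_background(n: int, transition: np.ndarray | None, rng) -> np.ndarray:
    if transition is None:
        return rng.integers(0, 4, size=n, dtype=np.int8)
    transition = np.asarray(transition, dtype=float)
    cum = np.cumsum(transition / transition.sum(axis=1, keepdims=True), axis=1)
    t0, t1, t2 = cum[:, 0].tolist(), cum[:, 1].tolist(), cum[:, 2].tolist()
    us = rng.random(n).tolist()
    out = [0] * n
    s = int(rng.integers(0, 4))
    out[0] = s
    for i in range(1, n):
        u = us[i]
        s = (u > t0[s]) + (u > t1[s]) + (u > t2[s])
        out[i] = s
    return np.array(out, dtype=np.int8)


def _mutate(master_codes: np.ndarray, divergence: float, rng) -> tuple[np.ndarray, float]:
    """Jukes-Cantor-like i.i.d. substitution; returns (codes, realised divergence)."""
    n = master_codes.size
    hit = rng.random(n) < divergence
    out = master_codes.copy()
    if hit.any():
        # uniform choice among the 3 alternative bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out, float(hit.mean())


def plant_genome(
    background_bp: int,
    families: list[RepeatFamilySpec],
    seed: int,
    transition: np.ndarray | None = None,
    chrom: str = "synth1",
    strand_prob: float = 0.5,
    max_retries: int = 200,
) -> PlantedGenome:
    """Plant repeat-family copies into a simulated background.

    Copies overwrite background sequence at uniform non-overlapping
    positions (the genome keeps length ``background_bp``); each copy sits
    on the reverse strand with probability ``strand_prob``.  Raises if
    non-overlapping placement fails after bounded retries.
    """
    rng = np.random.default_rng(seed)
    total_plant = 0
    for f in families:
        if f.fragmentation == "full":
            total_plant += f.master_length * f.copies
        else:
            _, lo, hi = f.fragmentation
            total_plant += hi * f.copies  # worst case
    if background_bp <= total_plant:
        raise ValueError(
            f"background ({background_bp} bp) must exceed planted bp (<= {total_plant})"
        )
    bg = _markov_background(background_bp, transition, rng)
    genome = bg.copy()
    truth: list[TruthInterval] = []
    fam_out: dict[str, dict] = {}
    occupied: list[tuple[int, int]] = []

    def place(length: int) -> int:
        from bisect import bisect_left, insort

        for _ in range(max_retries):
            start = int(rng.integers(0, background_bp - length + 1))
            i = bisect_left(occupied, (start, start))
            ok = True
            if i > 0 and occupied[i - 1][1] > start:
                ok = False
            if ok and i < len(occupied) and occupied[i][0] < start + length:
                ok = False
            if ok:
                insort(occupied, (start, start + length))
                return start
        raise RuntimeError(
            f"could not place a {length}-bp copy without overlap after "
            f"{max_retries} retries; lower copy number or raise background_bp"
        )

    for f in families:
        master = rng.integers(0, 4, size=f.master_length, dtype=np.int8)
        master_seq = "".join(_BASES[master])
        copies_seq: list[str] = []
        for ci in range(f.copies):
            codes, realised = _mutate(master, f.divergence, rng)
            if f.fragmentation != "full":
                _, lo, hi = f.fragmentation
                ln = int(rng.integers(lo, hi + 1))
                ln = min(ln, f.master_length)
                off = int(rng.integers(0, f.master_length - ln + 1))
                codes = codes[off : off + ln]
            copy_seq = "".join(_BASES[codes])
            copies_seq.append(copy_seq)
            strand = "-" if rng.random() < strand_prob else "+"
            planted = revcomp(copy_seq) if strand == "-" else copy_seq
            start = place(len(planted))
            genome[start : start + len(planted)] = [
                "ACGT".index(b) for b in planted
            ]
            truth.append(
                TruthInterval(
                    chrom=chrom,
                    start=start,
                    end=start + len(planted),
                    family=f.name,
                    copy_id=ci,
                    divergence=realised,
                    strand=strand,
                )
            )
        fam_out[f.name] = {"master": master_seq, "copies": copies_seq}
    seq = "".join(_BASES[genome])
    truth.sort(key=lambda t: (t.chrom, t.start))
    return PlantedGenome(records=[(chrom, seq)], truth=truth, families=fam_out)


def write_truth_bed(truth: list[TruthInterval], path, header: str | None = None) -> None:
    """Truth intervals as BED6 (name = family.copy, score = 1000*divergence)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for t in truth:
            score = int(round(1000 * t.divergence))
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.family}.{t.copy_id}\t{score}\t{t.strand}\n"
            )


def family_fasta_out(
    families: dict[str, dict], path, include_master: bool = False
) -> None:
    """Write realised family copies (optionally the master) as FASTA."""
    with open(path, "w") as fh:
        for name, fam in families.items():
            if include_master:
                fh.write(f">{name}.master\n{fam['master']}\n")
            for i, seq in enumerate(fam["copies"]):
                fh.write(f">{name}.{i}\n{seq}\n")
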