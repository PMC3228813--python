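"""FASTA/BED round-tripping, interval complement, and run provenance."""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .annotate import AnnotatedRegion


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) multi-record FASTA into (id, sequence) pairs."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[AnnotatedRegion]:
    """Read BED3+ intervals; score column (if any) maps back to posterior/1000."""
    out: list[AnnotatedRegion] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: BED line has <3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            name = cols[3] if len(cols) > 3 else ""
            post = int(cols[4]) / 1000.0 if len(cols) > 4 and cols[4] != "." else 1.0
            out.append(
                AnnotatedRegion(
                    chrom=cols[0], start=start, end=end, name=name, posterior=post
                )
            )
    return out


def complement_intervals(
    regions: list[AnnotatedRegion], record_lengths: dict[str, int]
) -> list[AnnotatedRegion]:
    """Complement of an interval set within each record (record ends bound it).

    Used by element-specific scans that restrict to the portion of a genome
    not already covered by an existing annotation.
    """
    by_rec: dict[str, list[tuple[int, int]]] = {c: [] for c in record_lengths}
    for r in regions:
        if r.chrom in by_rec:
            by_rec[r.chrom].append((r.start, r.end))
    out: list[AnnotatedRegion] = []
    for chrom, n in record_lengths.items():
        ivs = sorted(by_rec[chrom])
        pos = 0
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            if s > pos:
                out.append(AnnotatedRegion(chrom=chrom, start=pos, end=min(s, n)))
            pos = max(pos, e)
        if pos < n:
            out.append(AnnotatedRegion(chrom=chrom, start=pos, end=n))
    return out


def mask_to_complement(
    records: list[tuple[str, str]], regions: list[AnnotatedRegion]
) -> list[tuple[str, str]]:
    """Replace annotated intervals with N so scanning sees only the complement."""
    by_rec: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_rec.setdefault(r.chrom, []).append((r.start, r.end))
    out = []
    for rid, seq in records:
        if rid in by_rec:
            chars = list(seq)
            for s, e in by_rec[rid]:
                chars[s:e] = "N" * (min(e, len(seq)) - s)
            seq = "".join(chars)
        out.append((rid, seq))
    return out


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run, written next to every output."""

    mode: str
    k: int = 16
    cloud_params: tuple = (2, 10, 20, 200, 2000)
    window: int = 10
    min_frac: float = 0.8
    null_window_bp: int = 1_000_000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "mode": self.mode,
            "k": self.k,
            "cloud_params": list(self.cloud_params),
            "window": self.window,
            "min_frac": self.min_frac,
            "null_window_bp": self.null_window_bp,
            "seed": self.seed,
        }
        d.update(self.extra)
        return json.dumps(d, sort_keys=True, indent=2)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def read_config_file(path) -> dict:
    """Flat key=value config file (# comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value")
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out
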