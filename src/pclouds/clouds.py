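"""Oligo-cloud construction under the five-parameter cutoff scheme.

A cloud is a cluster of related high-copy oligos: a seed oligo whose count
reaches the core cutoff, grown outward through Hamming distance-1 steps to
oligos whose counts reach the lower cutoff.  How far the growth may extend
(distance 1, 2 or 3 from the seed) is gated by the seed's own count against
the three extension cutoffs.  The widely used conservative setting for
whole mammalian genomes is (lower, core, ext1, ext2, ext3) =
(2, 10, 20, 200, 2000), referred to as C10 throughout.

Clouds can be built de novo from whole-genome counts, or from the known
copies of a single transposable-element family ("element-specific" clouds,
ESPs) to annotate further members of that family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import as_records, oligos_to_kmers, revcomp, revcomp_kmers
from .oligos import OligoCountTable, count_oligos, hamming_neighbors

#: conservative whole-genome parameter set
C10 = None  # assigned below once CloudParams exists


@dataclass(frozen=True)
class CloudParams:
    """Cutoff scheme controlling cloud seeding and expansion.

    lower_cutoff   minimum count for an oligo to join a cloud
    core_cutoff    minimum count for an oligo to seed a cloud
    ext1..ext3     seed-count thresholds enabling growth to Hamming
                   distance 1, 2, 3
    """

    lower_cutoff: int
    core_cutoff: int
    ext1: int
    ext2: int
    ext3: int

    def __post_init__(self) -> None:
        seq = (self.lower_cutoff, self.core_cutoff, self.ext1, self.ext2, self.ext3)
        if seq[0] < 1 or any(a > b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                f"cutoffs must satisfy 1 <= lower <= core <= ext1 <= ext2 <= ext3, got {seq}"
            )

    def radius_for(self, seed_count: int) -> int:
        if seed_count >= self.ext3:
            return 3
        if seed_count >= self.ext2:
            return 2
        if seed_count >= self.ext1:
            return 1
        return 0

    def astuple(self) -> tuple[int, int, int, int, int]:
        return (self.lower_cutoff, self.core_cutoff, self.ext1, self.ext2, self.ext3)


C10 = CloudParams(2, 10, 20, 200, 2000)
#: permissive setting used for old, diverged SINE families (e.g. MIR)
MIR_ESP = CloudParams(1, 2, 4, 40, 40)


@dataclass
class Cloud:
    seed: str
    members: set[str]
    radius: int


@dataclass
class CloudSet:
    """A disjoint partition of high-copy oligos into clouds."""

    k: int
    params: CloudParams
    clouds: list[Cloud] = field(default_factory=list)
    membership: dict[str, int] = field(default_factory=dict)
    _kmer_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.clouds)

    @property
    def n_members(self) -> int:
        return len(self.membership)

    def is_member(self, oligo: str) -> bool:
        """True iff the oligo or its reverse complement belongs to any cloud."""
        if len(oligo) != self.k:
            raise ValueError(f"oligo length {len(oligo)} != k={self.k}")
        oligo = oligo.upper()
        return oligo in self.membership or revcomp(oligo) in self.membership

    def member_kmer_array(self) -> np.ndarray:
        """Sorted packed members plus reverse complements, for vector lookup."""
        if self._kmer_cache is None:
            km = oligos_to_kmers(sorted(self.membership), self.k)
            self._kmer_cache = np.union1d(km, revcomp_kmers(km, self.k))
        return self._kmer_cache

    def to_tsv(self, path) -> None:
        """One sorted line per member (oligo, cloud_id, is_seed); diff-stable."""
        seeds = {c.seed: i for i, c in enumerate(self.clouds)}
        with open(path, "w") as fh:
            fh.write(
                f"# k={self.k}\tparams={','.join(map(str, self.params.astuple()))}\n"
            )
            for o in sorted(self.membership):
                cid = self.membership[o]
                fh.write(f"{o}\t{cid}\t{int(seeds.get(o) == cid)}\n")

    @classmethod
    def from_tsv(cls, path) -> "CloudSet":
        k = 0
        params = None
        rows: list[tuple[str, int, bool]] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "params":
                            params = CloudParams(*map(int, val.split(",")))
                    continue
                o, cid, is_seed = line.split("\t")
                rows.append((o, int(cid), bool(int(is_seed))))
        n = 1 + max((cid for _, cid, _ in rows), default=-1)
        clouds = [Cloud(seed="", members=set(), radius=0) for _ in range(n)]
        membership: dict[str, int] = {}
        for o, cid, is_seed in rows:
            clouds[cid].members.add(o)
            membership[o] = cid
            if is_seed:
                clouds[cid].seed = o
        for c in clouds:
            # radius is not serialized; recover the realised growth radius
            c.radius = max(
                (sum(a != b for a, b in zip(c.seed, m)) for m in c.members),
                default=0,
            )
        return cls(k=k, params=params, clouds=clouds, membership=membership)


def build_clouds(counts: OligoCountTable, params: CloudParams) -> CloudSet:
    """Cluster high-copy oligos into disjoint clouds.

    Oligos with count >= core_cutoff are processed in descending-count
    order (ties lexicographic).  Each still-unassigned core oligo seeds a
    cloud whose growth radius r (0-3) is set by the seed's count against
    the extension cutoffs; growth proceeds breadth-first through
    distance-1 steps between admitted members, admitting any unassigned
    oligo with count >= lower_cutoff, for at most r levels.  Assignment is
    greedy and final: an oligo reachable from two seeds joins the
    higher-count (earlier) one.
    """
    eligible = {o: c for o, c in counts.counts.items() if c >= params.lower_cutoff}
    seeds = sorted(
        (o for o, c in eligible.items() if c >= params.core_cutoff),
        key=lambda o: (-eligible[o], o),
    )
    clouds: list[Cloud] = []
    membership: dict[str, int] = {}
    for s in seeds:
        if s in membership:
            continue
        idx = len(clouds)
        radius = params.radius_for(eligible[s])
        members = {s}
        membership[s] = idx
        frontier = [s]
        for _level in range(radius):
            nxt: list[str] = []
            for o in frontier:
                for nb in hamming_neighbors(o, 1):
                    if nb in eligible and nb not in membership:
                        membership[nb] = idx
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
        clouds.append(Cloud(seed=s, members=members, radius=radius))
    return CloudSet(k=counts.k, params=params, clouds=clouds, membership=membership)


def build_esp_clouds(
    family_seqs,
    params: CloudParams,
    k: int,
    exclude: set[str] | None = None,
) -> CloudSet:
    """Element-specific clouds from the known copies of one repeat family.

    Counting runs over the family sequences instead of a whole genome;
    ``exclude`` holds record ids (or full sequences) of held-out copies,
    supporting cross-validated sensitivity measurement where the test
    elements did not contribute to cloud construction.
    """
    records = as_records(family_seqs)
    if exclude:
        records = [
            (rid, seq)
            for rid, seq in records
            if rid not in exclude and seq not in exclude
        ]
    if not records:
        raise ValueError("all family records excluded; nothing to build clouds from")
    return build_clouds(count_oligos(records, k), params)


def is_member(cloudset: CloudSet, oligo: str) -> bool:
    """Strand-symmetric cloud membership lookup (free function form)."""
    return cloudset.is_member(oligo)
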