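"""Write a planted-repeat fixture to disk: genome FASTA, truth BED, family FASTA.

The same files can be produced from the shell:
    pclouds simulate -o fixture --background-bp 500000 --copies 120 --seed 9
"""

from pathlib import Path

import pclouds as pc

out = Path("scratch_fixture")
out.mkdir(exist_ok=True)

fams = [
    pc.RepeatFamilySpec(master_length=300, copies=120, divergence=0.08, name="young"),
    pc.RepeatFamilySpec(master_length=260, copies=80, divergence=0.25,
                        fragmentation=("uniform", 80, 260), name="old"),
]
g = pc.plant_genome(500_000, fams, seed=9)

pc.write_fasta(g.records, out / "genome.fasta")
pc.write_truth_bed(g.truth, out / "truth.bed", header="seed=9")
pc.family_fasta_out(g.families, out / "families.fasta", include_master=True)

print(f"wrote {out}/genome.fasta ({len(g.records[0][1]):,} bp)")
print(f"wrote {out}/truth.bed ({len(g.truth)} planted copies, "
      f"{g.planted_bp:,} bp; name=family.copy, score=1000*divergence)")
print(f"wrote {out}/families.fasta "
      f"({sum(len(f['copies']) for f in g.families.values())} copies + 2 masters)")
print("the 'old' family is fragmented and diverged - the hard case for "
      "library-free detection")
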