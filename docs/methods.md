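# Methods

## Model

The package treats repetitive sequence detection as a k-mer clustering
problem. A family of transposable elements descends from a master
element; each copy accumulates substitutions, so the family's k-mers form
a cluster in Hamming space around the master's k-mers — many distinct
words, each individually rare, but collectively dense and mutually
adjacent. A cloud captures such a cluster directly from counts, with no
alignment and no consensus library. There is more statistical power in
the joint signal of many related medium-copy oligos than in any single
oligo's excess count, which is what lets the approach find old, diverged,
fragmented families that alignment against a consensus misses.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 16 | oligo word length; smallest `l` with `N/4^l < 1` so a random word is expected less than once in an `N`-bp genome (16 covers genomes up to 4.3 Gbp) |
| `lower` | 2 | min count to join a cloud |
| `core` | 10 | min count to seed a cloud |
| `ext1/ext2/ext3` | 20/200/2000 | seed-count thresholds enabling growth to Hamming distance 1/2/3 |
| `window` | 10 | demarcation window, in oligo start positions |
| `min_frac` | 0.8 | member fraction for a dense window (≥ 8 of 10, ceiling rule) |
| `window_bp` | 1,000,000 | null-genome window within which dinucleotide frequencies are matched |
| `density` | 0.10 | repeat fraction of benchmark artificial genomes |

The `(2,10,20,200,2000)` scheme (`C10`) is the conservative whole-genome
setting; `(1,2,4,40,40)` (`MIR_ESP`) is the permissive setting for
element-specific clouds of old, diverged families, where most informative
oligos occur only once or twice in the family library.

## Algorithmic choices

**Cloud growth is seed-gated.** The growth radius of a cloud is fixed by
its seed's count alone, because growth only ever adds lower-count oligos,
so the seed is the most frequent member throughout. The alternative —
re-gating each extension step on intermediate members' own counts — is a
defensible reading but is not used; the exhaustive-oracle tests pin the
seed-gated semantics.

**Assignment is greedy and final.** Seeds are processed in descending
count order (ties broken lexicographically); an oligo reachable from two
seeds joins the first (higher-count) one and is never reassigned. This
makes construction deterministic and serialisation byte-stable. Seeds
with counts in `[core, ext1)` form singleton clouds.

**Strand handling.** Counting is strand-asymmetric (words counted as
written); membership lookup at annotation time queries an oligo and its
reverse complement, so annotation is strand-symmetric while count
semantics stay simple. One consequence at low copy number: a family
planted on both strands splits its counts between the two orientations
of each word.

**Demarcation geometry.** Windows are evaluated only within runs of
contiguous valid oligo positions: they never span record boundaries or
any window containing a non-ACGT symbol, so assembly gaps are never
annotated across. Annotated oligo-position runs extend `k − 1` nt to the
right; runs closer than `k` oligo positions would produce overlapping
nucleotide intervals and are coalesced. The shortest possible annotation
is `window + k − 1` = 25 nt; the shortest *perfect* fragment that can be
detected by any-overlap is `k + ceil(min_frac·window) − 1` = 23 nt, since
a dense window may straddle the fragment boundary.

**FP table.** False-positive rates are recorded per exact annotation
length as a count ratio, `FP(L) = min(1, n_sim(L)·(real_bp/sim_bp) /
n_real(L))`; lookup for an unlisted length falls back to the nearest
smaller listed length, then to the overall `n_real`-weighted mean rate.
No parametric smoothing by default; an optional isotonic (non-increasing
in `L`) smoothing (`FPTable.smoothed()`) pools adjacent violators, which
is appropriate because chance annotations get rarer with length.

**Null simulation.** Each 1-Mbp window is regenerated as a first-order
Markov chain with the window's observed dinucleotide conditional
frequencies; the initial state of each run, and any base with no observed
outgoing transitions, falls back to the window's mononucleotide
frequencies. Non-ACGT runs are copied through verbatim at their original
coordinates, so record lengths and gap structure are preserved exactly.
Windows with fewer than 2 ACGT nt are copied verbatim with a warning.

**Interpolation.** Sensitivity-by-size uses a cubic spline through the
measured knots, clamped to [0,1] and constant-extrapolated outside the
measured range; two knots degrade to linear interpolation, one to a
constant with a warning. Missed-bp prediction divides observed detection
counts by interpolated sensitivity and never divides by zero — sizes with
zero sensitivity are excluded and reported.

**Detection rule.** A benchmark fragment counts as detected when ≥ 1 bp
of it is annotated (the most literal reading of "identified"); a
minimum-overlap-fraction option exists for stricter analyses. The
positional curve is a trailing running average over 10 consecutive start
offsets.

## What the synthetic generator does and does not emulate

`plant_genome` draws a uniform-random master per family, mutates each
copy i.i.d. per site at the nominal divergence (uniform over the three
alternatives; Jukes-Cantor-like), optionally truncates copies, and
overwrites them at uniform non-overlapping positions on either strand of
a first-order-Markov background. It emulates the master-element structure
that clouds exploit — many copies, star-shaped divergence — and supports
an age proxy (higher divergence = older family = lower sensitivity).

It does **not** emulate: indels (the cloud sequence space is
substitution-only), nested insertions, CpG-driven mutation hotspots,
subfamily structure, tandem/low-complexity repeats, or realistic genomic
base composition beyond first order. Passing tests therefore demonstrate
the machinery is correct under the stated model, not that desk-scale
sensitivity numbers transfer to real genomes.

## Copy number limits desk-scale sensitivity

Cloud membership requires an *exact* k-mer recurrence: a scanned word
joins no cloud unless that word (or its reverse complement) itself has
count ≥ `lower` and lies within the growth radius of a seed. At 500
copies, a specific single-mutant 16-mer of the master recurs a handful of
times and usually qualifies, but a specific double-mutant word is
expected ≈ 0.1 times — effectively never — and seed counts (~10² here)
stay below `ext2`, so distance-2/3 growth never engages. The per-position
membership probability is then capped by P(≤ 1 mismatch in a 16-mer) and
the 8-of-10 demarcation rule yields ~65–75% planted-bp recovery at 10%
divergence, as the acceptance run measures. The regime changes with
family size: at the 10⁵–10⁶ copies typical of major SINE families,
multi-mutant words recur, the larger extension radii engage, and
short-fragment sensitivity approaches 100%. Benchmarks at desk scale
should therefore read recovery fractions as properties of the stated
copy-number/divergence condition, not as ceilings of the method.

## Problem sizes used

The test and acceptance workloads use 2-Mbp genomes (500 × 300-bp copies
at 10% divergence for de novo recovery), 1-Mbp null windows over 2-Mbp
sources, and ESP benchmarks with 200 training copies plus 4+4 held-out
elements over ~3-Mbp artificial genomes — sizes chosen so every
experiment reruns from scratch in seconds while keeping per-size fragment
counts in the hundreds-to-thousands (binomial standard errors of a few
percent).

## Determinism

Every random stage takes an explicit seed (`numpy.random.default_rng`);
identical seeds give byte-identical FASTA/BED/TSV outputs. The CLI writes
a JSON provenance block (all parameters and seeds) next to every output.
Spacer sequence in benchmark genomes is consumed from the null pool
without replacement, so spacers never repeat and cannot form artifactual
clouds.

## Known limitations

- No indel model anywhere in the stack; real diverged copies contain
  indels, which fragment exact-word matches further.
- Memory is dict-of-strings bounded (~100 bytes per distinct k-mer):
  ample for desk-scale genomes, not for a 3-Gbp assembly in one pass;
  the design permits sharded counting but does not implement it.
- The FP calibration needs the null to produce annotations to estimate
  nonzero rates; at desk scale with conservative parameters the null is
  usually perfectly clean, making all posteriors 1.0 — correct, but
  uninformative about the long-tail FP structure seen at genome scale.
- `merge_regions` recomputes a merged region's posterior from the FP
  table when one is supplied, else takes the max of the inputs — a
  heuristic, since the joint null distribution of merged lengths is not
  modelled.
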