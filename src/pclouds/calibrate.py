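"""Length-dependent false-positive calibration against a dinucleotide null.

Short cloud-dense regions arise by chance even in non-repetitive sequence.
To quantify that, a null genome is simulated that preserves the local
dinucleotide (first-order Markov) structure of the real sequence in fixed
windows but carries no higher-order repeat structure.  Annotating the null
with the same parameters yields, for every annotated-region length, an
empirical false-positive probability; each real annotation then receives a
posterior probability of being truly repetitive equal to 1 - FP(length),
and expected truly-repetitive bp totals are sums of length * posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import isotonic_regression

from ._seq import as_records, encode
from .annotate import AnnotatedRegion

log = logging.getLogger(__name__)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class NullGenomeSpec:
    """Parameters of the dinucleotide-preserving null simulation.

    window_bp: size of the window (bp) within which the output chain
        matches the source's dinucleotide conditional frequencies
        (1 Mbp in the standard workflow).
    seed: RNG seed; recorded in output headers for reproducibility.
    """

    window_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp < 2:
            raise ValueError("window_bp must be >= 2")


def _markov_run(length: int, init_cum, row_thresh, rng) -> np.ndarray:
    """Sample a first-order Markov chain of 2-bit codes."""
    us = rng.random(length).tolist()
    s = min(int(np.searchsorted(init_cum, us[0], side="right")), 3)
    res = [0] * length
    res[0] = s
    t0, t1, t2 = row_thresh
    # plain-python loop: the chain is inherently sequential
    for i in range(1, length):
        u = us[i]
        s = (u > t0[s]) + (u > t1[s]) + (u > t2[s])
        res[i] = s
    return np.array(res, dtype=np.uint8)


def simulate_null_genome(source, spec: NullGenomeSpec) -> list[tuple[str, str]]:
    """Simulate a non-repetitive genome with the source's local dinucleotide structure.

    Per window of ``spec.window_bp`` nt, the output is a first-order Markov
    chain whose transition probabilities are the window's observed
    dinucleotide conditional frequencies (initial state and any row with no
    observed transitions fall back to the window's mononucleotide
    frequencies).  Non-ACGT runs are copied through verbatim at the same
    coordinates, so output record lengths equal input lengths.  Windows with
    fewer than two ACGT nt are copied verbatim with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    out_records: list[tuple[str, str]] = []
    for rid, seq in as_records(source):
        codes = encode(seq)
        out_chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n = codes.size
        for w0 in range(0, n, spec.window_bp):
            w1 = min(w0 + spec.window_bp, n)
            wc = codes[w0:w1]
            ok = wc < 4
            if ok.sum() < 2:
                if ok.any():
                    log.warning(
                        "window %s:%d-%d has <2 ACGT nt; copied verbatim", rid, w0, w1
                    )
                continue
            a, b = wc[:-1], wc[1:]
            pair_ok = (a < 4) & (b < 4)
            trans = np.bincount(
                (a[pair_ok].astype(np.intp) << 2) | b[pair_ok], minlength=16
            ).reshape(4, 4)
            mono = np.bincount(wc[ok], minlength=4).astype(float)
            mono_p = mono / mono.sum()
            rows = np.empty((4, 4))
            for s in range(4):
                tot = trans[s].sum()
                rows[s] = trans[s] / tot if tot > 0 else mono_p
            cum = np.cumsum(rows, axis=1)
            thresh = (cum[:, 0].tolist(), cum[:, 1].tolist(), cum[:, 2].tolist())
            init_cum = np.cumsum(mono_p)
            # regenerate each ACGT run in place; non-ACGT stays verbatim
            d = np.diff(np.concatenate(([0], ok.view(np.int8), [0])))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for rs, re in zip(starts, ends):
                sim = _markov_run(int(re - rs), init_cum, thresh, rng)
                out_chars[w0 + rs : w0 + re] = _BASE_ARR[sim]
        out_records.append((rid, out_chars.tobytes().decode("ascii")))
    return out_records


def dinucleotide_counts(seq: str) -> np.ndarray:
    """4x4 transition counts over adjacent ACGT pairs (rows = first base)."""
    codes = encode(seq)
    a, b = codes[:-1], codes[1:]
    ok = (a < 4) & (b < 4)
    return np.bincount((a[ok].astype(np.intp) << 2) | b[ok], minlength=16).reshape(4, 4)


@dataclass
class FPTable:
    """Empirical false-positive probability as a function of region length.

    ``rates`` holds FP(L) for every length observed in the real annotation;
    lookup for an unlisted length falls back to the nearest listed smaller
    length, then to the overall (n_real-weighted) mean FP rate.
    ``normalization`` is the real/simulated scanned-bp ratio (1 when the
    null genome has the same total length as the real input).
    """

    rates: dict[int, float] = field(default_factory=dict)
    n_real: dict[int, int] = field(default_factory=dict)
    n_sim: dict[int, int] = field(default_factory=dict)
    normalization: float = 1.0
    default_fp: float = 0.0
    _sorted_lengths: list[int] | None = field(default=None, repr=False, compare=False)

    def lookup(self, length: int) -> float:
        if length in self.rates:
            return self.rates[length]
        if self._sorted_lengths is None:
            self._sorted_lengths = sorted(self.rates)
        import bisect

        ls = self._sorted_lengths
        i = bisect.bisect_right(ls, length)
        if i > 0:
            return self.rates[ls[i - 1]]
        return self.default_fp

    def mean_fp(self) -> float:
        """n_real-weighted mean FP rate over observed lengths."""
        tot = sum(self.n_real.values())
        if tot == 0:
            return self.default_fp
        return sum(self.rates[L] * n for L, n in self.n_real.items()) / tot

    def smoothed(self) -> "FPTable":
        """Isotonic (non-increasing in length) smoothing of the rates.

        Longer chance annotations are rarer, so the true FP curve is
        non-increasing; pooling adjacent violators removes sampling noise
        in sparse length classes.  Off by default.
        """
        if not self.rates:
            return replace(self)
        ls = sorted(self.rates)
        y = np.array([self.rates[L] for L in ls])
        w = np.array([max(self.n_real.get(L, 1), 1) for L in ls], dtype=float)
        fit = isotonic_regression(y, weights=w, increasing=False)
        sm = {L: float(np.clip(v, 0.0, 1.0)) for L, v in zip(ls, fit.x)}
        return replace(self, rates=sm, _sorted_lengths=None)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# normalization={self.normalization}\tdefault_fp={self.default_fp}\n"
            )
            fh.write("length\tn_real\tn_sim\tfp\n")
            for L in sorted(self.rates):
                fh.write(
                    f"{L}\t{self.n_real.get(L, 0)}\t{self.n_sim.get(L, 0)}\t{self.rates[L]:.6g}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "FPTable":
        t = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        if key == "normalization":
                            t.normalization = float(val)
                        elif key == "default_fp":
                            t.default_fp = float(val)
                    continue
                if line.startswith("length"):
                    continue
                L, nr, ns, fp = line.split("\t")
                L = int(L)
                t.rates[L] = float(fp)
                t.n_real[L] = int(nr)
                t.n_sim[L] = int(ns)
        return t


def estimate_fp_table(
    real_regions: list[AnnotatedRegion],
    sim_regions: list[AnnotatedRegion],
    real_bp: int,
    sim_bp: int,
    smooth: bool = False,
) -> FPTable:
    """Per-length false-positive probabilities from matched annotations.

    For each length L observed in the real annotation,
    FP(L) = min(1, n_sim(L) * (real_bp / sim_bp) / n_real(L)) — the rate at
    which the null genome produced annotations of exactly that length,
    normalised for scanned-bp imbalance.  Both region lists must come from
    identical counting/cloud/annotation parameters.
    """
    if sim_bp <= 0:
        raise ValueError("sim_bp must be positive")
    ratio = real_bp / sim_bp
    n_real: dict[int, int] = {}
    for r in real_regions:
        n_real[r.length] = n_real.get(r.length, 0) + 1
    n_sim: dict[int, int] = {}
    for r in sim_regions:
        n_sim[r.length] = n_sim.get(r.length, 0) + 1
    tot_real = sum(n_real.values())
    tot_sim = sum(n_sim.values())
    default_fp = min(1.0, ratio * tot_sim / max(tot_real, 1))
    rates = {
        L: min(1.0, (n_sim.get(L, 0) * ratio) / n)
        for L, n in n_real.items()
    }
    table = FPTable(
        rates=rates,
        n_real=n_real,
        n_sim=n_sim,
        normalization=ratio,
        default_fp=default_fp,
    )
    return table.smoothed() if smooth else table


def assign_posteriors(
    regions: list[AnnotatedRegion], fp_table: FPTable
) -> list[AnnotatedRegion]:
    """Set each region's posterior to 1 - FP(length); coordinates unchanged."""
    return [replace(r, posterior=1.0 - fp_table.lookup(r.length)) for r in regions]


def expected_true_bp(regions: list[AnnotatedRegion]) -> float:
    """Expected truly repetitive bp: sum of length * posterior over regions."""
    return float(sum(r.length * r.posterior for r in regions))
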