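"""Null-genome simulation, FP tables, posterior assignment."""

import numpy as np
import pytest
from scipy import stats

import pclouds as pc
from pclouds.calibrate import dinucleotide_counts


def biased_source(n, seed):
    """Markov sequence with a deliberately skewed dinucleotide structure."""
    trans = np.array(
        [
            [0.40, 0.20, 0.30, 0.10],
            [0.10, 0.40, 0.05, 0.45],  # CG suppressed, CT enriched
            [0.25, 0.25, 0.25, 0.25],
            [0.30, 0.10, 0.35, 0.25],
        ]
    )
    g = pc.plant_genome(
        n, [pc.RepeatFamilySpec(master_length=50, copies=0, divergence=0.0)],
        seed=seed, transition=trans,
    )
    return g.records[0][1]


class TestSimulateNullGenome:
    def test_all_a_source_gives_all_a(self):
        out = pc.simulate_null_genome([("r", "A" * 500)], pc.NullGenomeSpec(1000, 1))
        assert out == [("r", "A" * 500)]

    def test_length_contract_and_n_runs_preserved(self):
        src = "ACGTAC" * 100 + "N" * 37 + "GGTTAACC" * 50
        out = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(10_000, 2))
        assert len(out[0][1]) == len(src)
        i = src.index("N")
        assert out[0][1][i : i + 37] == "N" * 37

    def test_determinism(self):
        src = biased_source(50_000, 9)
        a = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(10_000, 5))
        b = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(10_000, 5))
        assert a == b
        c = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(10_000, 6))
        assert c != a

    def test_dinucleotide_frequencies_match_per_window(self):
        # per-window transition counts of the output are consistent with the
        # source's conditional frequencies (chi-square GOF, p > 0.001)
        window = 100_000
        src = biased_source(300_000, 11)
        out = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(window, 12))[0][1]
        for w0 in range(0, len(src), window):
            src_t = dinucleotide_counts(src[w0 : w0 + window])
            out_t = dinucleotide_counts(out[w0 : w0 + window])
            chi2 = 0.0
            df = 0
            for row in range(4):
                p = src_t[row] / src_t[row].sum()
                n = out_t[row].sum()
                keep = p > 0
                c = stats.chisquare(out_t[row][keep], p[keep] * n)
                chi2 += c.statistic
                df += keep.sum() - 1
            assert stats.chi2.sf(chi2, df) > 0.001

    def test_repeats_destroyed(self):
        # a null genome built from a planted-repeat genome annotates far less
        # family sequence than the original
        fam = pc.RepeatFamilySpec(master_length=300, copies=150, divergence=0.05)
        g = pc.plant_genome(600_000, [fam], seed=31)
        null = pc.simulate_null_genome(g.records, pc.NullGenomeSpec(1_000_000, 32))
        cs = pc.build_clouds(pc.count_oligos(g.records, 16), pc.C10)
        orig_bp = pc.total_bp(pc.annotate(g.records, cs))
        null_cs = pc.build_clouds(pc.count_oligos(null, 16), pc.C10)
        null_bp = pc.total_bp(pc.annotate(null, null_cs))
        assert null_bp < 0.1 * orig_bp

    def test_tiny_window_copied_verbatim(self, caplog):
        src = "NNNNNA"
        with caplog.at_level("WARNING"):
            out = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(10, 1))
        assert out == [("r", src)]


class TestFPTable:
    def test_empty_sim_regions_fp_zero_posteriors_one(self):
        real = [pc.AnnotatedRegion("c", 0, 30), pc.AnnotatedRegion("c", 50, 90)]
        t = pc.estimate_fp_table(real, [], 1000, 1000)
        assert all(v == 0.0 for v in t.rates.values())
        scored = pc.assign_posteriors(real, t)
        assert all(r.posterior == 1.0 for r in scored)

    def test_equal_counts_fp_one_posterior_zero(self):
        real = [pc.AnnotatedRegion("c", 0, 30)]
        sim = [pc.AnnotatedRegion("s", 10, 40)]
        t = pc.estimate_fp_table(real, sim, 1000, 1000)
        assert t.rates[30] == 1.0
        assert pc.assign_posteriors(real, t)[0].posterior == 0.0

    def test_direct_ratio(self):
        real = [pc.AnnotatedRegion("c", i * 100, i * 100 + 30) for i in range(10)]
        sim = [pc.AnnotatedRegion("s", i * 100, i * 100 + 30) for i in range(5)]
        t = pc.estimate_fp_table(real, sim, 1000, 1000)
        assert t.rates[30] == pytest.approx(0.5)

    def test_bp_normalization(self):
        real = [pc.AnnotatedRegion("c", 0, 30)] * 4
        sim = [pc.AnnotatedRegion("s", 0, 30)]
        # simulated genome half the size: its counts are scaled by 2,
        # so 1 sim vs 4 real regions gives FP = 2/4
        t = pc.estimate_fp_table(real, sim, 1000, 500)
        assert t.normalization == 2.0
        assert t.rates[30] == pytest.approx(0.5)

    def test_lookup_falls_back_to_nearest_smaller_length(self):
        t = pc.FPTable(rates={25: 0.8, 40: 0.2}, n_real={25: 4, 40: 1}, default_fp=0.5)
        assert t.lookup(25) == 0.8
        assert t.lookup(39) == 0.8  # nearest smaller listed length
        assert t.lookup(60) == 0.2
        assert t.lookup(20) == 0.5  # below all listed lengths -> default

    def test_mean_fp_weighted_by_real_counts(self):
        t = pc.FPTable(rates={25: 0.8, 40: 0.2}, n_real={25: 4, 40: 1})
        assert t.mean_fp() == pytest.approx((0.8 * 4 + 0.2 * 1) / 5)

    def test_empty_real_regions(self):
        t = pc.estimate_fp_table([], [pc.AnnotatedRegion("s", 0, 30)], 1000, 1000)
        assert t.rates == {}
        assert t.lookup(30) == 1.0  # null annotates but real does not

    def test_isotonic_smoothing_non_increasing(self):
        rng = np.random.default_rng(0)
        lengths = np.arange(25, 80)
        rates = {int(L): float(np.clip(1.2 - 0.015 * L + rng.normal(0, 0.1), 0, 1)) for L in lengths}
        t = pc.FPTable(rates=rates, n_real={int(L): 5 for L in lengths})
        sm = t.smoothed()
        vals = [sm.rates[int(L)] for L in lengths]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_tsv_roundtrip(self, tmp_path):
        t = pc.FPTable(
            rates={25: 0.8, 40: 0.25},
            n_real={25: 4, 40: 8},
            n_sim={25: 3, 40: 2},
            normalization=1.5,
            default_fp=0.7,
        )
        p = tmp_path / "fp.tsv"
        t.to_tsv(p)
        back = pc.FPTable.from_tsv(p)
        assert back.rates == pytest.approx(t.rates)
        assert back.n_real == t.n_real and back.n_sim == t.n_sim
        assert back.normalization == 1.5 and back.default_fp == 0.7


class TestPosteriorAccounting:
    def test_elementwise_complement(self):
        t = pc.FPTable(rates={25: 0.9, 30: 0.4, 50: 0.0}, n_real={25: 1, 30: 1, 50: 1})
        regs = [
            pc.AnnotatedRegion("c", 0, 25),
            pc.AnnotatedRegion("c", 100, 130),
            pc.AnnotatedRegion("c", 200, 250),
        ]
        scored = pc.assign_posteriors(regs, t)
        assert [r.posterior for r in scored] == pytest.approx([0.1, 0.6, 1.0])
        # coordinates and order unchanged
        assert [(r.start, r.end) for r in scored] == [(0, 25), (100, 130), (200, 250)]

    def test_expected_true_bp_direct_sum(self):
        regs = [
            pc.AnnotatedRegion("c", 0, 30, posterior=0.5),
            pc.AnnotatedRegion("c", 50, 90, posterior=1.0),
        ]
        assert pc.expected_true_bp(regs) == pytest.approx(55.0)

    def test_bounds(self):
        regs = [pc.AnnotatedRegion("c", 0, 30, posterior=0.0)]
        assert pc.expected_true_bp(regs) == 0.0
        regs = [pc.AnnotatedRegion("c", 0, 30, posterior=1.0),
                pc.AnnotatedRegion("c", 40, 100, posterior=1.0)]
        assert pc.expected_true_bp(regs) == pc.total_bp(regs) == 90

    def test_linear_and_bounded(self):
        rng = np.random.default_rng(4)
        regs = [
            pc.AnnotatedRegion("c", int(s), int(s) + int(l), posterior=float(p))
            for s, l, p in zip(
                np.arange(0, 10_000, 100), rng.integers(25, 80, 100), rng.random(100)
            )
        ]
        tot = pc.expected_true_bp(regs)
        assert 0 <= tot <= pc.total_bp(regs)
        half = pc.expected_true_bp(regs[:50]) + pc.expected_true_bp(regs[50:])
        assert tot == pytest.approx(half)


def test_null_fp_fraction_stable_across_seeds():
    """Annotated fraction of a pure Markov null is small and seed-stable."""
    src = biased_source(400_000, 77)
    fracs = []
    for seed in range(5):
        null = pc.simulate_null_genome([("r", src)], pc.NullGenomeSpec(1_000_000, seed))
        cs = pc.build_clouds(pc.count_oligos(null, 16), pc.C10)
        fracs.append(pc.total_bp(pc.annotate(null, cs)) / len(src))
    fracs = np.array(fracs)
    assert fracs.max() < 0.05
    if fracs.mean() > 0:
        assert fracs.std(ddof=1) / max(fracs.mean(), 1e-12) < 0.2 or fracs.max() < 1e-3
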