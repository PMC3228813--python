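"""Fragment-detection sensitivity benchmarking and missed-repeat estimation.

Known full-length elements are chopped into fragments of fixed sizes
(every possible start offset), embedded in simulated non-repetitive
sequence at a fixed repeat density (10% by default), and annotated.  From
the detection indicators one obtains size-specific and position-specific
sensitivity curves; spline interpolation extends sensitivity to
unevaluated sizes, and dividing observed detection counts by sensitivity
predicts how much repetitive sequence an annotator misses.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._seq import as_records
from .annotate import AnnotatedRegion

log = logging.getLogger(__name__)


@dataclass
class FragmentSpec:
    """Design of a fragment-sensitivity experiment.

    sizes: fragment lengths (bp) to evaluate; the standard panels are
        30/40/50 for a young dense family and 30/50/80/100/150/200 for an
        old diverged one.
    density: repeat fraction of the artificial genome (0.10 standard).
    elements: full-length element sequences (id, seq) to fragment.
    """

    sizes: list[int]
    elements: list[tuple[str, str]]
    density: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if not self.sizes:
            raise ValueError("at least one fragment size required")
        self.elements = as_records(self.elements)


@dataclass
class FragmentTruth:
    """Location and provenance of one embedded fragment."""

    chrom: str
    start: int
    end: int
    element: str
    size: int
    offset: int
    detected: bool = False


@dataclass
class SensitivityCurve:
    """Detection sensitivity by fragment size and by start position.

    by_position holds, per size, a trailing running average over 10
    consecutive start offsets of the per-offset detection fraction;
    by_position_raw holds the unsmoothed per-offset fractions.
    """

    by_size: dict[int, float] = field(default_factory=dict)
    by_position: dict[int, np.ndarray] = field(default_factory=dict)
    by_position_raw: dict[int, np.ndarray] = field(default_factory=dict)
    n_fragments: dict[int, int] = field(default_factory=dict)
    n_detected: dict[int, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("size\tn_fragments\tn_detected\tsensitivity\n")
            for s in sorted(self.by_size):
                fh.write(
                    f"{s}\t{self.n_fragments[s]}\t{self.n_detected[s]}"
                    f"\t{self.by_size[s]:.6g}\n"
                )


def make_fragment_genome(
    spec: FragmentSpec,
    null_source,
    seed: int,
    chrom: str = "bench1",
) -> tuple[list[tuple[str, str]], list[FragmentTruth]]:
    """Build an artificial genome of element fragments in null spacer sequence.

    For every element and size s, every possible start offset contributes
    one fragment.  Fragments (in seed-shuffled order) alternate with
    spacers of round(s * (1 - density) / density) bp, drawn sequentially
    (without replacement) from the null pool, so fragments make up
    ``density`` of the genome up to rounding.  Raises if the pool cannot
    supply the spacer bp, naming the requirement.
    """
    rng = np.random.default_rng(seed)
    frags: list[tuple[str, int, int, str]] = []
    for eid, eseq in spec.elements:
        for s in spec.sizes:
            if s > len(eseq):
                log.warning("element %s shorter than size %d; skipped", eid, s)
                continue
            for off in range(len(eseq) - s + 1):
                frags.append((eid, s, off, eseq[off : off + s]))
    if not frags:
        raise ValueError("no fragments produced; sizes exceed all element lengths")
    order = rng.permutation(len(frags))
    pool = "".join(seq for _rid, seq in as_records(null_source))
    d = spec.density
    need = sum(int(round(len(f[3]) * (1 - d) / d)) for f in frags)
    if len(pool) < need:
        raise ValueError(
            f"null pool too short: {need} spacer bp required, {len(pool)} available"
        )
    parts: list[str] = []
    truth: list[FragmentTruth] = []
    pos = 0
    pp = 0  # pool cursor; consumed without replacement
    for i in order:
        eid, s, off, fseq = frags[i]
        spacer = int(round(s * (1 - d) / d))
        parts.append(pool[pp : pp + spacer])
        pp += spacer
        pos += spacer
        parts.append(fseq)
        truth.append(
            FragmentTruth(
                chrom=chrom, start=pos, end=pos + s, element=eid, size=s, offset=off
            )
        )
        pos += s
    return [(chrom, "".join(parts))], truth


def measure_sensitivity(
    truth: list[FragmentTruth],
    regions: list[AnnotatedRegion],
    min_overlap_frac: float = 0.0,
    running_window: int = 10,
) -> SensitivityCurve:
    """Fraction of embedded fragments overlapped by any annotated region.

    A fragment counts as detected when at least 1 bp of it (or at least
    ``min_overlap_frac`` of its length, if set) is covered by annotation.
    Position-specific sensitivity is averaged over elements at each start
    offset and smoothed with a trailing running average over
    ``running_window`` consecutive offsets.
    """
    by_rec: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_rec.setdefault(r.chrom, []).append((r.start, r.end))
    for iv in by_rec.values():
        iv.sort()
    starts = {c: [iv[0] for iv in lst] for c, lst in by_rec.items()}

    def overlap_bp(chrom: str, a: int, b: int) -> int:
        lst = by_rec.get(chrom)
        if not lst:
            return 0
        i = bisect_right(starts[chrom], b) - 1
        tot = 0
        while i >= 0:
            s0, e0 = lst[i]
            if e0 <= a:
                # regions are non-overlapping and sorted; nothing further left overlaps
                break
            tot += max(0, min(b, e0) - max(a, s0))
            i -= 1
        return tot

    for f in truth:
        ov = overlap_bp(f.chrom, f.start, f.end)
        thr = max(1, int(np.ceil(min_overlap_frac * f.size)))
        f.detected = ov >= thr

    curve = SensitivityCurve()
    sizes = sorted({f.size for f in truth})
    for s in sizes:
        fs = [f for f in truth if f.size == s]
        curve.n_fragments[s] = len(fs)
        curve.n_detected[s] = sum(f.detected for f in fs)
        curve.by_size[s] = curve.n_detected[s] / len(fs)
        max_off = max(f.offset for f in fs)
        hit = np.zeros(max_off + 1)
        tot = np.zeros(max_off + 1)
        for f in fs:
            tot[f.offset] += 1
            hit[f.offset] += f.detected
        with np.errstate(invalid="ignore"):
            raw = np.where(tot > 0, hit / np.maximum(tot, 1), np.nan)
        curve.by_position_raw[s] = raw
        w = running_window
        run = np.full_like(raw, np.nan)
        for o in range(raw.size):
            win = raw[max(0, o - w + 1) : o + 1]
            win = win[~np.isnan(win)]
            if win.size:
                run[o] = win.mean()
        curve.by_position[s] = run
    return curve


def interpolate_sensitivity(curve: SensitivityCurve, sizes_evaluated=None):
    """Sensitivity as a function of arbitrary fragment length.

    Cubic spline through the measured (size, sensitivity) knots, clamped to
    [0, 1], constant-extrapolated beyond the measured range.  With two
    knots the spline degenerates to the linear interpolant; with fewer, a
    step function is returned with a warning.
    """
    sizes = sorted(sizes_evaluated if sizes_evaluated is not None else curve.by_size)
    ys = np.array([curve.by_size[s] for s in sizes], dtype=float)
    xs = np.array(sizes, dtype=float)
    if xs.size == 0:
        raise ValueError("no measured sizes to interpolate")
    if xs.size == 1:
        warnings.warn("single measured size; sensitivity treated as constant")
        y0 = float(ys[0])
        return lambda s: np.clip(np.full_like(np.asarray(s, float), y0), 0.0, 1.0)
    if xs.size == 2:
        return lambda s: np.clip(
            np.interp(np.asarray(s, float), xs, ys), 0.0, 1.0
        )
    cs = CubicSpline(xs, ys)

    def fn(s):
        s = np.asarray(s, dtype=float)
        v = cs(np.clip(s, xs[0], xs[-1]))
        return np.clip(v, 0.0, 1.0)

    return fn


@dataclass
class MissedBpReport:
    predicted_true: dict[int, float]
    observed: dict[int, int]
    missed_bp: float
    predicted_true_bp: float
    excluded_sizes: list[int]


def predict_missed_bp(
    observed: dict[int, int],
    sensitivity,
    bp_per_fragment: dict[int, int] | None = None,
) -> MissedBpReport:
    """Correct observed detection counts for size-specific sensitivity.

    predicted_true(s) = observed(s) / sensitivity(s); the missed bp total
    is sum over sizes of (predicted_true - observed) * bp-per-fragment
    (the fragment size itself unless overridden).  Sizes where the
    sensitivity function is 0 are excluded and reported, never divided by.
    """
    pred: dict[int, float] = {}
    excluded: list[int] = []
    missed = 0.0
    pred_bp = 0.0
    for s, obs in sorted(observed.items()):
        sens = float(np.asarray(sensitivity(s)))
        bp = s if bp_per_fragment is None else bp_per_fragment[s]
        if sens <= 0.0:
            excluded.append(s)
            log.warning("sensitivity 0 at size %d; %d observed fragments excluded", s, obs)
            continue
        p = obs / sens
        pred[s] = p
        missed += (p - obs) * bp
        pred_bp += p * bp
    return MissedBpReport(
        predicted_true=pred,
        observed=dict(observed),
        missed_bp=missed,
        predicted_true_bp=pred_bp,
        excluded_sizes=excluded,
    )
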