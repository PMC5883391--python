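"""Coverage histograms, peak detection and the four-state base partition.

The per-base depth distribution of a read-to-assembly mapping carries a
diagnostic signature: haplotype-separated sequence sits at the per-haplotype
coverage mode, collapsed (diploid-consensus) sequence near twice that,
under-represented repeats above, and bases near contig ends or mis-joins
below.  This module finds the haploid mode and the diploid shoulder in a
smoothed histogram and partitions assembly bases into the four states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alnio import DepthTrack
from .synthio import HAP_SEP, COLLAPSED, REPEAT_UNDERREP, BREAKPOINT

REPEAT = "REPEAT"  # partition label for high-coverage bases
STATE_ORDER = (BREAKPOINT, HAP_SEP, COLLAPSED, REPEAT)


@dataclass
class CoverageHistogram:
    """Counts of assembly bases at each integer depth (zero included)."""

    counts: np.ndarray  # counts[d] = bases at depth d

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or (self.counts.size and self.counts.min() < 0):
            raise ValueError("histogram counts must be a 1-D non-negative array")

    @property
    def total_bases(self) -> int:
        return int(self.counts.sum())

    @property
    def nonzero_bases(self) -> int:
        return int(self.counts[1:].sum())

    def as_dict(self) -> dict[int, int]:
        return {int(d): int(c) for d, c in enumerate(self.counts) if c}


@dataclass
class PeakModel:
    """Detected haploid mode, diploid shoulder and state boundaries.

    ``b_low`` separates breakpoint-adjacent low coverage from the haploid
    peak, ``b_mid`` the haploid peak from the diploid shoulder, ``b_high``
    the shoulder from repeat-level coverage.  ``fallback`` records which
    boundaries came from the fixed fractions of the mode rather than a
    detected local minimum.
    """

    mode: int
    shoulder: int | None
    b_low: float
    b_mid: float
    b_high: float
    mode_height: float = 0.0
    shoulder_height: float = 0.0
    fallback: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.b_low < self.mode < self.b_mid < self.b_high):
            raise ValueError(
                f"boundary ordering violated: 0 < {self.b_low} < {self.mode} "
                f"< {self.b_mid} < {self.b_high}")
        if self.shoulder is not None and not (self.b_mid < self.shoulder < self.b_high):
            raise ValueError("shoulder must lie between b_mid and b_high")


@dataclass
class StatePartition:
    """Bases per state plus the genome-size lower bound they imply.

    Zero-depth bases are reported separately, not assigned a state; the
    implied lower bound counts haplotype-separated bases once per haplotype
    pair (span/2) plus collapsed bases at face value.
    """

    spans: dict[str, int]
    zero_depth_bases: int
    total_bases: int
    implied_genome_lower_bound: int
    boundaries: PeakModel | None = None

    @property
    def fractions(self) -> dict[str, float]:
        nz = max(self.total_bases - self.zero_depth_bases, 1)
        return {s: self.spans[s] / nz for s in self.spans}


def histogram(track: DepthTrack) -> CoverageHistogram:
    """Tally bases per integer depth over all contigs (zero depth included)."""
    if track.total_bases == 0:
        raise ValueError("empty depth track")
    maxd = max((int(a.max()) if a.size else 0) for a in track.depths.values())
    counts = np.zeros(maxd + 1, dtype=np.int64)
    for a in track.depths.values():
        counts += np.bincount(a, minlength=maxd + 1)
    return CoverageHistogram(counts)


def _smooth(counts: np.ndarray, bandwidth: int) -> np.ndarray:
    w = max(1, int(bandwidth))
    kernel = np.ones(w) / w
    return np.convolve(counts.astype(float), kernel, mode="same")


def _local_minima(s: np.ndarray) -> np.ndarray:
    if s.size < 3:
        return np.empty(0, dtype=np.int64)
    interior = np.flatnonzero((s[1:-1] <= s[:-2]) & (s[1:-1] < s[2:])) + 1
    return interior


def fit_peaks(hist: CoverageHistogram, smooth_bandwidth: int = 5) -> PeakModel:
    """Locate the haploid mode, the ~2x shoulder and the state boundaries.

    The mode is the argmax of the smoothed histogram over depth >= 2 (the
    depth-1 bin is dominated by error/breakpoint artifacts).  A shoulder is
    accepted in the window [1.6x, 2.4x] of the mode when its smoothed height
    exceeds 25% of the mode peak.  Boundaries prefer detected local minima
    and fall back to mode/3, 1.5x mode and 2.5x mode.
    """
    if hist.nonzero_bases == 0:
        raise ValueError("histogram has no bases at depth >= 1")
    counts = hist.counts
    s = _smooth(counts, smooth_bandwidth)
    if counts.size <= 2:
        mode = int(np.flatnonzero(counts)[-1])
        mode = max(mode, 1)
        return PeakModel(mode=mode, shoulder=None, b_low=mode / 3,
                         b_mid=1.5 * mode, b_high=2.5 * mode,
                         mode_height=float(s[min(mode, s.size - 1)]),
                         fallback={"b_low": True, "b_mid": True, "b_high": True})
    def _argmax(lo: int, hi: int) -> int:
        """Argmax of the smoothed counts on [lo, hi]; plateau ties (smoothing
        flattens narrow peaks) break toward the largest raw count."""
        window = s[lo:hi + 1]
        best = window.max()
        cand = np.flatnonzero(window >= best * (1 - 1e-12)) + lo
        return int(cand[np.argmax(counts[cand])])

    lo = min(2, s.size - 1)
    mode = _argmax(lo, s.size - 1)
    mode_height = float(s[mode])

    w0, w1 = int(np.ceil(1.6 * mode)), int(np.floor(2.4 * mode))
    shoulder = None
    shoulder_height = 0.0
    if w0 < s.size and w1 >= w0:
        w1 = min(w1, s.size - 1)
        cand = _argmax(w0, w1)
        if s[cand] >= 0.25 * mode_height:
            shoulder = cand
            shoulder_height = float(s[cand])

    minima = _local_minima(s)
    fallback = {}

    in_low = minima[(minima > 0) & (minima < mode)]
    if in_low.size:
        b_low = float(in_low[np.argmin(s[in_low])])
    else:
        b_low, fallback["b_low"] = mode / 3, True
    if b_low <= 0:
        b_low, fallback["b_low"] = mode / 3, True

    upper_mid = shoulder if shoulder is not None else 2 * mode
    in_mid = minima[(minima > mode) & (minima < upper_mid)]
    if in_mid.size:
        b_mid = float(in_mid[np.argmin(s[in_mid])])
    else:
        b_mid, fallback["b_mid"] = 1.5 * mode, True

    if shoulder is not None:
        in_high = minima[(minima > shoulder) & (minima <= 4 * mode)]
        if in_high.size:
            b_high = float(in_high[np.argmin(s[in_high])])
        else:
            b_high, fallback["b_high"] = 2.5 * mode, True
    else:
        b_high, fallback["b_high"] = 2.5 * mode, True
    if b_high <= b_mid:
        b_high, fallback["b_high"] = max(2.5 * mode, b_mid + 1), True
    if shoulder is not None and not (b_mid < shoulder < b_high):
        shoulder = None
        shoulder_height = 0.0

    return PeakModel(mode=mode, shoulder=shoulder, b_low=b_low, b_mid=b_mid,
                     b_high=b_high, mode_height=mode_height,
                     shoulder_height=shoulder_height, fallback=fallback)


def partition_states(hist: CoverageHistogram, peaks: PeakModel) -> StatePartition:
    """Partition nonzero-depth bases into the four coverage states.

    BREAKPOINT: 0 < depth <= b_low; HAP_SEP: (b_low, b_mid];
    COLLAPSED: (b_mid, b_high]; REPEAT: depth > b_high.  Zero-depth bases
    are reported separately.  The implied genome lower bound is
    HAP_SEP/2 + COLLAPSED (half-up rounded).
    """
    if not (0 < peaks.b_low < peaks.b_mid < peaks.b_high):
        raise ValueError("boundary ordering violated")
    counts = hist.counts
    d = np.arange(counts.size)
    zero = int(counts[0]) if counts.size else 0
    spans = {
        BREAKPOINT: int(counts[(d > 0) & (d <= peaks.b_low)].sum()),
        HAP_SEP: int(counts[(d > peaks.b_low) & (d <= peaks.b_mid)].sum()),
        COLLAPSED: int(counts[(d > peaks.b_mid) & (d <= peaks.b_high)].sum()),
        REPEAT: int(counts[d > peaks.b_high].sum()),
    }
    bound = int(np.floor(spans[HAP_SEP] / 2 + spans[COLLAPSED] + 0.5))
    return StatePartition(spans=spans, zero_depth_bases=zero,
                          total_bases=hist.total_bases,
                          implied_genome_lower_bound=bound,
                          boundaries=peaks)


@dataclass
class ContigClass:
    state: str
    mean_depth: float
    state_bases: dict[str, int]


def classify_contigs(track: DepthTrack, peaks: PeakModel) -> dict[str, ContigClass]:
    """Label each contig by the state holding a plurality of its covered bases.

    Ties go to COLLAPSED (the conservative call: a collapsed contig is
    counted once toward genome size).  Contigs with no covered bases are
    labelled ``UNCOVERED``.
    """
    out: dict[str, ContigClass] = {}
    for name, arr in track.items():
        if arr.size == 0:
            out[name] = ContigClass("UNCOVERED", 0.0, {})
            continue
        spans = {
            BREAKPOINT: int(((arr > 0) & (arr <= peaks.b_low)).sum()),
            HAP_SEP: int(((arr > peaks.b_low) & (arr <= peaks.b_mid)).sum()),
            COLLAPSED: int(((arr > peaks.b_mid) & (arr <= peaks.b_high)).sum()),
            REPEAT: int((arr > peaks.b_high).sum()),
        }
        if sum(spans.values()) == 0:
            out[name] = ContigClass("UNCOVERED", float(arr.mean()), spans)
            continue
        best = max(spans.values())
        winners = [s for s in STATE_ORDER if spans[s] == best]
        state = COLLAPSED if len(winners) > 1 else winners[0]
        out[name] = ContigClass(state, float(arr.mean()), spans)
    return out


def write_histogram_tsv(hist: CoverageHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tbases\n")
        for depth, bases in enumerate(hist.counts.tolist()):
            if bases:
                fh.write(f"{depth}\t{bases}\n")


def read_histogram_tsv(path) -> CoverageHistogram:
    pairs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0].isdigit():
                continue
            pairs.append((int(parts[0]), int(parts[1])))
    maxd = max((d for d, _ in pairs), default=0)
    counts = np.zeros(maxd + 1, dtype=np.int64)
    for depth, bases in pairs:
        counts[depth] = bases
    return CoverageHistogram(counts)


def plot_partition(hist: CoverageHistogram, peaks: PeakModel, path,
                   max_depth: int | None = None) -> None:
    """Depth-versus-bases plot with the four state bands shaded (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = hist.counts
    md = max_depth or min(counts.size - 1, int(3.5 * peaks.mode))
    d = np.arange(1, md + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(d, counts[1:md + 1], color="black", lw=1)
    bands = [(0.5, peaks.b_low, "tab:green", "breakpoint"),
             (peaks.b_low, peaks.b_mid, "tab:blue", "haplotype-separated"),
             (peaks.b_mid, peaks.b_high, "tab:olive", "collapsed"),
             (peaks.b_high, md, "tab:red", "repeat")]
    for x0, x1, color, label in bands:
        ax.axvspan(x0, min(x1, md), alpha=0.2, color=color, label=label)
    ax.set_xlabel("per-base read depth")
    ax.set_ylabel("assembly bases")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
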