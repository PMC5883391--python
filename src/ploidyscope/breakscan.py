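"""Within-contig coverage-shift detection and contig splitting.

An abrupt change in read depth inside a contig is the signature of foreign
(e.g., endosymbiont) sequence or a chimeric join.  Detection is greedy
binary segmentation on window-mean depth; flagged segments can then be cut
out of the contig, mirroring the resubmission action of removing a
contaminant region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alnio import DepthTrack


@dataclass
class ShiftSegment:
    """A contig interval whose mean depth differs fold_threshold-fold from
    its flanks."""

    contig: str
    start: int
    end: int
    inner_mean_depth: float
    flank_mean_depth: float

    @property
    def fold(self) -> float:
        lo = min(self.inner_mean_depth, self.flank_mean_depth)
        hi = max(self.inner_mean_depth, self.flank_mean_depth)
        return hi / max(lo, 1e-9)


def _best_split(cum: np.ndarray, lo: int, hi: int, min_win: int) -> tuple[int, float]:
    """Changepoint in window-index range [lo, hi) maximising the weighted
    between-segment mean difference (the split with the largest SSE drop)."""
    n = hi - lo
    if n < 2 * min_win:
        return -1, 0.0
    k = np.arange(lo + min_win, hi - min_win + 1)
    if k.size == 0:
        return -1, 0.0
    left_n = k - lo
    right_n = hi - k
    left_mean = (cum[k] - cum[lo]) / left_n
    right_mean = (cum[hi] - cum[k]) / right_n
    gain = left_n * right_n / n * (left_mean - right_mean) ** 2
    j = int(np.argmax(gain))
    return int(k[j]), float(np.abs(left_mean[j] - right_mean[j]))


def _fold(a: float, b: float) -> float:
    lo, hi = min(a, b), max(a, b)
    return hi / max(lo, 1e-9)


def detect_shifts(track: DepthTrack,
                  min_segment: int = 5000,
                  fold_threshold: float = 2.0,
                  window: int = 1000) -> list[ShiftSegment]:
    """Flag contig segments whose depth steps >= fold_threshold vs the flanks.

    Greedy binary segmentation on ``window``-mean depth: recursively place
    the changepoint with the largest between-segment mean difference, accept
    it while the two sides differ by at least ``fold_threshold``-fold, stop
    when segments would fall below ``min_segment``.  Contigs shorter than
    3 x min_segment are skipped.  Boundaries are reported at window
    resolution.
    """
    if min_segment < window:
        raise ValueError("min_segment must be >= window")
    out: list[ShiftSegment] = []
    min_win = max(1, min_segment // window)
    for name, arr in track.items():
        L = arr.size
        if L < 3 * min_segment:
            continue
        nw = L // window
        means = arr[:nw * window].reshape(nw, window).mean(axis=1)
        cum = np.concatenate(([0.0], np.cumsum(means)))

        cuts: set[int] = set()

        def recurse(lo: int, hi: int) -> None:
            k, _ = _best_split(cum, lo, hi, min_win)
            if k < 0:
                return
            # judge the candidate on the depth step across it locally, so an
            # interior bump is not averaged away by long matching flanks
            l0 = max(lo, k - min_win)
            r1 = min(hi, k + min_win)
            lmean = (cum[k] - cum[l0]) / (k - l0)
            rmean = (cum[r1] - cum[k]) / (r1 - k)
            if _fold(lmean, rmean) < fold_threshold:
                return
            cuts.add(k)
            recurse(lo, k)
            recurse(k, hi)

        recurse(0, nw)
        if not cuts:
            continue
        bounds = [0, *sorted(cuts), nw]
        seg_lens = [b - a for a, b in zip(bounds, bounds[1:])]
        seg_means = [(cum[b] - cum[a]) / (b - a) for a, b in zip(bounds, bounds[1:])]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            flank_means, flank_len = [], 0
            if i > 0:
                flank_means.append(seg_means[i - 1])
                flank_len += seg_lens[i - 1]
            if i + 1 < len(seg_means):
                flank_means.append(seg_means[i + 1])
                flank_len += seg_lens[i + 1]
            flank = float(np.mean(flank_means))
            inner = seg_means[i]
            if _fold(inner, flank) < fold_threshold:
                continue
            if seg_lens[i] >= flank_len:
                continue  # flag the local anomaly, not the background
            start = a * window
            end = b * window if b < nw else L
            if end - start < min_segment:
                continue
            out.append(ShiftSegment(contig=name, start=start, end=end,
                                    inner_mean_depth=float(inner),
                                    flank_mean_depth=flank))
    return out


def split_at(contigs: Mapping[str, str],
             segments: Sequence[ShiftSegment]):
    """Remove flagged segments from their contigs.

    Each flagged contig is replaced by its left and right flanks (empty
    flanks dropped); the removed sequence is returned separately so nothing
    is lost.  Returns ``(new_contigs, removed, mapping)`` where ``mapping``
    rows are (new_name, old_name, old_start, old_end).
    """
    by_contig: dict[str, list[ShiftSegment]] = {}
    for s in segments:
        if s.contig not in contigs:
            raise KeyError(f"segment references unknown contig {s.contig!r}")
        L = len(contigs[s.contig])
        if not (0 <= s.start < s.end <= L):
            raise ValueError(f"segment [{s.start},{s.end}) outside {s.contig} (len {L})")
        by_contig.setdefault(s.contig, []).append(s)
    for name, segs in by_contig.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments on {name}")

    new_contigs: dict[str, str] = {}
    removed: dict[str, str] = {}
    mapping: list[tuple[str, str, int, int]] = []
    for name, seq in contigs.items():
        segs = by_contig.get(name)
        if not segs:
            new_contigs[name] = seq
            mapping.append((name, name, 0, len(seq)))
            continue
        part = 1
        cursor = 0
        for i, s in enumerate(segs, 1):
            if s.start > cursor:
                nn = f"{name}_part{part}"
                new_contigs[nn] = seq[cursor:s.start]
                mapping.append((nn, name, cursor, s.start))
                part += 1
            rn = f"{name}_removed{i}"
            removed[rn] = seq[s.start:s.end]
            mapping.append((rn, name, s.start, s.end))
            cursor = s.end
        if cursor < len(seq):
            nn = f"{name}_part{part}"
            new_contigs[nn] = seq[cursor:]
            mapping.append((nn, name, cursor, len(seq)))
    return new_contigs, removed, mapping


def write_segments_bed(segments: Sequence[ShiftSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t"
                     f"fold={s.fold:.2f};inner={s.inner_mean_depth:.1f};"
                     f"flank={s.flank_mean_depth:.1f}\n")


def write_mapping_tsv(mapping, path) -> None:
    with open(path, "w") as fh:
        fh.write("new_name\told_name\told_start\told_end\n")
        for row in mapping:
            fh.write("\t".join(str(x) for x in row) + "\n")
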