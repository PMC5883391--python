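"""Read-mapping metrics for host-subtraction benchmarking.

Per-pair concordance classes, mapping-site multiplicity (how many candidate
concordant placements a pair has), the read-vs-consensus disagreement rate,
and a side-by-side comparison of two references.  All fraction sets are
exact partitions of their denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alnio import SamRecord

PAIR_CLASSES = ("concordant", "discordant", "single_end_only", "unmapped")
SITE_CLASSES = ("zero", "one", "multiple")


@dataclass
class PairReport:
    total_pairs: int
    fractions: dict[str, float]
    mode: str
    unpaired_reads: int = 0

    def __post_init__(self):
        if self.total_pairs and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("pair-class fractions must sum to 1")


@dataclass
class SiteReport:
    total_pairs: int
    fractions: dict[str, float]

    def __post_init__(self):
        if self.total_pairs and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("site-class fractions must sum to 1")


@dataclass
class DisagreementReport:
    mismatch_bases: int
    aligned_bases: int
    skipped_records: int = 0

    @property
    def rate(self) -> float:
        return self.mismatch_bases / self.aligned_bases if self.aligned_bases else 0.0


def _pairs(records: Iterable[SamRecord]):
    """Group primary records of paired reads into (mate1, mate2) tuples."""
    by_name: dict[str, dict[int, SamRecord]] = {}
    unpaired = 0
    for r in records:
        if r.is_secondary:
            continue
        if not r.is_paired:
            unpaired += 1
            continue
        slot = 1 if r.is_read1 else 2
        by_name.setdefault(r.qname, {})[slot] = r
    pairs = []
    for name in by_name:
        d = by_name[name]
        if len(d) == 2:
            pairs.append((d[1], d[2]))
        else:
            unpaired += 1
    return pairs, unpaired


def pair_classes(records: Sequence[SamRecord], mode: str = "local") -> PairReport:
    """Concordant / discordant / single-end-only / unmapped pair fractions.

    A pair is concordant iff both mates are mapped with the proper-pair flag
    set.  Unpaired reads in the input are counted, warned about and excluded
    from the fractions.
    """
    pairs, unpaired = _pairs(records)
    if unpaired:
        warnings.warn(f"{unpaired} unpaired read(s) excluded from pair classes")
    counts = dict.fromkeys(PAIR_CLASSES, 0)
    for r1, r2 in pairs:
        m1, m2 = not r1.is_unmapped, not r2.is_unmapped
        if m1 and m2 and r1.is_proper_pair and r2.is_proper_pair:
            counts["concordant"] += 1
        elif m1 and m2:
            counts["discordant"] += 1
        elif m1 or m2:
            counts["single_end_only"] += 1
        else:
            counts["unmapped"] += 1
    n = len(pairs)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return PairReport(total_pairs=n, fractions=fractions, mode=mode,
                      unpaired_reads=unpaired)


def site_classes(records: Sequence[SamRecord], multi_reported: bool = True) -> SiteReport:
    """Fractions of pairs with zero, one or multiple concordant mapping sites.

    Requires an alignment source that reported *all* candidate placements
    (secondary records included); with single-best input the zero/one/multi
    split is meaningless, so ``multi_reported=False`` refuses to compute.
    A site is a distinct (contig, mate1 position, mate2 position) with the
    proper-pair flag set on both mates.
    """
    if not multi_reported:
        raise ValueError(
            "site_classes needs alignments with all candidate sites reported; "
            "refusing single-best input")
    pairs, _ = _pairs(records)
    placements: dict[str, set[tuple]] = {}
    for r in records:
        if not r.is_paired or r.is_unmapped or not r.is_proper_pair:
            continue
        key = (r.rname, min(r.pos, r.pnext), max(r.pos, r.pnext))
        placements.setdefault(r.qname, set()).add(key)
    counts = dict.fromkeys(SITE_CLASSES, 0)
    for r1, r2 in pairs:
        k = len(placements.get(r1.qname, ()))
        counts["zero" if k == 0 else "one" if k == 1 else "multiple"] += 1
    n = len(pairs)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return SiteReport(total_pairs=n, fractions=fractions)


def disagreement_rate(records: Sequence[SamRecord],
                      mode: str = "end_to_end") -> DisagreementReport:
    """Edit-distance disagreement between read sequence and contig consensus.

    rate = sum(NM) / sum(aligned read bases) over mapped primary records.
    Records without an NM tag are skipped with a warning and counted.
    Meant for global (end-to-end) alignments, where soft-clipping does not
    hide disagreement; ``mode`` is recorded for report provenance.
    """
    mism = aligned = skipped = 0
    for r in records:
        if r.is_unmapped or r.is_secondary:
            continue
        if r.nm is None:
            skipped += 1
            continue
        mism += r.nm
        aligned += r.aligned_read_bases
    if skipped:
        warnings.warn(f"{skipped} mapped record(s) without NM tag skipped")
    return DisagreementReport(mismatch_bases=mism, aligned_bases=aligned,
                              skipped_records=skipped)


def mapped_read_fraction(records: Sequence[SamRecord]) -> float:
    """Fraction of reads mapped, pairing ignored (primary records only)."""
    total = mapped = 0
    for r in records:
        if r.is_secondary:
            continue
        total += 1
        mapped += not r.is_unmapped
    return mapped / total if total else 0.0


def subtraction_summary(reports_a: dict, reports_b: dict,
                        label_a: str = "A", label_b: str = "B") -> dict:
    """Side-by-side metric table for two candidate host references.

    ``reports_a``/``reports_b`` may hold any of the keys ``pairs``
    (PairReport), ``sites`` (SiteReport), ``disagreement``
    (DisagreementReport) and ``mapped_fraction`` (float).  Modes must match.
    """
    pa, pb = reports_a.get("pairs"), reports_b.get("pairs")
    if pa is not None and pb is not None and pa.mode != pb.mode:
        raise ValueError(f"alignment-mode mismatch: {pa.mode} vs {pb.mode}")
    rows = []

    def add(metric, va, vb):
        rows.append({"metric": metric, label_a: va, label_b: vb,
                     "delta": None if va is None or vb is None else va - vb})

    if pa is not None and pb is not None:
        for c in PAIR_CLASSES:
            add(f"pair_{c}", pa.fractions[c], pb.fractions[c])
    sa, sb = reports_a.get("sites"), reports_b.get("sites")
    if sa is not None and sb is not None:
        for c in SITE_CLASSES:
            add(f"sites_{c}", sa.fractions[c], sb.fractions[c])
    da, db = reports_a.get("disagreement"), reports_b.get("disagreement")
    if da is not None and db is not None:
        add("disagreement_rate", da.rate, db.rate)
    ma, mb = reports_a.get("mapped_fraction"), reports_b.get("mapped_fraction")
    if ma is not None and mb is not None:
        add("mapped_fraction", ma, mb)
    return {"labels": (label_a, label_b), "rows": rows}
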