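"""Whole-genome-alignment multiplicity: best-per-query filtering, containment
statistics and 1:N classification.

A reference contig aligning substantially to two contigs of the other
assembly (a 1:2 relation) is the signature of haplotype separation: the two
query contigs are the two haplotypes of that locus.  Filtering to one best
alignment per query position first keeps a repeat-rich query from inflating
the counts.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alnio import AlignmentRecord

CLASSES = ("1:1", "1:2", "1:3+", "uncategorized")


@dataclass
class ContainmentStats:
    """Reference-base fractions covered by alignments above a length floor.

    ``any_alignment`` is the fraction of reference bases in contigs with at
    least one qualifying alignment; ``by_level[c]`` restricts to contigs
    with >= c of their length covered by a single alignment (non-increasing
    in c).
    """

    any_alignment: float
    by_level: dict[float, float]
    min_aln_len: int

    def __post_init__(self):
        for f in [self.any_alignment, *self.by_level.values()]:
            if not (0 <= f <= 1):
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class MultiplicityTable:
    """Base-weighted class fractions plus the per-reference-contig detail."""

    fractions: dict[str, float]
    per_contig: dict[str, dict]
    min_cov: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")


def _weight(r: AlignmentRecord) -> float:
    return r.alnlen * r.identity


def best_per_query(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Maximum-weight set of query-disjoint alignments, per query sequence.

    Weight is alnlen x identity (= matched bases).  Weighted interval
    scheduling on the query intervals; every query base is covered by at
    most one retained alignment.  Ties are resolved deterministically by the
    sort order (higher identity, then longer alignment, then reference name).
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.qname, []).append(r)
    kept: list[AlignmentRecord] = []
    for qname in sorted(by_query):
        rs = sorted(by_query[qname],
                    key=lambda r: (r.qend, r.qstart, -r.identity, -r.alnlen, r.rname))
        n = len(rs)
        ends = [r.qend for r in rs]
        # p[i]: rightmost j < i with rs[j].qend <= rs[i].qstart
        p = [bisect.bisect_right(ends, rs[i].qstart) - 1 for i in range(n)]
        dp = [0.0] * (n + 1)
        take = [False] * n
        for i in range(n):
            w = _weight(rs[i]) + dp[p[i] + 1]
            if w >= dp[i] - 1e-12:  # prefer taking on ties: deterministic
                dp[i + 1] = w
                take[i] = True
            else:
                dp[i + 1] = dp[i]
        chosen = []
        i = n
        while i > 0:
            if take[i - 1]:
                chosen.append(rs[i - 1])
                i = p[i - 1] + 1
            else:
                i -= 1
        kept.extend(reversed(chosen))
    return kept


def containment_stats(records: Iterable[AlignmentRecord],
                      ref_lengths: Mapping[str, int],
                      min_aln_len: int = 1000,
                      coverage_levels: Sequence[float] = (0.5, 0.9)) -> ContainmentStats:
    """Reference-base fractions with >= 1 alignment of ``min_aln_len`` or
    more, and with >= c of the contig covered by any single alignment."""
    best_cov: dict[str, float] = {}
    has_any: set[str] = set()
    for r in records:
        if r.rname not in ref_lengths:
            raise KeyError(f"alignment references unknown contig {r.rname!r}")
        if r.alnlen < min_aln_len:
            continue
        has_any.add(r.rname)
        cov = r.ref_span / ref_lengths[r.rname]
        if cov > best_cov.get(r.rname, 0.0):
            best_cov[r.rname] = cov
    total = sum(ref_lengths.values())
    if total == 0:
        raise ValueError("empty reference")
    any_frac = sum(ref_lengths[n] for n in has_any) / total
    by_level = {
        float(c): sum(ref_lengths[n] for n, v in best_cov.items() if v >= c) / total
        for c in coverage_levels
    }
    return ContainmentStats(any_alignment=any_frac, by_level=by_level,
                            min_aln_len=min_aln_len)


def classify_multiplicity(best: Sequence[AlignmentRecord],
                          ref_lengths: Mapping[str, int],
                          min_cov: float = 0.5) -> MultiplicityTable:
    """Classify reference contigs by how many query contigs cover them.

    ``best`` must be query-disjoint (the output of :func:`best_per_query`).
    A reference contig is categorized iff some single retained alignment
    covers at least ``min_cov`` of it; its N is the number of distinct query
    contigs with such an alignment; classes are N = 1, 2, >= 3.  Fractions
    are weighted by reference contig length; everything else is
    uncategorized.
    """
    if not (0 < min_cov <= 1):
        raise ValueError("min_cov must be in (0, 1]")
    qualifying: dict[str, set[str]] = {}
    for r in best:
        if r.rname not in ref_lengths:
            raise KeyError(f"alignment references unknown contig {r.rname!r}")
        if r.ref_span / ref_lengths[r.rname] >= min_cov:
            qualifying.setdefault(r.rname, set()).add(r.qname)
    per_contig: dict[str, dict] = {}
    bases = {c: 0 for c in CLASSES}
    for rname in sorted(ref_lengths):
        partners = sorted(qualifying.get(rname, ()))
        n = len(partners)
        if n == 0:
            cls = "uncategorized"
        elif n == 1:
            cls = "1:1"
        elif n == 2:
            cls = "1:2"
        else:
            cls = "1:3+"
        per_contig[rname] = {"class": cls, "n_partners": n, "partners": partners,
                             "length": int(ref_lengths[rname])}
        bases[cls] += int(ref_lengths[rname])
    total = sum(ref_lengths.values())
    fractions = {c: bases[c] / total for c in CLASSES}
    return MultiplicityTable(fractions=fractions, per_contig=per_contig,
                             min_cov=min_cov)


def write_multiplicity_tsv(table: MultiplicityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tlength\tclass\tn_partners\tpartners\n")
        for name, row in table.per_contig.items():
            fh.write(f"{name}\t{row['length']}\t{row['class']}\t"
                     f"{row['n_partners']}\t{','.join(row['partners'])}\n")
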