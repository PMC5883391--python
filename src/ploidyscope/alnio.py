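"""Readers and writers for alignment and depth formats, plus basic assembly statistics.

Every coordinate held in memory is 0-based, half-open.  The 1-based
conventions of SAM, samtools-depth TSV and nucmer show-coords are converted
at the file boundary, in both directions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class MalformedLineError(ValueError):
    """A line in an input file could not be parsed; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One local alignment between a query and a reference sequence.

    The shared carrier for PAF, show-coords and (mapped) SAM alignments.
    ``matches``/``alnlen`` give the identity; ``nm`` is the edit distance
    when the source format provides one.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    rname: str
    rlen: int
    rstart: int
    rend: int
    matches: int
    alnlen: int
    mapq: int | None = None
    is_secondary: bool = False
    nm: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"query interval [{self.qstart},{self.qend}) outside [0,{self.qlen}]"
            )
        if not (0 <= self.rstart < self.rend <= self.rlen):
            raise ValueError(
                f"reference interval [{self.rstart},{self.rend}) outside [0,{self.rlen}]"
            )
        if not (0 <= self.matches <= self.alnlen):
            raise ValueError(f"matches {self.matches} outside [0,{self.alnlen}]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def identity(self) -> float:
        return self.matches / self.alnlen

    @property
    def ref_span(self) -> int:
        return self.rend - self.rstart

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart


# ---------------------------------------------------------------------------
# SAM records
# ---------------------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class SamRecord:
    """A single SAM alignment line (0-based ``pos``)."""

    qname: str
    flag: int
    rname: str | None
    pos: int
    mapq: int
    cigar: str
    rnext: str | None = None
    pnext: int = -1
    tlen: int = 0
    seq: str | None = None
    nm: int | None = None

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FLAG_READ2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    def cigar_ops(self) -> list[tuple[int, str]]:
        return [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for n, op in self.cigar_ops() if op in "MDN=X")

    @property
    def aligned_read_bases(self) -> int:
        """Number of read bases that take part in the alignment (clips excluded)."""
        return sum(n for n, op in self.cigar_ops() if op in "MI=X")

    @property
    def rstart(self) -> int:
        return self.pos

    @property
    def rend(self) -> int:
        return self.pos + self.reference_span


def read_sam(path) -> list[SamRecord]:
    """Parse a SAM file (through pysam); unmapped records are kept."""
    out: list[SamRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh.fetch(until_eof=True):
            nm = a.get_tag("NM") if a.has_tag("NM") else None
            out.append(
                SamRecord(
                    qname=a.query_name,
                    flag=a.flag,
                    rname=None if a.is_unmapped else a.reference_name,
                    pos=-1 if a.is_unmapped else a.reference_start,
                    mapq=a.mapping_quality,
                    cigar=a.cigarstring or "*",
                    rnext=a.next_reference_name if a.next_reference_id >= 0 else None,
                    pnext=a.next_reference_start,
                    tlen=a.template_length,
                    seq=a.query_sequence,
                    nm=nm,
                )
            )
    return out


def write_sam(records: Iterable[SamRecord], contig_lengths: Mapping[str, int], path) -> None:
    """Write records as plain SAM text with an @SQ header per contig."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{int(length)}\n")
        for r in records:
            rname = r.rname if r.rname is not None else "*"
            pos1 = r.pos + 1 if r.rname is not None else 0
            if r.rnext is None:
                rnext = "*"
            elif r.rnext == r.rname:
                rnext = "="
            else:
                rnext = r.rnext
            pnext1 = r.pnext + 1 if r.rnext is not None else 0
            seq = r.seq if r.seq else "*"
            qual = "I" * len(seq) if seq != "*" else "*"
            fields = [
                r.qname, str(r.flag), rname, str(pos1), str(r.mapq),
                r.cigar, rnext, str(pnext1), str(r.tlen), seq, qual,
            ]
            if r.nm is not None:
                fields.append(f"NM:i:{r.nm}")
            fh.write("\t".join(fields) + "\n")


def sam_to_alignment_records(records: Iterable[SamRecord],
                             contig_lengths: Mapping[str, int],
                             read_lengths: Mapping[str, int] | None = None
                             ) -> list[AlignmentRecord]:
    """Convert mapped SAM records to :class:`AlignmentRecord`.

    Identity comes from the NM tag as (alnlen - NM) / alnlen; records without
    NM get identity 1.0.
    """
    out = []
    for r in records:
        if r.is_unmapped or r.rname is None:
            continue
        ops = r.cigar_ops()
        lead = ops[0][0] if ops and ops[0][1] in "SH" else 0
        aligned = r.aligned_read_bases
        qlen = aligned + sum(n for n, op in ops if op in "SH")
        if read_lengths and r.qname in read_lengths:
            qlen = read_lengths[r.qname]
        alnlen = max(aligned, r.reference_span)
        nm = r.nm if r.nm is not None else 0
        out.append(
            AlignmentRecord(
                qname=r.qname, qlen=qlen, qstart=lead, qend=lead + aligned,
                strand="-" if r.is_reverse else "+",
                rname=r.rname, rlen=int(contig_lengths[r.rname]),
                rstart=r.rstart, rend=r.rend,
                matches=max(0, alnlen - nm), alnlen=alnlen,
                mapq=r.mapq, is_secondary=r.is_secondary, nm=r.nm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path) -> list[AlignmentRecord]:
    """Read a PAF file (12 mandatory columns; NM:i and tp:A tags honoured)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise MalformedLineError(path, lineno, "PAF needs >= 12 columns")
            try:
                qname, qlen, qstart, qend, strand = cols[0], int(cols[1]), int(cols[2]), int(cols[3]), cols[4]
                rname, rlen, rstart, rend = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
                matches, alnlen, mapq = int(cols[9]), int(cols[10]), int(cols[11])
            except ValueError as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
            nm = None
            secondary = False
            for tag in cols[12:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
                elif tag.startswith("tp:A:"):
                    secondary = tag[5:] in ("S", "s")
            try:
                out.append(
                    AlignmentRecord(
                        qname=qname, qlen=qlen, qstart=qstart, qend=qend,
                        strand=strand, rname=rname, rlen=rlen, rstart=rstart,
                        rend=rend, matches=matches, alnlen=alnlen,
                        mapq=None if mapq == 255 else mapq,
                        is_secondary=secondary, nm=nm,
                    )
                )
            except ValueError as exc:
                warnings.warn(f"{path}:{lineno}: rejected record: {exc}")
    return out


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            mapq = 255 if r.mapq is None else r.mapq
            cols = [
                r.qname, r.qlen, r.qstart, r.qend, r.strand,
                r.rname, r.rlen, r.rstart, r.rend, r.matches, r.alnlen, mapq,
                f"tp:A:{'S' if r.is_secondary else 'P'}",
            ]
            if r.nm is not None:
                cols.append(f"NM:i:{r.nm}")
            fh.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# nucmer show-coords (tab dialect)
# ---------------------------------------------------------------------------

def read_coords(path,
                ref_lengths: Mapping[str, int] | None = None,
                query_lengths: Mapping[str, int] | None = None) -> list[AlignmentRecord]:
    """Read the tab dialect of nucmer show-coords (``show-coords -T [-l]``).

    Columns: S1 E1 S2 E2 LEN1 LEN2 %IDY [LENR LENQ [COVR COVQ]] R Q, with
    1-based inclusive coordinates; reference first.  Reverse-strand records
    (E2 < S2) are normalised to ascending coordinates with strand '-'.
    Without the -l length columns, ``ref_lengths``/``query_lengths`` must be
    supplied.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            first = line.split("\t")[0].split()[0] if line.split("\t") else ""
            try:
                int(first)
            except ValueError:
                continue  # header / banner lines
            cols = line.split("\t")
            if len(cols) < 9:
                raise MalformedLineError(path, lineno, "coords tab dialect needs >= 9 columns")
            try:
                s1, e1, s2, e2 = (int(c) for c in cols[:4])
                len1, len2 = int(cols[4]), int(cols[5])
                idy = float(cols[6]) / 100.0
            except ValueError as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
            rname, qname = cols[-2], cols[-1]
            extras = cols[7:-2]
            lenr = lenq = None
            ints = [c for c in extras if re.fullmatch(r"\d+", c)]
            if len(ints) >= 2:
                lenr, lenq = int(ints[0]), int(ints[1])
            if lenr is None:
                if ref_lengths is None or query_lengths is None:
                    raise MalformedLineError(
                        path, lineno,
                        "no LENR/LENQ columns: pass ref_lengths and query_lengths")
                lenr, lenq = int(ref_lengths[rname]), int(query_lengths[qname])
            rstart, rend = s1 - 1, e1
            if s2 <= e2:
                strand, qstart, qend = "+", s2 - 1, e2
            else:
                strand, qstart, qend = "-", e2 - 1, s2
            alnlen = max(len1, len2)
            matches = int(round(idy * alnlen))
            try:
                out.append(
                    AlignmentRecord(
                        qname=qname, qlen=lenq, qstart=qstart, qend=qend,
                        strand=strand, rname=rname, rlen=lenr,
                        rstart=rstart, rend=rend, matches=matches, alnlen=alnlen,
                    )
                )
            except ValueError as exc:
                warnings.warn(f"{path}:{lineno}: rejected record: {exc}")
    return out


def write_coords(records: Iterable[AlignmentRecord], path) -> None:
    """Write records in the show-coords -T -l tab dialect (reference first)."""
    with open(path, "w") as fh:
        fh.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[LEN R]\t[LEN Q]\t[TAGS]\n")
        for r in records:
            s1, e1 = r.rstart + 1, r.rend
            if r.strand == "+":
                s2, e2 = r.qstart + 1, r.qend
            else:
                s2, e2 = r.qend, r.qstart + 1
            len1 = r.rend - r.rstart
            len2 = r.qend - r.qstart
            idy = 100.0 * r.matches / r.alnlen
            fh.write(
                f"{s1}\t{e1}\t{s2}\t{e2}\t{len1}\t{len2}\t{idy:.4f}\t"
                f"{r.rlen}\t{r.qlen}\t{r.rname}\t{r.qname}\n"
            )


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

class DepthTrack:
    """Per-contig, per-base read coverage (non-negative integers)."""

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self.depths: dict[str, np.ndarray] = {}
        for name, arr in depths.items():
            a = np.asarray(arr, dtype=np.int64)
            if a.ndim != 1:
                raise ValueError(f"{name}: depth array must be 1-D")
            if a.size and a.min() < 0:
                raise ValueError(f"{name}: negative depth")
            self.depths[name] = a

    def __getitem__(self, name: str) -> np.ndarray:
        return self.depths[name]

    def __contains__(self, name: str) -> bool:
        return name in self.depths

    def __iter__(self):
        return iter(self.depths)

    def items(self):
        return self.depths.items()

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {n: int(a.size) for n, a in self.depths.items()}

    @property
    def total_bases(self) -> int:
        return int(sum(a.size for a in self.depths.values()))

    @property
    def total_depth(self) -> int:
        """Sum of all per-base depth values == total aligned bases."""
        return int(sum(int(a.sum()) for a in self.depths.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        return self.depths.keys() == other.depths.keys() and all(
            np.array_equal(self.depths[k], other.depths[k]) for k in self.depths
        )


def depth_from_alignments(records: Iterable,
                          contig_lengths: Mapping[str, int],
                          include_secondary: bool = False) -> DepthTrack:
    """Per-base depth from alignment reference intervals.

    Accepts :class:`AlignmentRecord` or mapped :class:`SamRecord` items.
    Secondary records are excluded unless asked for.
    """
    diffs = {n: np.zeros(int(l) + 1, dtype=np.int64) for n, l in contig_lengths.items()}
    for r in records:
        if isinstance(r, SamRecord):
            if r.is_unmapped or r.rname is None:
                continue
            rname, rstart, rend, secondary = r.rname, r.rstart, r.rend, r.is_secondary
        else:
            rname, rstart, rend, secondary = r.rname, r.rstart, r.rend, r.is_secondary
        if secondary and not include_secondary:
            continue
        if rname not in diffs:
            raise KeyError(f"alignment references unknown contig {rname!r}")
        length = len(diffs[rname]) - 1
        if rend > length or rstart < 0:
            raise ValueError(
                f"alignment [{rstart},{rend}) beyond contig {rname} length {length}")
        diffs[rname][rstart] += 1
        diffs[rname][rend] -= 1
    return DepthTrack({n: np.cumsum(d[:-1]) for n, d in diffs.items()})


def read_depth_tsv(path, contig_lengths: Mapping[str, int] | None = None) -> DepthTrack:
    """Read samtools-depth-style TSV (contig, 1-based position, depth).

    Positions missing from the file are taken as depth 0; without
    ``contig_lengths`` each contig's length is the largest position seen.
    """
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MalformedLineError(path, lineno, "expected 3 columns")
            try:
                rows.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
    depths = {}
    names = list(rows)
    if contig_lengths is not None:
        names = list(contig_lengths)
    for name in names:
        pairs = rows.get(name, [])
        length = max((p for p, _ in pairs), default=0)
        if contig_lengths is not None:
            length = int(contig_lengths[name])
        arr = np.zeros(length, dtype=np.int64)
        for pos1, d in pairs:
            arr[pos1 - 1] = d
        depths[name] = arr
    return DepthTrack(depths)


def write_depth_tsv(track: DepthTrack, path) -> None:
    """Write every position (1-based), including zero-depth bases."""
    with open(path, "w") as fh:
        for name, arr in track.items():
            lines = "\n".join(f"{name}\t{i + 1}\t{v}" for i, v in enumerate(arr.tolist()))
            if lines:
                fh.write(lines + "\n")


def read_bedgraph(path, contig_lengths: Mapping[str, int] | None = None) -> DepthTrack:
    runs: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise MalformedLineError(path, lineno, "expected 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), int(float(parts[3]))
            except ValueError as exc:
                raise MalformedLineError(path, lineno, str(exc)) from exc
            runs.setdefault(parts[0], []).append((start, end, value))
    depths = {}
    names = list(contig_lengths) if contig_lengths is not None else list(runs)
    for name in names:
        ivals = sorted(runs.get(name, []))
        for (s1, e1, _), (s2, e2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"{name}: overlapping bedGraph intervals [{s1},{e1}) and [{s2},{e2})")
        length = max((e for _, e, _ in ivals), default=0)
        if contig_lengths is not None:
            length = int(contig_lengths[name])
        arr = np.zeros(length, dtype=np.int64)
        for s, e, v in ivals:
            arr[s:e] = v
        depths[name] = arr
    return DepthTrack(depths)


def write_bedgraph(track: DepthTrack, path) -> None:
    """Write maximal runs (adjacent equal-depth positions merged); zero runs kept."""
    with open(path, "w") as fh:
        for name, arr in track.items():
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{name}\t{s}\t{e}\t{int(arr[s])}\n")


# ---------------------------------------------------------------------------
# Assembly statistics / FASTA helpers
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    contig_count: int
    span: int
    n50: int
    max_contig: int


def assembly_stats(contigs) -> AssemblyStats:
    """Contig count, span, N50 and longest contig.

    ``contigs`` may be a mapping name -> sequence or an iterable of lengths.
    N50 is the largest length L such that contigs of length >= L jointly
    cover at least half the span.
    """
    if isinstance(contigs, Mapping):
        lengths = [len(s) for s in contigs.values()]
    else:
        lengths = [int(x) for x in contigs]
    if not lengths:
        raise ValueError("empty contig set")
    lengths.sort(reverse=True)
    span = sum(lengths)
    half = span / 2
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= half:
            n50 = L
            break
    return AssemblyStats(contig_count=len(lengths), span=span, n50=n50,
                         max_contig=lengths[0])


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fai(path) -> dict[str, int]:
    """Contig lengths from a samtools .fai index."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) >= 2:
                out[parts[0]] = int(parts[1])
    return out
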