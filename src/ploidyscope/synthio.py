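"""Synthetic diploid genomes, state-annotated assemblies, reads and truth alignments.

The generator emulates the situation the rest of the package diagnoses: a
heterozygous diploid genome with interspersed repeat families, an assembly
in which a planned fraction of loci is haplotype-separated (both alleles
emitted as separate contigs), collapsed (one consensus contig, haplotype A's
sequence by convention) or repeat-under-represented (one exemplar copy kept,
the others omitted), and reads whose true origins are recorded so that an
oracle mapper can place them on the assembly without an external aligner.

All coordinates are 0-based half-open.  Everything is driven by
``numpy.random.default_rng`` seeds: the same configuration yields
byte-identical FASTA/FASTQ/SAM/BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alnio import (AlignmentRecord, DepthTrack, SamRecord, FLAG_PAIRED,
                    FLAG_PROPER, FLAG_UNMAPPED, FLAG_MATE_UNMAPPED,
                    FLAG_REVERSE, FLAG_MATE_REVERSE, FLAG_READ1, FLAG_READ2,
                    FLAG_SECONDARY, write_fasta)

# assembly-state labels, shared with covprof
HAP_SEP = "HAP_SEP"
COLLAPSED = "COLLAPSED"
REPEAT_UNDERREP = "REPEAT_UNDERREP"
BREAKPOINT = "BREAKPOINT"

# internal locus-state codes
_S_HAPSEP, _S_COLLAPSED, _S_REPKEPT, _S_OMITTED = 0, 1, 2, 3

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

DEFAULT_STATE_PLAN = {HAP_SEP: 0.6, COLLAPSED: 0.3, REPEAT_UNDERREP: 0.1}


def decode(arr: np.ndarray) -> str:
    """Base-code array (0..3) -> ACGT string."""
    return _BASE_BYTES[arr].tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeConfig:
    """Parameters of the simulated diploid genome.

    ``het_rate`` is the per-base probability of a heterozygous event between
    the two haplotypes (90% SNVs, 10% short 1-3 bp indels).
    ``repeat_fraction`` of the haploid genome is tiled with copies from
    ``repeat_family_count`` interspersed repeat families of
    ``repeat_unit_len`` bases each.
    """

    haploid_size: int = 2_000_000
    het_rate: float = 0.005
    repeat_fraction: float = 0.10
    repeat_family_count: int = 4
    repeat_unit_len: int = 8_000
    unique_locus_len: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.haploid_size <= 0:
            raise ValueError("haploid_size must be positive")
        if not (0 <= self.het_rate < 0.1):
            raise ValueError("het_rate must be in [0, 0.1)")
        if not (0 <= self.repeat_fraction < 1):
            raise ValueError("repeat_fraction must be in [0, 1)")
        if self.repeat_fraction > 0:
            if self.repeat_fraction * self.haploid_size < self.repeat_unit_len:
                raise ValueError(
                    "repeat_fraction * haploid_size cannot hold one repeat unit")
        if self.repeat_unit_len <= 0 or self.repeat_family_count <= 0:
            raise ValueError("repeat geometry must be positive")


@dataclass
class ReadSimConfig:
    """Parameters of the read simulator.

    ``depth`` is fold-coverage of the *diploid* genome: total simulated bases
    approximately equal ``depth`` times the summed length of both haplotypes,
    so each haplotype is itself covered about ``depth``-fold.
    """

    platform: str = "long"  # "long" | "short_paired"
    depth: float = 30.0
    long_len_mean: float = 3_000.0
    long_len_sigma: float = 0.35
    short_read_len: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.platform not in ("long", "short_paired"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.error_rate <= 0.25):
            raise ValueError("error_rate must be in [0, 0.25]")


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class AssemblyTruth:
    """Ground truth about one generated assembly."""

    contigs: dict[str, np.ndarray]
    contig_names: list[str]
    contig_lengths: dict[str, int]
    state_intervals: list[tuple[str, int, int, str]]
    # primary-stream runs: maximal contiguous assembly stretches on haplotype A
    a_run_start: np.ndarray = field(repr=False, default=None)
    a_run_end: np.ndarray = field(repr=False, default=None)
    a_run_ctg: np.ndarray = field(repr=False, default=None)
    # haplotig runs on haplotype-B coordinates
    b_run_start: np.ndarray = field(repr=False, default=None)
    b_run_end: np.ndarray = field(repr=False, default=None)
    b_run_ctg: np.ndarray = field(repr=False, default=None)
    loci_state: np.ndarray = field(repr=False, default=None)
    survivors: dict[int, list[int]] = None  # family -> locus indices kept
    state_plan: dict[str, float] = None
    duplication_fraction: float = 0.0

    @property
    def span(self) -> int:
        return int(sum(self.contig_lengths.values()))


@dataclass
class SyntheticTruth:
    """Ground truth shared by all downstream stages."""

    config: SyntheticGenomeConfig
    true_haploid_size: int
    hap_lengths: tuple[int, int]
    # locus layout on haplotype A
    loci_start: np.ndarray
    loci_end: np.ndarray
    loci_kind: np.ndarray    # 0 unique, 1 repeat copy
    loci_family: np.ndarray  # -1 for unique loci
    # heterozygous events (haplotype-A coordinates)
    snv_pos: np.ndarray
    snv_ref: np.ndarray
    snv_alt: np.ndarray
    indel_pos: np.ndarray
    indel_len: np.ndarray
    indel_is_ins: np.ndarray
    # exact-correspondence segments between the haplotypes
    seg_a: np.ndarray
    seg_b: np.ndarray
    seg_len: np.ndarray
    assembly: AssemblyTruth | None = None
    read_sets: list = field(default_factory=list)

    # -- haplotype coordinate maps ------------------------------------------
    def a2b(self, a):
        a = np.asarray(a)
        k = np.searchsorted(self.seg_a, a, side="right") - 1
        off = np.minimum(a - self.seg_a[k], self.seg_len[k])
        return self.seg_b[k] + off

    def b2a(self, b):
        b = np.asarray(b)
        k = np.searchsorted(self.seg_b, b, side="right") - 1
        off = np.minimum(b - self.seg_b[k], self.seg_len[k])
        return self.seg_a[k] + off

    @property
    def het_positions(self) -> list[tuple[int, str, str]]:
        """SNV truth as (haplotype-A position, allele A, allele B)."""
        return [
            (int(p), "ACGT"[r], "ACGT"[a])
            for p, r, a in zip(self.snv_pos, self.snv_ref, self.snv_alt)
        ]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_diploid_genome(cfg: SyntheticGenomeConfig):
    """Build the two haplotypes and the truth record.

    Returns ``(hapA, hapB, truth)`` where each haplotype is a dict mapping
    the chromosome name to a base-code array (0..3; use :func:`decode`).
    Haplotype B is derived from A by het_rate substitutions and short indels;
    repeat copies within a family are identical on haplotype A.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    unit = cfg.repeat_unit_len
    n_rep = int(round(cfg.repeat_fraction * cfg.haploid_size / unit)) if cfg.repeat_fraction > 0 else 0
    rep_span = n_rep * unit
    if rep_span >= cfg.haploid_size:
        raise ValueError("repeat span leaves no room for unique sequence")
    unique_span = cfg.haploid_size - rep_span
    n_uniq = max(1, int(round(unique_span / cfg.unique_locus_len)))

    w = rng.uniform(0.8, 1.2, n_uniq)
    uniq_lens = np.floor(w / w.sum() * unique_span).astype(np.int64)
    uniq_lens[0] += unique_span - uniq_lens.sum()  # make the span exact

    family_seqs = [rng.integers(0, 4, unit, dtype=np.uint8) for _ in range(cfg.repeat_family_count)]
    fam_of_copy = rng.permutation(np.arange(n_rep, dtype=np.int64) % cfg.repeat_family_count) \
        if n_rep else np.empty(0, dtype=np.int64)

    kinds = np.concatenate([np.zeros(n_uniq, dtype=np.int8), np.ones(n_rep, dtype=np.int8)])
    order = rng.permutation(kinds.size)
    kinds = kinds[order]

    pieces: list[np.ndarray] = []
    loci_start, loci_end, loci_kind, loci_family = [], [], [], []
    iu = ir = 0
    pos = 0
    for k in kinds:
        if k == 0:
            seq = rng.integers(0, 4, int(uniq_lens[iu]), dtype=np.uint8)
            fam = -1
            iu += 1
        else:
            seq = family_seqs[int(fam_of_copy[ir])]
            fam = int(fam_of_copy[ir])
            ir += 1
        pieces.append(seq)
        loci_start.append(pos)
        loci_end.append(pos + len(seq))
        loci_kind.append(int(k))
        loci_family.append(fam)
        pos += len(seq)
    hap_a = np.concatenate(pieces)
    size = int(hap_a.size)

    # heterozygous events
    n_ev = rng.binomial(size, cfg.het_rate)
    ev_pos = np.sort(rng.choice(size, size=n_ev, replace=False)) if n_ev else np.empty(0, dtype=np.int64)
    if ev_pos.size:
        keep = np.concatenate(([True], np.diff(ev_pos) >= 4))  # keep indel bookkeeping simple
        ev_pos = ev_pos[keep]
        ev_pos = ev_pos[ev_pos < size - 4]
    is_indel = rng.random(ev_pos.size) < 0.10
    snv_pos = ev_pos[~is_indel]
    snv_ref = hap_a[snv_pos].copy()
    snv_alt = ((snv_ref + rng.integers(1, 4, snv_pos.size)) % 4).astype(np.uint8)
    indel_pos = ev_pos[is_indel]
    indel_len = rng.integers(1, 4, indel_pos.size).astype(np.int64)
    indel_is_ins = rng.random(indel_pos.size) < 0.5

    hap_b_base = hap_a.copy()
    hap_b_base[snv_pos] = snv_alt
    b_pieces = []
    seg_a, seg_b, seg_len = [0], [0], []
    cur_a = cur_b = 0
    for p, l, ins in zip(indel_pos.tolist(), indel_len.tolist(), indel_is_ins.tolist()):
        run = p - cur_a
        b_pieces.append(hap_b_base[cur_a:p])
        seg_len.append(run)
        if ins:
            b_pieces.append(rng.integers(0, 4, l, dtype=np.uint8))
            cur_a = p
            cur_b += run + l
        else:
            cur_a = p + l
            cur_b += run
        seg_a.append(cur_a)
        seg_b.append(cur_b)
    b_pieces.append(hap_b_base[cur_a:])
    seg_len.append(size - cur_a)
    hap_b = np.concatenate(b_pieces) if b_pieces else hap_b_base

    truth = SyntheticTruth(
        config=cfg,
        true_haploid_size=size,
        hap_lengths=(size, int(hap_b.size)),
        loci_start=np.asarray(loci_start, dtype=np.int64),
        loci_end=np.asarray(loci_end, dtype=np.int64),
        loci_kind=np.asarray(loci_kind, dtype=np.int8),
        loci_family=np.asarray(loci_family, dtype=np.int64),
        snv_pos=snv_pos.astype(np.int64),
        snv_ref=snv_ref,
        snv_alt=snv_alt,
        indel_pos=indel_pos.astype(np.int64),
        indel_len=indel_len,
        indel_is_ins=indel_is_ins,
        seg_a=np.asarray(seg_a, dtype=np.int64),
        seg_b=np.asarray(seg_b, dtype=np.int64),
        seg_len=np.asarray(seg_len, dtype=np.int64),
    )
    return {"chr1": hap_a}, {"chr1": hap_b}, truth


# ---------------------------------------------------------------------------
# Assembly generation
# ---------------------------------------------------------------------------

def generate_assembly(hap_a: Mapping[str, np.ndarray],
                      hap_b: Mapping[str, np.ndarray],
                      truth: SyntheticTruth,
                      state_plan: Mapping[str, float] | None = None,
                      survivors_per_family: int = 1,
                      seed: int | None = None):
    """Emit an assembly whose loci are in planned, recorded states.

    HAP_SEP loci contribute two contig segments (one per haplotype, the
    B side as separate "haplotig" contigs); COLLAPSED loci contribute
    haplotype A's sequence; repeat copies are omitted except
    ``survivors_per_family`` exemplars per family, whose bases are labelled
    REPEAT_UNDERREP.  Returns ``(contigs, state_bed)`` and records the full
    truth in ``truth.assembly``.
    """
    plan = dict(DEFAULT_STATE_PLAN if state_plan is None else state_plan)
    for k in plan:
        if k not in (HAP_SEP, COLLAPSED, REPEAT_UNDERREP):
            raise ValueError(f"unknown state in plan: {k}")
    for v in plan.values():
        if not (0 <= v <= 1):
            raise ValueError("plan fractions must be in [0, 1]")
    tot = sum(plan.values())
    if abs(tot - 1.0) > 1e-6:
        raise ValueError(f"plan fractions must sum to 1 (got {tot})")

    rng = np.random.default_rng(truth.config.seed + 1000 if seed is None else seed)
    a = hap_a["chr1"]
    b = hap_b["chr1"]
    n_loci = truth.loci_start.size
    state = np.full(n_loci, _S_COLLAPSED, dtype=np.int8)

    uniq_idx = np.flatnonzero(truth.loci_kind == 0)
    uniq_lens = (truth.loci_end - truth.loci_start)[uniq_idx]
    f_hs = plan.get(HAP_SEP, 0.0)
    f_col = plan.get(COLLAPSED, 0.0)
    hs_target = (f_hs / (f_hs + f_col) if (f_hs + f_col) > 0 else 0.0) * uniq_lens.sum()
    perm = rng.permutation(uniq_idx.size)
    acc = 0
    for j in perm:
        if acc >= hs_target:
            break
        # include the locus only if it brings the span closer to the quota
        if abs(acc + int(uniq_lens[j]) - hs_target) > abs(acc - hs_target):
            break
        state[uniq_idx[j]] = _S_HAPSEP
        acc += int(uniq_lens[j])

    survivors: dict[int, list[int]] = {}
    rep_idx = np.flatnonzero(truth.loci_kind == 1)
    state[rep_idx] = _S_OMITTED
    for fam in np.unique(truth.loci_family[rep_idx]):
        members = rep_idx[truth.loci_family[rep_idx] == fam]
        keep = members[:survivors_per_family]
        state[keep] = _S_REPKEPT
        survivors[int(fam)] = [int(i) for i in keep]

    # primary stream: maximal runs of non-omitted loci
    contigs: dict[str, np.ndarray] = {}
    names: list[str] = []
    state_intervals: list[tuple[str, int, int, str]] = []
    a_run_start, a_run_end, a_run_ctg = [], [], []
    label = {_S_HAPSEP: HAP_SEP, _S_COLLAPSED: COLLAPSED, _S_REPKEPT: REPEAT_UNDERREP}
    i = 0
    while i < n_loci:
        if state[i] == _S_OMITTED:
            i += 1
            continue
        j = i
        while j < n_loci and state[j] != _S_OMITTED:
            j += 1
        name = f"ctgA_{len(a_run_start):04d}"
        run_a0 = int(truth.loci_start[i])
        run_a1 = int(truth.loci_end[j - 1])
        contigs[name] = a[run_a0:run_a1]
        names.append(name)
        a_run_start.append(run_a0)
        a_run_end.append(run_a1)
        a_run_ctg.append(len(names) - 1)
        for k in range(i, j):
            state_intervals.append(
                (name, int(truth.loci_start[k]) - run_a0,
                 int(truth.loci_end[k]) - run_a0, label[int(state[k])]))
        i = j

    # haplotig stream: maximal runs of HAP_SEP loci, haplotype-B sequence
    b_run_start, b_run_end, b_run_ctg = [], [], []
    i = 0
    hap_count = 0
    while i < n_loci:
        if state[i] != _S_HAPSEP:
            i += 1
            continue
        j = i
        while j < n_loci and state[j] == _S_HAPSEP:
            j += 1
        b0 = int(truth.a2b(int(truth.loci_start[i])))
        b1 = int(truth.a2b(int(truth.loci_end[j - 1])))
        name = f"ctgB_{hap_count:04d}"
        hap_count += 1
        contigs[name] = b[b0:b1]
        names.append(name)
        b_run_start.append(b0)
        b_run_end.append(b1)
        b_run_ctg.append(len(names) - 1)
        state_intervals.append((name, 0, b1 - b0, HAP_SEP))
        i = j

    # merge adjacent same-state intervals per contig
    merged: list[tuple[str, int, int, str]] = []
    for iv in state_intervals:
        if merged and merged[-1][0] == iv[0] and merged[-1][2] == iv[1] and merged[-1][3] == iv[3]:
            merged[-1] = (iv[0], merged[-1][1], iv[2], iv[3])
        else:
            merged.append(iv)

    hs_span = int(uniq_lens[state[uniq_idx] == _S_HAPSEP].sum()) if uniq_idx.size else 0
    dup_fraction = hs_span / uniq_lens.sum() if uniq_idx.size else 0.0

    truth.assembly = AssemblyTruth(
        contigs=contigs,
        contig_names=names,
        contig_lengths={n: int(s.size) for n, s in contigs.items()},
        state_intervals=merged,
        a_run_start=np.asarray(a_run_start, dtype=np.int64),
        a_run_end=np.asarray(a_run_end, dtype=np.int64),
        a_run_ctg=np.asarray(a_run_ctg, dtype=np.int64),
        b_run_start=np.asarray(b_run_start, dtype=np.int64),
        b_run_end=np.asarray(b_run_end, dtype=np.int64),
        b_run_ctg=np.asarray(b_run_ctg, dtype=np.int64),
        loci_state=state,
        survivors=survivors,
        state_plan=plan,
        duplication_fraction=float(dup_fraction),
    )
    return contigs, merged


def write_state_bed(state_intervals, path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, state in state_intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{state}\n")


def write_genome_fasta(haplotype: Mapping[str, np.ndarray], path) -> None:
    write_fasta({n: decode(s) for n, s in haplotype.items()}, path)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated reads with their true origins (the spec of record for reads).

    ``start``/``end`` are origin coordinates on the source haplotype;
    ``rev`` marks reads sequenced from the reverse genome strand; error
    offsets are positions along the origin interval (forward orientation).
    """

    platform: str
    config: ReadSimConfig
    hap: np.ndarray          # 0 = haplotype A, 1 = haplotype B
    chrom: str
    start: np.ndarray
    end: np.ndarray
    rev: np.ndarray
    mate: np.ndarray         # 0 unpaired, 1 first mate, 2 second mate
    frag: np.ndarray         # fragment index (pairs share it)
    err_flat: np.ndarray
    err_idx: np.ndarray
    seqs: list[str] | None = None

    def __len__(self) -> int:
        return int(self.hap.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    def name(self, i: int) -> str:
        if self.platform == "long":
            return f"L{self.frag[i]:08d}"
        return f"P{self.frag[i]:08d}"

    def n_errors(self, i: int) -> int:
        return int(self.err_idx[i + 1] - self.err_idx[i])

    def errors(self, i: int) -> np.ndarray:
        return self.err_flat[self.err_idx[i]:self.err_idx[i + 1]]


def simulate_reads(haplotypes, cfg: ReadSimConfig,
                   truth: SyntheticTruth | None = None,
                   with_sequences: bool = True) -> ReadSet:
    """Sample reads from the two haplotypes at the configured diploid depth.

    ``haplotypes`` is the ``(hapA, hapB)`` pair from
    :func:`generate_diploid_genome`.  Reads are split evenly between
    haplotypes, so each haplotype is covered ``cfg.depth``-fold.
    """
    cfg.validate()
    hap_a, hap_b = haplotypes
    if len(hap_a) != 1 or len(hap_b) != 1:
        raise ValueError("simulate_reads expects single-chromosome haplotypes")
    (chrom, seq_a), = hap_a.items()
    seq_b = hap_b[chrom]
    lens = np.array([seq_a.size, seq_b.size], dtype=np.int64)
    target = cfg.depth * lens.sum()
    rng = np.random.default_rng(cfg.seed)

    if cfg.platform == "long":
        mu = np.log(cfg.long_len_mean) - cfg.long_len_sigma ** 2 / 2
        n_est = int(target / cfg.long_len_mean * 1.25) + 16
        raw = rng.lognormal(mu, cfg.long_len_sigma, n_est)
        if cfg.long_len_mean > lens.min():
            raise ValueError("long_len_mean exceeds contig length")
        L = np.clip(np.round(raw).astype(np.int64), 50, lens.min())
        cut = int(np.searchsorted(np.cumsum(L), target)) + 1
        L = L[:min(cut, n_est)]
        n = L.size
        hap = rng.integers(0, 2, n).astype(np.int8)
        start = np.floor(rng.random(n) * (lens[hap] - L + 1)).astype(np.int64)
        end = start + L
        rev = rng.random(n) < 0.5
        mate = np.zeros(n, dtype=np.int8)
        frag = np.arange(n, dtype=np.int64)
    else:
        rl = int(cfg.short_read_len)
        if rl > lens.min():
            raise ValueError("short_read_len exceeds contig length")
        n_frag = max(1, int(round(target / (2 * rl))))
        flen = np.clip(np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, n_frag)).astype(np.int64),
                       rl, lens.min())
        fhap = rng.integers(0, 2, n_frag).astype(np.int8)
        fstart = np.floor(rng.random(n_frag) * (lens[fhap] - flen + 1)).astype(np.int64)
        frev = rng.random(n_frag) < 0.5
        n = 2 * n_frag
        hap = np.repeat(fhap, 2)
        start = np.empty(n, dtype=np.int64)
        end = np.empty(n, dtype=np.int64)
        # the first mate sits at the fragment's sequencing start: the left
        # end for forward fragments, the right end for reverse ones (FR)
        start[0::2] = np.where(frev, fstart + flen - rl, fstart)
        end[0::2] = start[0::2] + rl
        start[1::2] = np.where(frev, fstart, fstart + flen - rl)
        end[1::2] = start[1::2] + rl
        rev = np.empty(n, dtype=bool)
        rev[0::2] = frev          # first mate on the fragment's strand
        rev[1::2] = ~frev         # second mate opposite
        mate = np.tile(np.array([1, 2], dtype=np.int8), n_frag)
        frag = np.repeat(np.arange(n_frag, dtype=np.int64), 2)

    read_len = end - start
    n_err = rng.binomial(read_len, cfg.error_rate) if cfg.error_rate > 0 else np.zeros(n, dtype=np.int64)
    err_idx = np.concatenate(([0], np.cumsum(n_err))).astype(np.int64)
    total_err = int(err_idx[-1])
    err_flat = np.floor(rng.random(total_err) * np.repeat(read_len, n_err)).astype(np.int64)

    seqs = None
    if with_sequences:
        sub = rng.integers(1, 4, total_err).astype(np.uint8)
        seqs = []
        src = (seq_a, seq_b)
        for i in range(n):
            s = src[hap[i]][start[i]:end[i]].copy()
            e0, e1 = err_idx[i], err_idx[i + 1]
            if e1 > e0:
                off = err_flat[e0:e1]
                s[off] = (s[off] + sub[e0:e1]) % 4
            if rev[i]:
                s = revcomp(s)
            seqs.append(decode(s))

    rs = ReadSet(platform=cfg.platform, config=cfg, hap=hap, chrom=chrom,
                 start=start, end=end, rev=np.asarray(rev, dtype=bool), mate=mate,
                 frag=frag, err_flat=err_flat, err_idx=err_idx, seqs=seqs)
    if truth is not None:
        truth.read_sets.append(rs)
    return rs


def write_fastq(reads: ReadSet, path, mate: int = 0) -> None:
    """Write reads (``mate`` 0 = all/unpaired, 1 or 2 = that mate only)."""
    if reads.seqs is None:
        raise ValueError("reads were simulated without sequences")
    with open(path, "w") as fh:
        for i in range(len(reads)):
            if mate and reads.mate[i] != mate:
                continue
            name = reads.name(i)
            if reads.mate[i]:
                name += f"/{reads.mate[i]}"
            s = reads.seqs[i]
            fh.write(f"@{name}\n{s}\n+\n{'I' * len(s)}\n")


# ---------------------------------------------------------------------------
# Truth-based alignment (oracle mapper)
# ---------------------------------------------------------------------------

@dataclass
class TruthAlignments:
    """Oracle placements of a :class:`ReadSet` on a synthetic assembly."""

    records: list[SamRecord]
    contig_lengths: dict[str, int]
    prim_ctg: np.ndarray      # -1 for unmapped reads
    prim_start: np.ndarray
    prim_end: np.ndarray
    sec_ctg: np.ndarray
    sec_start: np.ndarray
    sec_end: np.ndarray
    contig_names: list[str]

    @property
    def n_unmapped(self) -> int:
        return int((self.prim_ctg < 0).sum())

    def depth(self, include_secondary: bool = False) -> DepthTrack:
        """Per-base depth from placements (array path; matches
        alnio.depth_from_alignments on the SAM records)."""
        diffs = {n: np.zeros(l + 1, dtype=np.int64)
                 for n, l in self.contig_lengths.items()}
        arrs = [(self.prim_ctg, self.prim_start, self.prim_end)]
        if include_secondary:
            arrs.append((self.sec_ctg, self.sec_start, self.sec_end))
        for ctg, s, e in arrs:
            m = ctg >= 0
            for ci, name in enumerate(self.contig_names):
                sel = m & (ctg == ci)
                np.add.at(diffs[name], s[sel], 1)
                np.add.at(diffs[name], e[sel], -1)
        return DepthTrack({n: np.cumsum(d[:-1]) for n, d in diffs.items()})

    @property
    def mapped_bases(self) -> int:
        """Total contig-aligned bases over primary placements."""
        m = self.prim_ctg >= 0
        return int((self.prim_end[m] - self.prim_start[m]).sum())

    def write_sam(self, path) -> None:
        from .alnio import write_sam
        write_sam(self.records, self.contig_lengths, path)

    def to_alignment_records(self) -> list[AlignmentRecord]:
        out = []
        for r in self.records:
            if r.is_unmapped or r.rname is None:
                continue
            ops = r.cigar_ops()
            lead = ops[0][0] if ops and ops[0][1] == "S" else 0
            tail = ops[-1][0] if ops and ops[-1][1] == "S" else 0
            aligned = r.aligned_read_bases
            qlen = aligned + lead + tail
            alnlen = max(aligned, r.reference_span)
            nm = r.nm or 0
            out.append(AlignmentRecord(
                qname=r.qname, qlen=qlen, qstart=lead, qend=lead + aligned,
                strand="-" if r.is_reverse else "+", rname=r.rname,
                rlen=self.contig_lengths[r.rname], rstart=r.rstart, rend=r.rend,
                matches=max(0, alnlen - nm), alnlen=alnlen,
                mapq=60, is_secondary=r.is_secondary, nm=r.nm))
        return out

    def write_paf(self, path) -> None:
        from .alnio import write_paf
        write_paf(self.to_alignment_records(), path)


def _cigar_ops_b_on_a(truth: SyntheticTruth, ca_lo: int, ca_hi: int):
    """M/I/D ops for a haplotype-B read segment against haplotype-A sequence
    over A-interval [ca_lo, ca_hi); returns (ops, aligned_read, ref_span, indel_bases)."""
    seg_a, seg_b, seg_len = truth.seg_a, truth.seg_b, truth.seg_len
    k = int(np.searchsorted(seg_a, ca_lo, side="right")) - 1
    ops: list[tuple[int, str]] = []
    a_cur = ca_lo
    indel_bases = 0
    while a_cur < ca_hi:
        seg_end = int(seg_a[k] + seg_len[k])
        take = min(ca_hi, seg_end) - a_cur
        if take > 0:
            ops.append((take, "M"))
            a_cur += take
        if a_cur >= ca_hi or k + 1 >= seg_a.size:
            break
        ins_len = int(seg_b[k + 1] - (seg_b[k] + seg_len[k]))
        del_len = int(seg_a[k + 1]) - seg_end
        if ins_len > 0:
            ops.append((ins_len, "I"))
            indel_bases += ins_len
        if del_len > 0:
            take_d = min(ca_hi, int(seg_a[k + 1])) - a_cur
            if take_d > 0:
                ops.append((take_d, "D"))
                indel_bases += take_d
                a_cur += take_d
        k += 1
    # strip leading/trailing D (cannot border a clip)
    while ops and ops[0][1] == "D":
        ops.pop(0)
    while ops and ops[-1][1] == "D":
        ops.pop()
    # merge adjacent equal ops
    merged: list[tuple[int, str]] = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    aligned = sum(n for n, op in merged if op in "MI")
    ref_span = sum(n for n, op in merged if op in "MD")
    return merged, aligned, ref_span, indel_bases


def truth_align(reads: ReadSet, truth: SyntheticTruth,
                max_secondary: int = 10,
                include_seq: bool = False) -> TruthAlignments:
    """Place every read at its true assembly location(s).

    Reads from loci present in the assembly get one placement; reads wholly
    within a repeat copy get one placement per surviving copy of the family
    (primary = lowest coordinate, the rest flagged secondary, capped at
    ``max_secondary``); reads from omitted loci that are not wholly inside
    the repeat unit are emitted unmapped.  Proper-pair flags are set when
    both mates land on one contig in FR orientation with an outer span
    within 4 SD of the configured insert mean.
    """
    asm = truth.assembly
    if asm is None:
        raise ValueError("generate_assembly must be run before truth_align")
    n = len(reads)
    is_b = reads.hap == 1

    a_lo = reads.start.astype(np.int64).copy()
    a_hi = reads.end.astype(np.int64).copy()
    if is_b.any():
        a_lo[is_b] = truth.b2a(reads.start[is_b])
        a_hi[is_b] = truth.b2a(reads.end[is_b])
    mid = (a_lo + a_hi) // 2
    loc = np.searchsorted(truth.loci_start, mid, side="right") - 1
    loc = np.clip(loc, 0, truth.loci_start.size - 1)
    lstate = asm.loci_state[loc]
    lkind = truth.loci_kind[loc]
    lfam = truth.loci_family[loc]
    wholly = (lkind == 1) & (a_lo >= truth.loci_start[loc]) & (a_hi <= truth.loci_end[loc])

    ROUTE_A, ROUTE_BH, ROUTE_MULTI, ROUTE_UNMAPPED = 0, 1, 2, 3
    route = np.full(n, ROUTE_A, dtype=np.int8)
    route[is_b & (lstate == _S_HAPSEP)] = ROUTE_BH
    route[wholly] = ROUTE_MULTI
    route[(lstate == _S_OMITTED) & ~wholly] = ROUTE_UNMAPPED

    # vectorised columns for the single-placement routes
    n_arun = asm.a_run_start.size
    ridx = np.clip(np.searchsorted(asm.a_run_start, mid, side="right") - 1, 0, max(n_arun - 1, 0))
    ca_lo = np.maximum(a_lo, asm.a_run_start[ridx]) if n_arun else a_lo
    ca_hi = np.minimum(a_hi, asm.a_run_end[ridx]) if n_arun else a_hi
    if asm.b_run_start.size:
        midb = (reads.start + reads.end) // 2
        bidx = np.clip(np.searchsorted(asm.b_run_start, midb, side="right") - 1,
                       0, asm.b_run_start.size - 1)
        cb_lo = np.maximum(reads.start, asm.b_run_start[bidx])
        cb_hi = np.minimum(reads.end, asm.b_run_end[bidx])
    else:
        bidx = np.zeros(n, dtype=np.int64)
        cb_lo = reads.start
        cb_hi = reads.end

    snv_lo = np.searchsorted(truth.snv_pos, ca_lo)
    snv_hi = np.searchsorted(truth.snv_pos, ca_hi)
    ind_lo = np.searchsorted(truth.indel_pos, ca_lo)
    ind_hi = np.searchsorted(truth.indel_pos, ca_hi)
    n_err_all = np.diff(reads.err_idx)
    read_len = reads.lengths

    # survivors per family as exemplar locus start positions
    surv_starts = {fam: np.array([int(truth.loci_start[i]) for i in idx], dtype=np.int64)
                   for fam, idx in asm.survivors.items()}

    prim_ctg = np.full(n, -1, dtype=np.int64)
    prim_start = np.zeros(n, dtype=np.int64)
    prim_end = np.zeros(n, dtype=np.int64)
    cigars: list[str | None] = [None] * n
    nms = np.zeros(n, dtype=np.int64)
    secondaries: dict[int, list[tuple[int, int, int, str, int]]] = {}

    def _err_in(i: int, lead: int, tail: int) -> int:
        if lead == 0 and tail == 0:
            return int(n_err_all[i])
        e = reads.errors(i)
        L = int(read_len[i])
        return int(((e >= lead) & (e < L - tail)).sum())

    for i in range(n):
        rt = route[i]
        if rt == ROUTE_UNMAPPED:
            continue
        if rt == ROUTE_BH:
            lo, hi = int(cb_lo[i]), int(cb_hi[i])
            if hi <= lo:
                continue
            lead = lo - int(reads.start[i])
            tail = int(reads.end[i]) - hi
            ci = int(asm.b_run_ctg[bidx[i]])
            pos = lo - int(asm.b_run_start[bidx[i]])
            m = hi - lo
            cig = (f"{lead}S" if lead else "") + f"{m}M" + (f"{tail}S" if tail else "")
            prim_ctg[i], prim_start[i], prim_end[i] = ci, pos, pos + m
            cigars[i] = cig
            nms[i] = _err_in(i, lead, tail)
            continue
        if rt == ROUTE_A:
            lo, hi = int(ca_lo[i]), int(ca_hi[i])
            if hi <= lo:
                continue
            ci = int(asm.a_run_ctg[ridx[i]])
            pos = lo - int(asm.a_run_start[ridx[i]])
            if not is_b[i]:
                lead = lo - int(a_lo[i])
                tail = int(a_hi[i]) - hi
                m = hi - lo
                cig = (f"{lead}S" if lead else "") + f"{m}M" + (f"{tail}S" if tail else "")
                prim_ctg[i], prim_start[i], prim_end[i] = ci, pos, pos + m
                cigars[i] = cig
                nms[i] = _err_in(i, lead, tail)
            else:
                nsnv = int(snv_hi[i] - snv_lo[i])
                if ind_hi[i] == ind_lo[i]:
                    lead = int(truth.a2b(lo)) - int(reads.start[i])
                    m = hi - lo
                    tail = int(read_len[i]) - lead - m
                    if tail < 0:  # clamp rare boundary effects
                        m += tail
                        tail = 0
                    if m <= 0:
                        continue
                    cig = (f"{lead}S" if lead else "") + f"{m}M" + (f"{tail}S" if tail else "")
                    prim_ctg[i], prim_start[i], prim_end[i] = ci, pos, pos + m
                    cigars[i] = cig
                    nms[i] = _err_in(i, lead, tail) + nsnv
                else:
                    ops, aligned, ref_span, indel_bases = _cigar_ops_b_on_a(truth, lo, hi)
                    if aligned <= 0 or ref_span <= 0:
                        continue
                    lead = int(truth.a2b(lo)) - int(reads.start[i])
                    tail = int(read_len[i]) - lead - aligned
                    if tail < 0:  # trim read-side overrun at the window edge
                        over = -tail
                        tail = 0
                        trimmed = []
                        for cnt, op in reversed(ops):
                            if over > 0 and op in "MI":
                                cut = min(cnt, over)
                                over -= cut
                                cnt -= cut
                                if op == "M":
                                    ref_span -= cut
                                aligned -= cut
                            if cnt > 0:
                                trimmed.append((cnt, op))
                        ops = list(reversed(trimmed))
                        if not ops:
                            continue
                    cig = (f"{lead}S" if lead else "") + \
                        "".join(f"{cnt}{op}" for cnt, op in ops) + \
                        (f"{tail}S" if tail else "")
                    prim_ctg[i], prim_start[i], prim_end[i] = ci, pos, pos + ref_span
                    cigars[i] = cig
                    nms[i] = _err_in(i, lead, tail) + nsnv + indel_bases
            continue
        # ROUTE_MULTI: read wholly within a repeat copy
        fam = int(lfam[i])
        starts = surv_starts.get(fam)
        if starts is None or starts.size == 0:
            continue
        copy_start = int(truth.loci_start[loc[i]])
        off_lo = int(a_lo[i]) - copy_start
        off_hi = int(a_hi[i]) - copy_start
        if not is_b[i]:
            ops_str = None
            aligned = off_hi - off_lo
            ref_span = aligned
            base_nm = int(n_err_all[i])
            lead = tail = 0
        else:
            nsnv = int(snv_hi[i] - snv_lo[i])
            if ind_hi[i] == ind_lo[i]:
                aligned = off_hi - off_lo
                ref_span = aligned
                lead = int(truth.a2b(int(a_lo[i]))) - int(reads.start[i])
                tail = int(read_len[i]) - lead - aligned
                if tail < 0:
                    aligned += tail
                    ref_span = aligned
                    tail = 0
                if aligned <= 0:
                    continue
                ops_str = None
                base_nm = int(n_err_all[i]) + nsnv
            else:
                ops, aligned, ref_span, indel_bases = _cigar_ops_b_on_a(
                    truth, int(a_lo[i]), int(a_hi[i]))
                if aligned <= 0 or ref_span <= 0:
                    continue
                lead = int(truth.a2b(int(a_lo[i]))) - int(reads.start[i])
                tail = max(0, int(read_len[i]) - lead - aligned)
                ops_str = "".join(f"{cnt}{op}" for cnt, op in ops)
                base_nm = int(n_err_all[i]) + nsnv + indel_bases
        if ops_str is None:
            ops_str = f"{aligned}M"
        cig = (f"{lead}S" if lead else "") + ops_str + (f"{tail}S" if tail else "")
        placements = []
        for s0 in starts.tolist():
            pa_lo = s0 + off_lo
            ri = int(np.searchsorted(asm.a_run_start, s0 + (off_lo + off_hi) // 2,
                                     side="right")) - 1
            ci = int(asm.a_run_ctg[ri])
            pos = pa_lo - int(asm.a_run_start[ri])
            placements.append((ci, pos))
        placements.sort()
        ci, pos = placements[0]
        prim_ctg[i], prim_start[i], prim_end[i] = ci, pos, pos + ref_span
        cigars[i] = cig
        nms[i] = base_nm
        if len(placements) > 1:
            secondaries[i] = [(c, p, p + ref_span, cig, base_nm)
                              for c, p in placements[1:1 + max_secondary]]

    # --- pair geometry -----------------------------------------------------
    paired = reads.platform == "short_paired"
    proper = np.zeros(n, dtype=bool)
    if paired:
        i1 = np.arange(0, n, 2)
        i2 = i1 + 1
        both = (prim_ctg[i1] >= 0) & (prim_ctg[i2] >= 0) & (prim_ctg[i1] == prim_ctg[i2])
        rev1 = reads.rev[i1]
        rev2 = reads.rev[i2]
        fr = rev1 != rev2
        left = np.minimum(prim_start[i1], prim_start[i2])
        right = np.maximum(prim_end[i1], prim_end[i2])
        outer = right - left
        # the forward-strand mate must be the leftmost one
        fwd_pos = np.where(rev1, prim_start[i2], prim_start[i1])
        rev_pos = np.where(rev1, prim_start[i1], prim_start[i2])
        cfg = reads.config
        ok = both & fr & (fwd_pos <= rev_pos) & \
            (np.abs(outer - cfg.insert_mean) <= 4 * cfg.insert_sd)
        proper[i1] = ok
        proper[i2] = ok

    # --- SAM records -------------------------------------------------------
    names = asm.contig_names
    records: list[SamRecord] = []
    sec_ctg, sec_start, sec_end = [], [], []
    for i in range(n):
        qname = reads.name(i)
        mapped = prim_ctg[i] >= 0
        flag = 0
        if paired:
            flag |= FLAG_PAIRED
            flag |= FLAG_READ1 if reads.mate[i] == 1 else FLAG_READ2
            j = i + 1 if reads.mate[i] == 1 else i - 1
            mate_mapped = prim_ctg[j] >= 0
            if proper[i]:
                flag |= FLAG_PROPER
            if not mate_mapped:
                flag |= FLAG_MATE_UNMAPPED
            if mate_mapped and reads.rev[j]:
                flag |= FLAG_MATE_REVERSE
        if not mapped:
            flag |= FLAG_UNMAPPED
            records.append(SamRecord(qname=qname, flag=flag, rname=None, pos=-1,
                                     mapq=0, cigar="*", seq=None))
            continue
        if reads.rev[i]:
            flag |= FLAG_REVERSE
        rname = names[prim_ctg[i]]
        rnext = pnext = None
        tlen = 0
        if paired:
            j = i + 1 if reads.mate[i] == 1 else i - 1
            if prim_ctg[j] >= 0:
                rnext = names[prim_ctg[j]]
                pnext = int(prim_start[j])
                if prim_ctg[j] == prim_ctg[i]:
                    left = min(prim_start[i], prim_start[j])
                    right = max(prim_end[i], prim_end[j])
                    tlen = int(right - left)
                    if prim_start[i] > prim_start[j] or \
                            (prim_start[i] == prim_start[j] and reads.mate[i] == 2):
                        tlen = -tlen
        seq = None
        if include_seq and reads.seqs is not None:
            seq = reads.seqs[i]
            if reads.rev[i]:  # SAM stores the reference-forward orientation
                seq = _revcomp_str(seq)
        records.append(SamRecord(
            qname=qname, flag=flag, rname=rname, pos=int(prim_start[i]),
            mapq=60, cigar=cigars[i], rnext=rnext,
            pnext=pnext if pnext is not None else -1, tlen=tlen, seq=seq,
            nm=int(nms[i])))
        for (c, p, e, cig, nm_s) in secondaries.get(i, []):
            sflag = flag | FLAG_SECONDARY
            records.append(SamRecord(
                qname=qname, flag=sflag, rname=names[c], pos=int(p), mapq=0,
                cigar=cig, rnext=rnext, pnext=pnext if pnext is not None else -1,
                tlen=0, seq=None, nm=int(nm_s)))
            sec_ctg.append(c)
            sec_start.append(p)
            sec_end.append(e)

    return TruthAlignments(
        records=records,
        contig_lengths=asm.contig_lengths,
        prim_ctg=prim_ctg, prim_start=prim_start, prim_end=prim_end,
        sec_ctg=np.asarray(sec_ctg, dtype=np.int64),
        sec_start=np.asarray(sec_start, dtype=np.int64),
        sec_end=np.asarray(sec_end, dtype=np.int64),
        contig_names=names)


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp_str(s: str) -> str:
    return s.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Truth-based assembly-to-assembly alignments
# ---------------------------------------------------------------------------

def truth_assembly_alignments(truth: SyntheticTruth):
    """Oracle whole-genome alignments of the synthetic assembly (query) to a
    haploid reference cut into one contig per locus.

    Returns ``(records, ref_lengths, true_classes)`` where ``true_classes``
    maps each reference contig to its expected multiplicity class after
    best-per-query filtering ("1:2" for haplotype-separated loci, "1:1" for
    collapsed and surviving repeat loci, "uncategorized" for omitted copies,
    whose single exemplar alignment cannot be retained for every copy).
    """
    asm = truth.assembly
    if asm is None:
        raise ValueError("generate_assembly must be run before truth_assembly_alignments")
    records: list[AlignmentRecord] = []
    ref_lengths: dict[str, int] = {}
    true_classes: dict[str, str] = {}
    names = asm.contig_names
    n_loci = truth.loci_start.size
    qlens = asm.contig_lengths

    def _a_placement(a_pos: int):
        ri = int(np.searchsorted(asm.a_run_start, a_pos, side="right")) - 1
        return int(asm.a_run_ctg[ri]), a_pos - int(asm.a_run_start[ri])

    for k in range(n_loci):
        a0, a1 = int(truth.loci_start[k]), int(truth.loci_end[k])
        L = a1 - a0
        rname = f"ref_{k:05d}"
        ref_lengths[rname] = L
        st = int(asm.loci_state[k])
        if st == _S_OMITTED:
            fam = int(truth.loci_family[k])
            ex = asm.survivors.get(fam, [])
            true_classes[rname] = "uncategorized"
            if not ex:
                continue
            e0 = int(truth.loci_start[ex[0]])
            ci, qpos = _a_placement(e0 + L // 2)
            qpos -= L // 2
            qn = names[ci]
            records.append(AlignmentRecord(
                qname=qn, qlen=qlens[qn], qstart=qpos, qend=qpos + L,
                strand="+", rname=rname, rlen=L, rstart=0, rend=L,
                matches=L, alnlen=L))
            continue
        ci, qpos = _a_placement(a0 + L // 2)
        qpos -= L // 2
        qn = names[ci]
        records.append(AlignmentRecord(
            qname=qn, qlen=qlens[qn], qstart=qpos, qend=qpos + L,
            strand="+", rname=rname, rlen=L, rstart=0, rend=L,
            matches=L, alnlen=L))
        if st == _S_HAPSEP:
            b0 = int(truth.a2b(a0))
            b1 = int(truth.a2b(a1))
            bi = int(np.searchsorted(asm.b_run_start, (b0 + b1) // 2, side="right")) - 1
            hn = names[int(asm.b_run_ctg[bi])]
            hpos = b0 - int(asm.b_run_start[bi])
            nsnv = int(np.searchsorted(truth.snv_pos, a1) - np.searchsorted(truth.snv_pos, a0))
            i0 = int(np.searchsorted(truth.indel_pos, a0))
            i1 = int(np.searchsorted(truth.indel_pos, a1))
            indel_bases = int(truth.indel_len[i0:i1].sum())
            alnlen = max(L, b1 - b0)
            matches = max(0, alnlen - nsnv - indel_bases)
            if b1 > b0:
                records.append(AlignmentRecord(
                    qname=hn, qlen=qlens[hn], qstart=hpos, qend=hpos + (b1 - b0),
                    strand="+", rname=rname, rlen=L, rstart=0, rend=L,
                    matches=matches, alnlen=alnlen))
            true_classes[rname] = "1:2"
        else:
            true_classes[rname] = "1:1"
    return records, ref_lengths, true_classes


# ---------------------------------------------------------------------------
# Contaminant-contig simulation
# ---------------------------------------------------------------------------

def simulate_contaminated_contig(contig_len: int = 120_000,
                                 segment: tuple[int, int] = (60_000, 78_000),
                                 depth: float = 30.0,
                                 fold: float = 3.0,
                                 read_len_mean: float = 3_000.0,
                                 read_len_sigma: float = 0.35,
                                 seed: int = 0):
    """Depth track for a contig carrying a foreign insert at ``fold`` times
    the host coverage (the endosymbiont-contamination signature).

    Host reads sample the whole contig; the extra foreign reads fall inside
    the segment, clipped at its boundaries the way a mapper clips reads that
    run off the foreign sequence, so the depth step is sharp.  Returns
    ``(DepthTrack, segment)``.
    """
    a, b = segment
    if not (0 <= a < b <= contig_len):
        raise ValueError("segment outside contig")
    rng = np.random.default_rng(seed)
    mu = np.log(read_len_mean) - read_len_sigma ** 2 / 2

    def _sample(n_bases, lo, hi, clip_lo, clip_hi):
        """Reads whose starts may overhang [clip_lo, clip_hi); the overhang is
        clipped, so mean coverage is flat across the whole clipped span."""
        raw = rng.lognormal(mu, read_len_sigma, int(n_bases / read_len_mean * 1.3) + 8)
        L = np.clip(np.round(raw).astype(np.int64), 50, hi - lo)
        cut = int(np.searchsorted(np.cumsum(L), n_bases)) + 1
        L = L[:cut]
        start = np.floor(rng.random(L.size) * (hi - lo)).astype(np.int64) + lo
        end = np.minimum(start + L, clip_hi)
        start = np.maximum(start, clip_lo)
        return start, end

    rl = int(read_len_mean)
    hs, he = _sample(depth * (contig_len + rl), -rl, contig_len, 0, contig_len)
    fs, fe = _sample((fold - 1.0) * depth * (b - a + rl), a - rl, b, a, b)
    diff = np.zeros(contig_len + 1, dtype=np.int64)
    for s, e in ((hs, he), (fs, fe)):
        keep = e > s
        np.add.at(diff, s[keep], 1)
        np.add.at(diff, e[keep], -1)
    return DepthTrack({"ctg": np.cumsum(diff[:-1])}), segment
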