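"""Genome-size estimators for assemblies with partial haplotype separation.

Three routes to the haploid genome size, reported side by side rather than
averaged:

* coverage extrapolation — total aligned bases divided by the per-base
  coverage mode gives the combined-haplotype (diploid) size; half of that is
  the haploid size;
* duplication adjustment — an assembly span corrected by the fraction of
  single-copy genes found duplicated (each duplicated pair collapses to one
  copy, removing half the duplicated span);
* partition bound — haplotype-separated bases counted once per pair plus
  collapsed bases, a lower bound because under-represented repeats are not
  accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from .covprof import StatePartition, COLLAPSED, HAP_SEP

GBP = 1e9


@dataclass
class SizeEstimate:
    method: str
    haploid_size: float
    diploid_size: float | None = None
    lower_bound: bool = False
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.haploid_size <= 0:
            raise ValueError("haploid_size must be positive")
        if self.diploid_size is not None:
            if self.diploid_size <= 0:
                raise ValueError("diploid_size must be positive")
            if abs(self.haploid_size - self.diploid_size / 2) > 1e-6 * self.diploid_size:
                raise ValueError("haploid_size must equal diploid_size / 2")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.215 -> 2.22, 884.5 -> 885 at ndigits=0)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def gbp(value_bases: float, ndigits: int = 2) -> float:
    """Bases -> Gbp with half-up report rounding."""
    return round_half_up(value_bases / GBP, ndigits)


def rounded_gbp_pair(diploid_bases: float) -> tuple[float, float]:
    """Report presentation of a coverage estimate: (diploid Gbp, haploid Gbp).

    The haploid figure is half of the already-rounded diploid figure, so the
    printed chain is internally consistent (4.47 -> 2.24, 4.43 -> 2.22).
    """
    d = gbp(diploid_bases)
    return d, round_half_up(d / 2)


def size_from_coverage(mapped_bases: float, mode: float) -> SizeEstimate:
    """Diploid size = aligned bases / coverage mode; haploid = half of that.

    ``mapped_bases`` is the total of contig-aligned bases (the contig-side
    span for long reads, the mapped base count for short pairs); ``mode`` is
    the per-base coverage mode of haplotype-separated (unique) sequence.
    """
    if mapped_bases <= 0:
        raise ValueError("mapped_bases must be positive")
    if mode < 1:
        raise ValueError("coverage mode must be >= 1")
    diploid = mapped_bases / mode
    return SizeEstimate(
        method="coverage", haploid_size=diploid / 2, diploid_size=diploid,
        inputs={"mapped_bases": float(mapped_bases), "mode": float(mode)})


def size_from_duplication(assembly_span: float, dup_fraction: float) -> SizeEstimate:
    """Haploid size = span x (1 - dup_fraction/2).

    ``dup_fraction`` is the fraction of universal single-copy genes found
    complete and duplicated (a proxy for the haplotype-duplicated fraction
    of the assembly); collapsing each duplicated pair removes half of the
    duplicated span.
    """
    if not (0 <= dup_fraction <= 1):
        raise ValueError("dup_fraction must be in [0, 1]")
    if assembly_span <= 0:
        raise ValueError("assembly_span must be positive")
    return SizeEstimate(
        method="duplication_adjusted",
        haploid_size=assembly_span * (1 - dup_fraction / 2),
        inputs={"assembly_span": float(assembly_span),
                "dup_fraction": float(dup_fraction)})


def size_from_partition(p: StatePartition) -> SizeEstimate:
    """Haploid lower bound = HAP_SEP/2 + COLLAPSED (half-up rounded).

    A lower bound: repeat-level bases stand for an unknown, larger span of
    the genome, and breakpoint-adjacent bases are not counted.
    """
    hap = p.spans.get(HAP_SEP, 0)
    col = p.spans.get(COLLAPSED, 0)
    size = round_half_up(hap / 2 + col, 0)
    return SizeEstimate(
        method="partition_bound", haploid_size=size, lower_bound=True,
        inputs={"hap_sep_bases": int(hap), "collapsed_bases": int(col)})


def consolidate(estimates: list[SizeEstimate]) -> dict:
    """Tabulate estimates side by side; the spread is max - min (no averaging)."""
    if not estimates:
        raise ValueError("no estimates to consolidate")
    rows = sorted(
        ({"method": e.method,
          "haploid_size": float(e.haploid_size),
          "diploid_size": None if e.diploid_size is None else float(e.diploid_size),
          "lower_bound": e.lower_bound,
          "inputs": dict(e.inputs)}
         for e in estimates),
        key=lambda r: (r["method"], r["haploid_size"]))
    values = [r["haploid_size"] for r in rows]
    return {"estimates": rows, "spread": max(values) - min(values)}


def fold_coverage(total_read_bases: float, genome_size: float) -> float:
    """Sequencing depth implied by a read total over a genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_read_bases / genome_size


def busco_complete_percent(fragmented_pct: float, missing_pct: float) -> float:
    """Complete single-copy-orthologs percentage from the two complements."""
    if fragmented_pct < 0 or missing_pct < 0 or fragmented_pct + missing_pct > 100:
        raise ValueError("percentages must be non-negative and sum to <= 100")
    return 100.0 - fragmented_pct - missing_pct
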