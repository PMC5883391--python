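"""End-to-end pipeline configuration, orchestration and the consolidated report.

The report JSON is the single source of truth; the markdown rendering is
derived from it.  Runs are deterministic: identical config and seed give
byte-identical JSON.  Stages with missing inputs are skipped with an
explicit notice, never silently.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from . import __version__
from . import alnio, covprof, sizeest, multiplicity, mapstats, breakscan

log = logging.getLogger("ploidyscope")

SCHEMA_VERSION = 1
STAGES = ("coverage_profile", "genome_size", "multiplicity", "mapping",
          "coverage_shifts")


@dataclass
class RunConfig:
    """Pipeline inputs and tunables; unknown keys are rejected.

    Input paths may be omitted; the stages that need them are then skipped
    with a notice in the report.
    """

    # inputs
    assembly_fasta: str | None = None
    depth_tsv: str | None = None
    depth_bedgraph: str | None = None
    sam: str | None = None
    paf: str | None = None
    dup_fraction: float | None = None
    # tunables
    smooth_bandwidth: int = 5
    min_aln_len: int = 1000
    min_cov: float = 0.5
    coverage_levels: tuple = (0.5, 0.9)
    min_segment: int = 5000
    fold_threshold: float = 2.0
    window: int = 1000
    mapping_mode: str = "end_to_end"
    # run control
    seed: int = 0
    outdir: str = "ploidyscope_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.coverage_levels, list):
            cfg.coverage_levels = tuple(cfg.coverage_levels)
        return cfg


def _skip(reason: str) -> dict:
    return {"skipped": True, "reason": reason}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage whose inputs are present; return the report dict and
    write report.json / report.md under ``cfg.outdir``."""
    t0 = time.monotonic()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package": "ploidyscope",
            "version": __version__,
            "seed": cfg.seed,
            "config": asdict(cfg),
        },
        "stages": {},
    }

    track = None
    if cfg.depth_tsv:
        track = alnio.read_depth_tsv(cfg.depth_tsv)
    elif cfg.depth_bedgraph:
        track = alnio.read_bedgraph(cfg.depth_bedgraph)

    assembly = alnio.read_fasta(cfg.assembly_fasta) if cfg.assembly_fasta else None

    # --- coverage profile --------------------------------------------------
    peaks = partition = None
    if track is None:
        report["stages"]["coverage_profile"] = _skip("no depth input (depth_tsv/depth_bedgraph)")
    else:
        t = time.monotonic()
        hist = covprof.histogram(track)
        peaks = covprof.fit_peaks(hist, smooth_bandwidth=cfg.smooth_bandwidth)
        partition = covprof.partition_states(hist, peaks)
        classes = covprof.classify_contigs(track, peaks)
        state_counts: dict[str, int] = {}
        for c in classes.values():
            state_counts[c.state] = state_counts.get(c.state, 0) + 1
        report["stages"]["coverage_profile"] = {
            "total_bases": hist.total_bases,
            "mode": peaks.mode,
            "shoulder": peaks.shoulder,
            "boundaries": {"b_low": peaks.b_low, "b_mid": peaks.b_mid,
                           "b_high": peaks.b_high},
            "boundary_fallbacks": peaks.fallback,
            "state_spans": partition.spans,
            "zero_depth_bases": partition.zero_depth_bases,
            "implied_genome_lower_bound": partition.implied_genome_lower_bound,
            "contig_state_counts": dict(sorted(state_counts.items())),
        }
        covprof.write_histogram_tsv(hist, outdir / "coverage_histogram.tsv")
        log.info("coverage_profile done in %.2fs", time.monotonic() - t)

    # --- genome size -------------------------------------------------------
    estimates = []
    if track is not None and peaks is not None:
        estimates.append(sizeest.size_from_coverage(track.total_depth, peaks.mode))
    if partition is not None:
        estimates.append(sizeest.size_from_partition(partition))
    if assembly is not None and cfg.dup_fraction is not None:
        span = sum(len(s) for s in assembly.values())
        estimates.append(sizeest.size_from_duplication(span, cfg.dup_fraction))
    if estimates:
        report["stages"]["genome_size"] = sizeest.consolidate(estimates)
    else:
        report["stages"]["genome_size"] = _skip(
            "needs a depth input and/or assembly_fasta with dup_fraction")

    # --- multiplicity ------------------------------------------------------
    if cfg.paf:
        t = time.monotonic()
        records = alnio.read_paf(cfg.paf)
        ref_lengths = {}
        for r in records:
            ref_lengths[r.rname] = r.rlen
        best = multiplicity.best_per_query(records)
        table = multiplicity.classify_multiplicity(best, ref_lengths,
                                                   min_cov=cfg.min_cov)
        contain = multiplicity.containment_stats(
            records, ref_lengths, min_aln_len=cfg.min_aln_len,
            coverage_levels=cfg.coverage_levels)
        report["stages"]["multiplicity"] = {
            "class_fractions": table.fractions,
            "containment": {
                "any_alignment": contain.any_alignment,
                "by_level": {str(k): v for k, v in contain.by_level.items()},
                "min_aln_len": contain.min_aln_len,
            },
            "n_reference_contigs": len(ref_lengths),
        }
        multiplicity.write_multiplicity_tsv(table, outdir / "multiplicity.tsv")
        log.info("multiplicity done in %.2fs", time.monotonic() - t)
    else:
        report["stages"]["multiplicity"] = _skip("no assembly-to-assembly paf input")

    # --- mapping -----------------------------------------------------------
    if cfg.sam:
        t = time.monotonic()
        records = alnio.read_sam(cfg.sam)
        pr = mapstats.pair_classes(records, mode=cfg.mapping_mode)
        dr = mapstats.disagreement_rate(records, mode=cfg.mapping_mode)
        has_secondary = any(r.is_secondary for r in records)
        stage = {
            "pair_fractions": pr.fractions,
            "total_pairs": pr.total_pairs,
            "disagreement_rate": dr.rate,
            "mapped_read_fraction": mapstats.mapped_read_fraction(records),
            "mode": cfg.mapping_mode,
        }
        if has_secondary:
            sr = mapstats.site_classes(records)
            stage["site_fractions"] = sr.fractions
        else:
            stage["site_fractions"] = None
            stage["site_note"] = "no secondary records: input looks single-best"
        report["stages"]["mapping"] = stage
        log.info("mapping done in %.2fs", time.monotonic() - t)
    else:
        report["stages"]["mapping"] = _skip("no sam input")

    # --- coverage shifts ---------------------------------------------------
    if track is not None:
        t = time.monotonic()
        segments = breakscan.detect_shifts(
            track, min_segment=cfg.min_segment,
            fold_threshold=cfg.fold_threshold, window=cfg.window)
        report["stages"]["coverage_shifts"] = {
            "n_segments": len(segments),
            "segments": [
                {"contig": s.contig, "start": s.start, "end": s.end,
                 "inner_mean_depth": s.inner_mean_depth,
                 "flank_mean_depth": s.flank_mean_depth, "fold": s.fold}
                for s in segments
            ],
        }
        breakscan.write_segments_bed(segments, outdir / "coverage_shifts.bed")
        log.info("coverage_shifts done in %.2fs", time.monotonic() - t)
    else:
        report["stages"]["coverage_shifts"] = _skip("no depth input")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.md", "w") as fh:
        fh.write(render_markdown(report))
    log.info("pipeline done in %.2fs", time.monotonic() - t0)
    return report


def validate_report(report: dict) -> None:
    """Structural validation of a report dict; raises ValueError on problems."""
    for key in ("schema_version", "provenance", "stages"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ValueError("unknown schema_version")
    prov = report["provenance"]
    for key in ("package", "version", "seed", "config"):
        if key not in prov:
            raise ValueError(f"provenance missing {key!r}")
    stages = report["stages"]
    for name in STAGES:
        if name not in stages:
            raise ValueError(f"report missing stage {name!r}")
        st = stages[name]
        if not isinstance(st, dict):
            raise ValueError(f"stage {name!r} must be a dict")
        if st.get("skipped") and "reason" not in st:
            raise ValueError(f"skipped stage {name!r} must give a reason")
    cp = stages["coverage_profile"]
    if not cp.get("skipped"):
        spans = cp["state_spans"]
        if sum(spans.values()) + cp["zero_depth_bases"] != cp["total_bases"]:
            raise ValueError("coverage_profile spans do not conserve total bases")


def render_markdown(report: dict) -> str:
    lines = ["# ploidyscope report", ""]
    prov = report["provenance"]
    lines += [f"package {prov['package']} {prov['version']}, seed {prov['seed']}", ""]
    for name in STAGES:
        st = report["stages"][name]
        lines.append(f"## {name}")
        if st.get("skipped"):
            lines += [f"skipped: {st['reason']}", ""]
            continue
        for k, v in st.items():
            if isinstance(v, (list, dict)):
                lines.append(f"- {k}: `{json.dumps(v, sort_keys=True)}`")
            else:
                lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)
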