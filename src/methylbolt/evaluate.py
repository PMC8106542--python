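"""Benchmark metrics against simulator truth: mappability, on/off-target
classification, per-site coverage MAE and methylation-level MAE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam

from .reference import Strand
from .simulate import parse_truth_comment, read_truth_counts


@dataclass
class AlignmentEvaluation:
    n_reads: int
    mappability: float  # fraction of reads aligned
    on_target: float  # fraction of aligned reads on-target
    off_target: float

    def as_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "mappability": self.mappability,
            "on_target": self.on_target,
            "off_target": self.off_target,
        }


@dataclass
class MethylationEvaluation:
    coverage_mae: float  # mean |called_total - simulated_total| (reads)
    level_mae: float  # mean |called_level - truth_level|
    n_sites: int

    def as_dict(self) -> dict:
        return {
            "coverage_mae": self.coverage_mae,
            "level_mae": self.level_mae,
            "n_sites": self.n_sites,
        }


def _read_truth(read: pysam.AlignedSegment, truth_map: dict | None):
    if read.has_tag("ZT"):
        return parse_truth_comment(read.get_tag("ZT"))
    if truth_map is not None:
        key = (read.query_name, read.is_read2)
        if key in truth_map:
            return truth_map[key]
    raise ValueError(f"read {read.query_name!r} carries no parseable truth annotation")


def truth_map_from_fastq(fastq1: str | Path, fastq2: str | Path | None = None) -> dict:
    """Build {(name, is_read2): truth} from the simulator's FASTQ comments."""
    out = {}
    for path, is_read2 in ((fastq1, False), (fastq2, True)):
        if path is None:
            continue
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                if entry.comment is None:
                    raise ValueError(f"read {entry.name!r} in {path} has no truth comment")
                out[(entry.name, is_read2)] = parse_truth_comment(entry.comment)
    return out


def evaluate_alignments(
    bam_path: str | Path,
    truth_map: dict | None = None,
    on_target_fraction: float = 0.95,
) -> AlignmentEvaluation:
    """Classify each primary alignment against the simulator's truth.

    On-target: >= 95% of aligned bases inside the truth interval on the truth
    contig, correct bisulfite origin strand, and no QC-fail flag.  Everything
    else aligned is off-target (including the formally unclassified 5-95%
    band without strand error).
    """
    n_reads = n_aligned = n_on = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if read.is_secondary or read.is_supplementary:
                continue
            n_reads += 1
            if read.is_unmapped:
                continue
            n_aligned += 1
            truth = _read_truth(read, truth_map)
            positions = read.get_reference_positions()
            if not positions:
                continue
            if read.reference_name == truth["contig"]:
                lo, hi = truth["start"], truth["end"]
                inside = sum(1 for p in positions if lo <= p < hi)
            else:
                inside = 0
            frac = inside / len(positions)
            strand = Strand.SENSE if read.get_tag("YS") == "W" else Strand.ANTISENSE
            qc_fail = read.has_tag("XF") and read.get_tag("XF") == 1
            if frac >= on_target_fraction and strand == truth["strand"] and not qc_fail:
                n_on += 1
    if n_reads == 0:
        raise ValueError(f"no primary records in {bam_path}")
    mapp = n_aligned / n_reads
    on = n_on / n_aligned if n_aligned else 0.0
    return AlignmentEvaluation(n_reads, mapp, on, 1.0 - on if n_aligned else 0.0)


def evaluate_methylation(
    cgmap_path: str | Path,
    truth_counts_path: str | Path,
    penalize_missing_level: bool = False,
) -> MethylationEvaluation:
    """Compare called CG-site counts/levels with the simulator's truth counts.

    Truth sites missing from the call file contribute |0 - simulated_total| to
    coverage MAE and are excluded from level MAE (unless
    ``penalize_missing_level`` imputes a level error of 0.5).
    """
    from .call import read_cgmap

    truth = read_truth_counts(truth_counts_path)
    cg_truth = {
        k: (m, t) for k, (ctx, m, t) in truth.items() if ctx == "CG" and t > 0
    }
    if not cg_truth:
        raise ValueError(f"no covered CG truth sites in {truth_counts_path}")

    called: dict[tuple[str, int, str], tuple[int, int]] = {}
    for rec in read_cgmap(cgmap_path):
        strand = "W" if rec.ref_nucleotide == "C" else "C"
        called[(rec.contig, rec.position_1based - 1, strand)] = (
            rec.methylated_count,
            rec.total_count,
        )

    cov_err_sum = 0.0
    lev_err_sum = 0.0
    n_lev = 0
    overlap = 0
    for key, (t_meth, t_total) in cg_truth.items():
        c = called.get(key)
        if c is None:
            cov_err_sum += t_total
            if penalize_missing_level:
                lev_err_sum += 0.5
                n_lev += 1
            continue
        overlap += 1
        c_meth, c_total = c
        cov_err_sum += abs(c_total - t_total)
        lev_err_sum += abs(c_meth / c_total - t_meth / t_total)
        n_lev += 1
    if overlap == 0:
        raise ValueError("zero overlapping sites between call file and truth")
    n_sites = len(cg_truth)
    return MethylationEvaluation(
        coverage_mae=cov_err_sum / n_sites,
        level_mae=lev_err_sum / n_lev if n_lev else 0.0,
        n_sites=n_sites,
    )
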