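"""Strand-aware per-site methylation calling from coordinate-sorted alignments.

Sense-strand reads (YS:W) vote at reference C positions (C methylated,
T unmethylated); antisense reads (YS:C) vote at reference G positions
(G methylated, A unmethylated).  Overlapping mates of one fragment are
counted once: the higher-base-quality call wins, ties go to read 1.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .reference import (
    CTX_CG,
    CONTEXT_NAMES,
    GenomeReference,
    Strand,
    context_code_arrays,
    methylation_context,
)

logger = logging.getLogger(__name__)


@dataclass
class CallFilters:
    min_mapq: int = 20  # strict: reads with mapq exactly min_mapq are excluded
    min_base_quality: int = 0
    cg_only: bool = False
    exclude_conversion_fail: bool = False
    exclude_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.min_base_quality < 0:
            raise ValueError("filters must be non-negative")


@dataclass
class MethylationCall:
    contig: str
    ref_nucleotide: str  # C (sense) | G (antisense)
    position_1based: int
    context_class: str  # CG | CHG | CHH
    dinucleotide: str
    methylated_count: int
    total_count: int

    @property
    def methylation_level(self) -> float:
        return self.methylated_count / self.total_count


def _format_level(level: float) -> str:
    if level == 0:
        return "0.0"
    if level == 1:
        return "1.0"
    return f"{level:.6g}"


def _read_passes(read: pysam.AlignedSegment, filters: CallFilters) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.mapping_quality <= filters.min_mapq:
        return False
    if filters.exclude_duplicates and read.is_duplicate:
        return False
    if filters.exclude_conversion_fail and read.has_tag("XF") and read.get_tag("XF") == 1:
        return False
    return True


def call_sites(
    bam_path: str | Path,
    ref: GenomeReference,
    filters: CallFilters | None = None,
) -> Iterator[MethylationCall]:
    """Stream per-site methylation calls from a coordinate-sorted, indexed BAM."""
    filters = filters or CallFilters()
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} is not indexed; run sort + index first")
        sort_order = bam.header.to_dict().get("HD", {}).get("SO", "")
        if sort_order != "coordinate":
            raise ValueError(f"{bam_path} is not coordinate-sorted (SO={sort_order!r})")
        for contig in bam.references:
            if contig not in ref.contigs:
                raise ValueError(f"BAM contig {contig!r} absent from reference")
            yield from _call_contig(bam, contig, ref, filters)


def _informative_columns(read: pysam.AlignedSegment, codes: np.ndarray, strand: Strand,
                         min_bq: int):
    """(ref_pos, methylated, base_quality) triples for one read's informative columns."""
    seq = read.query_sequence
    quals = read.query_qualities
    want = 1 if strand == Strand.SENSE else 2  # ref C vs ref G
    if strand == Strand.SENSE:
        meth_base, unmeth_base = "C", "T"
    else:
        meth_base, unmeth_base = "G", "A"
    out = []
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if codes[rpos] != want:
            continue
        bq = quals[qpos] if quals is not None else 60
        if bq < min_bq:
            continue
        b = seq[qpos]
        if b == meth_base:
            out.append((rpos, True, bq))
        elif b == unmeth_base:
            out.append((rpos, False, bq))
    return out


def _call_contig(bam, contig: str, ref: GenomeReference, filters: CallFilters):
    seq = ref.contigs[contig]
    from .reference import encode_bases

    codes = encode_bases(seq)
    n = len(seq)
    sense_meth = np.zeros(n, dtype=np.int32)
    sense_total = np.zeros(n, dtype=np.int32)
    anti_meth = np.zeros(n, dtype=np.int32)
    anti_total = np.zeros(n, dtype=np.int32)
    n_missing_tag = 0

    # fragment-level dedup of overlapping mates: buffer first mate's columns
    pending: dict[str, tuple[Strand, list]] = {}

    def _apply(strand: Strand, cols):
        meth = sense_meth if strand == Strand.SENSE else anti_meth
        total = sense_total if strand == Strand.SENSE else anti_total
        for rpos, is_meth, _bq in cols:
            total[rpos] += 1
            if is_meth:
                meth[rpos] += 1

    for read in bam.fetch(contig):
        if not _read_passes(read, filters):
            continue
        if not read.has_tag("YS"):
            n_missing_tag += 1
            continue
        strand = Strand.SENSE if read.get_tag("YS") == "W" else Strand.ANTISENSE
        cols = _informative_columns(read, codes, strand, filters.min_base_quality)
        expect_mate = (
            read.is_paired
            and not read.mate_is_unmapped
            and read.next_reference_id == read.reference_id
        )
        if not expect_mate:
            _apply(strand, cols)
            continue
        prev = pending.pop(read.query_name, None)
        if prev is None:
            pending[read.query_name] = (strand, [(p, m, q, read.is_read1) for p, m, q in cols])
            continue
        prev_strand, prev_cols = prev
        merged: dict[int, tuple[bool, int, bool]] = {
            p: (m, q, r1) for p, m, q, r1 in prev_cols
        }
        for p, m, q in cols:
            cur = (m, q, read.is_read1)
            old = merged.get(p)
            if old is None:
                merged[p] = cur
            else:
                # higher base quality wins; ties take read 1
                if cur[1] > old[1] or (cur[1] == old[1] and cur[2] and not old[2]):
                    merged[p] = cur
        # mates share one template; strand tag should agree — trust read 1's
        strand_use = prev_strand
        _apply(strand_use, [(p, m, q) for p, (m, q, _r1) in merged.items()])
    # flush mates whose partner never arrived (mate filtered out or lost)
    for strand, cols in pending.values():
        _apply(strand, [(p, m, q) for p, m, q, _r1 in cols])
    if n_missing_tag:
        logger.warning("%d reads on %s lacked a YS tag and were skipped", n_missing_tag, contig)

    sense_ctx, anti_ctx = context_code_arrays(seq)
    covered = np.nonzero((sense_total > 0) | (anti_total > 0))[0]
    for pos in covered:
        pos = int(pos)
        for strand, meth, total, ctx_arr, nuc in (
            (Strand.SENSE, sense_meth, sense_total, sense_ctx, "C"),
            (Strand.ANTISENSE, anti_meth, anti_total, anti_ctx, "G"),
        ):
            if total[pos] == 0:
                continue
            code = int(ctx_arr[pos])
            if code == 0:
                continue
            cls = CONTEXT_NAMES[code]
            if filters.cg_only and code != CTX_CG:
                continue
            if cls == "unknown":
                cls = "CHH"  # undefined context reported CHH-like, never in CG-only output
            ctx = methylation_context(ref, contig, pos, strand)
            yield MethylationCall(
                contig, nuc, pos + 1, cls, ctx.dinucleotide,
                int(meth[pos]), int(total[pos]),
            )


# --------------------------------------------------------------------------
# CGmap and bedGraph serialization
# --------------------------------------------------------------------------


def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_cgmap(calls: Iterable[MethylationCall], out_path: str | Path) -> None:
    """8-column CGmap: contig, C|G, 1-based pos, context, dinucleotide, level,
    methylated count, total count."""
    with _open_maybe_gz(out_path, "wt") as fh:
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.ref_nucleotide}\t{c.position_1based}\t{c.context_class}"
                f"\t{c.dinucleotide}\t{_format_level(c.methylation_level)}"
                f"\t{c.methylated_count}\t{c.total_count}\n"
            )


def read_cgmap(path: str | Path) -> Iterator[MethylationCall]:
    with _open_maybe_gz(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 CGmap columns, got {len(f)}")
            try:
                yield MethylationCall(f[0], f[1], int(f[2]), f[3], f[4], int(f[6]), int(f[7]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None


def write_bedgraph(calls: Iterable[MethylationCall], out_path: str | Path) -> None:
    """Bismark-coverage-style 6 columns: contig, 0-based start, end, percent
    methylation, methylated count, unmethylated count."""
    with _open_maybe_gz(out_path, "wt") as fh:
        for c in calls:
            pct = 100.0 * c.methylated_count / c.total_count
            fh.write(
                f"{c.contig}\t{c.position_1based - 1}\t{c.position_1based}"
                f"\t{pct:.6g}\t{c.methylated_count}\t{c.total_count - c.methylated_count}\n"
            )


def call_and_write(
    bam_path: str | Path,
    ref: GenomeReference,
    out_prefix: str | Path,
    filters: CallFilters | None = None,
    bedgraph: bool = False,
) -> dict:
    """Run the caller and write CGmap (and optionally bedGraph) files."""
    calls = list(call_sites(bam_path, ref, filters))
    cgmap_path = f"{out_prefix}.CGmap"
    write_cgmap(calls, cgmap_path)
    out = {"cgmap": cgmap_path, "n_sites": len(calls)}
    if bedgraph:
        bg = f"{out_prefix}.bedGraph"
        write_bedgraph(calls, bg)
        out["bedgraph"] = bg
    return out
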