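"""Independent oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: the affine-gap
local aligner is a standalone numba DP, the pileup oracle goes through
htslib's pileup engine, and the aggregation oracle is a single-pass outer
join.
"""

from __future__ import annotations

import numpy as np
import pysam
from numba import njit

from methylbolt.reference import ConversionPattern, convert_sequence, reverse_complement


@njit(cache=True)
def _sw_affine(q: np.ndarray, t: np.ndarray, match: int, mismatch: int,
               gap_open: int, gap_extend: int) -> int:
    """Best local alignment score; a gap of length g costs gap_open + g*gap_extend."""
    m, n = len(q), len(t)
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, -10**9, dtype=np.int64)
    best = 0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = 0
        F = -10**9
        for j in range(1, n + 1):
            E[j] = max(H[j] - first, E[j] - gap_extend)
            F = max(H[j - 1] - first, F - gap_extend)
            s = match if q[i - 1] == t[j - 1] else -mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def sw_local_score(query: str, target: str, match=1, mismatch=4, gap_open=6,
                   gap_extend=1) -> int:
    q = np.frombuffer(query.encode(), dtype=np.uint8).astype(np.int64)
    t = np.frombuffer(target.encode(), dtype=np.uint8).astype(np.int64)
    return int(_sw_affine(q, t, match, mismatch, gap_open, gap_extend))


def best_bisulfite_score(read: str, index, pattern: ConversionPattern, **scores) -> int:
    """Exhaustive best local alignment score over both converted strands."""
    if pattern == ConversionPattern.C2T:
        q = convert_sequence(read, ConversionPattern.C2T)
    else:
        q = convert_sequence(reverse_complement(read), ConversionPattern.C2T)
    best = 0
    for contig in index.contig_names:
        for strand_seq in (index.sense_converted[contig], index.antisense_converted[contig]):
            best = max(best, sw_local_score(q, strand_seq, **scores))
    return best


def brute_force_substring_hits(query: str, sequences: dict[str, str]) -> set[tuple[str, int]]:
    """All exact occurrences of query in each sequence, by naive scan."""
    out = set()
    for name, seq in sequences.items():
        start = 0
        while True:
            i = seq.find(query, start)
            if i < 0:
                break
            out.add((name, i))
            start = i + 1
    return out


def naive_pileup_counts(bam_path, ref, min_mapq: int = 20):
    """Per-site counts via htslib pileup columns, classified by the YS tag.

    Returns {(contig, pos0, 'W'|'C'): (meth, total)}.  Reads with mapq <=
    min_mapq are excluded (strict threshold).  Assumes non-overlapping mates.
    """
    out: dict[tuple[str, int, str], list[int]] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for col in bam.pileup(min_base_quality=0, max_depth=100000,
                              ignore_overlaps=False, stepper="nofilter"):
            contig = col.reference_name
            pos = col.reference_pos
            ref_base = ref.contigs[contig][pos]
            for pr in col.pileups:
                read = pr.alignment
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality <= min_mapq:
                    continue
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                strand = read.get_tag("YS")
                base = read.query_sequence[pr.query_position]
                if strand == "W" and ref_base == "C":
                    if base == "C":
                        vote = 1
                    elif base == "T":
                        vote = 0
                    else:
                        continue
                elif strand == "C" and ref_base == "G":
                    if base == "G":
                        vote = 1
                    elif base == "A":
                        vote = 0
                    else:
                        continue
                else:
                    continue
                key = (contig, pos, strand)
                rec = out.setdefault(key, [0, 0])
                rec[1] += 1
                rec[0] += vote
    return {k: tuple(v) for k, v in out.items()}


def naive_aggregate_sites(cgmap_tables, min_coverage, min_proportion):
    """Retained-site set by full outer join then filtering.

    cgmap_tables: list of {site_key: total_count}.
    """
    all_sites = set()
    for t in cgmap_tables:
        all_sites |= set(t)
    n = len(cgmap_tables)
    retained = set()
    for site in all_sites:
        count = sum(1 for t in cgmap_tables if t.get(site, 0) >= min_coverage)
        if count / n >= min_proportion - 1e-12:
            retained.add(site)
    return retained
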