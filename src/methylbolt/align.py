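"""3-base bisulfite read alignment against the dual-strand converted index.

Reads are fully in-silico converted, seeded by exact suffix-array matches in
converted space, extended with affine-gap local alignment, and reported on
the unconverted sense reference with bisulfite tags:

    YS  bisulfite strand (W sense / C antisense)
    YC  conversion pattern used (C2T / G2A)
    XB  read-level methylation call string (run-length ints for uncalled
        stretches, x/X CH unmeth/meth, y/Y CG unmeth/meth, Z<base> variant)
    XF  conversion status (0 pass / 1 fail)
    AS/XS  best / suboptimal alignment score
    ZT  pass-through FASTQ comment (simulation truth)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import Align

from .index import BisulfiteIndex
from .reference import (
    ConversionPattern,
    GenomeReference,
    Strand,
    context_code_arrays,
    convert_sequence,
    reverse_complement,
)

CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_S = 0, 1, 2, 4


@dataclass
class ScoringScheme:
    """Affine-gap local scoring; a gap of length g costs gap_open + g*gap_extend."""

    match: int = 1
    mismatch_penalty: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    clip_penalty: int = 5
    ambiguity_penalty: int = 20  # mapq points subtracted for bisulfite-ambiguous hits

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        for f in ("mismatch_penalty", "gap_open", "gap_extend", "clip_penalty",
                  "ambiguity_penalty"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def ambiguity_window(self) -> int:
        return self.match * 10

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = -self.mismatch_penalty
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def assess_conversion_pattern(
    read1_seq: str, read2_seq: str | None = None, threshold: float = 0.1
) -> ConversionPattern:
    """Choose a conversion pattern from read base composition.

    Counts C vs G over the read, or over read1 + reverse-complement(read2)
    for a pair (mates share one template, so mate 2 is complemented before
    pooling).  A low C proportion selects C2T, a low G proportion G2A,
    otherwise BOTH.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    seq = read1_seq
    if read2_seq is not None:
        seq += reverse_complement(read2_seq)
    c = seq.count("C")
    g = seq.count("G")
    if c + g == 0:
        return ConversionPattern.BOTH
    if c / (c + g) <= threshold:
        return ConversionPattern.C2T
    if g / (c + g) <= threshold:
        return ConversionPattern.G2A
    return ConversionPattern.BOTH


@dataclass
class Candidate:
    """One candidate placement, still in converted space (query orientation)."""

    contig: str
    strand: Strand  # bisulfite strand == which converted text was hit
    pattern: ConversionPattern  # C2T or G2A
    conv_pos: int  # 0-based start on the converted sequence
    score: int
    cigar: list[tuple[int, int]]  # query-orientation cigar incl. soft clips
    ref_span: int

    @property
    def sense_pos_key(self) -> tuple[str, Strand, int]:
        return (self.contig, self.strand, self.conv_pos)


def _cigar_from_coordinates(coords, qlen: int, tstart_offset: int):
    """Convert Bio.Align coordinates to (cigar, target_start, ref_span)."""
    t, q = coords[0], coords[1]
    cigar: list[tuple[int, int]] = []
    if q[0] > 0:
        cigar.append((CIGAR_S, int(q[0])))
    for i in range(len(t) - 1):
        dt = int(t[i + 1] - t[i])
        dq = int(q[i + 1] - q[i])
        if dt and dq:
            cigar.append((CIGAR_M, dt))
        elif dt:
            cigar.append((CIGAR_D, dt))
        elif dq:
            cigar.append((CIGAR_I, dq))
    if qlen - int(q[-1]) > 0:
        cigar.append((CIGAR_S, qlen - int(q[-1])))
    ref_span = int(t[-1] - t[0])
    return cigar, tstart_offset + int(t[0]), ref_span


def align_read(
    read_seq: str,
    index: BisulfiteIndex,
    scoring: ScoringScheme,
    pattern: ConversionPattern,
    seed_min_length: int | None = None,
    min_score: int = 20,
    pad: int = 15,
    max_seed_hits: int = 100,
    rescue: bool = True,
    _aligner: Align.PairwiseAligner | None = None,
) -> list[Candidate]:
    """Seed-and-extend one read under one concrete conversion pattern.

    Returns candidates sorted by descending score.  When no seed of
    ``seed_min_length`` hits, seeds are retried at half length; if the index
    text is small (<= 50 kb) a final exhaustive local-alignment fallback over
    both converted strands is used, so desk-scale alignments match the
    brute-force oracle even for seedless reads.
    """
    if pattern == ConversionPattern.BOTH:
        raise ValueError("align_read requires a concrete pattern")
    k = seed_min_length or index.seed_min_length
    if len(read_seq) < k:
        return []
    if pattern == ConversionPattern.C2T:
        q = convert_sequence(read_seq, ConversionPattern.C2T)
    else:
        q = convert_sequence(reverse_complement(read_seq), ConversionPattern.C2T)
    aligner = _aligner or scoring.make_aligner()

    diags = _seed_diagonals(q, index, k, max_seed_hits)
    candidates = []
    if diags:
        candidates = _extend_diagonals(q, diags, index, scoring, aligner, pattern, pad)
    elif not rescue:
        pass
    elif len(index.text) <= 50_000:
        candidates = _exhaustive_candidates(q, index, aligner, pattern)
    else:
        # bounded rescue on large texts: half-length seeds, extend only
        # diagonals whose gap-free score estimate could clear min_score
        k2 = max(10, k // 2)
        if k2 < k and len(q) >= k2:
            diags = _seed_diagonals(q, index, k2, max_seed_hits)
            diags = _prefilter_diagonals(q, diags, index, scoring, min_score)
            if diags:
                candidates = _extend_diagonals(q, diags, index, scoring, aligner, pattern, pad)
    candidates = [c for c in candidates if c.score >= min_score]
    candidates.sort(key=lambda c: (-c.score, index.contig_names.index(c.contig),
                                   _sense_pos(c, index), c.strand.value))
    return candidates


def _sense_pos(cand: Candidate, index: BisulfiteIndex) -> int:
    if cand.strand == Strand.SENSE:
        return cand.conv_pos
    return index.lengths[cand.contig] - cand.conv_pos - cand.ref_span


def _seed_diagonals(q: str, index: BisulfiteIndex, k: int, max_seed_hits: int):
    offsets = list(range(0, len(q) - k + 1, k))
    if offsets and offsets[-1] != len(q) - k:
        offsets.append(len(q) - k)
    diags: set[tuple[str, Strand, int]] = set()
    for off in offsets:
        for hit in index.search(q[off : off + k], max_hits=max_seed_hits, allow_short=True):
            diags.add((hit.contig, hit.strand, hit.offset - off))
    # cluster diagonals within 8 bp of one another
    out: list[tuple[str, Strand, int]] = []
    for key in sorted(diags, key=lambda d: (d[0], d[1].value, d[2])):
        if out and out[-1][0] == key[0] and out[-1][1] == key[1] and abs(out[-1][2] - key[2]) <= 8:
            continue
        out.append(key)
    return out


def _prefilter_diagonals(q, diags, index, scoring, min_score, margin=12):
    """Keep diagonals whose gap-free diagonal score could plausibly clear min_score."""
    import numpy as np

    qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
    out = []
    for contig, strand, diag in diags:
        conv = index.converted_array(contig, strand)
        lo = max(0, diag)
        wa = conv[lo : lo + len(q)]
        m = int(np.count_nonzero(qa[: len(wa)] == wa))
        est = m * scoring.match - (len(wa) - m) * scoring.mismatch_penalty
        if est >= min_score - margin:
            out.append((contig, strand, diag))
    return out


def _extend_diagonals(q, diags, index, scoring, aligner, pattern, pad):
    candidates = []
    for contig, strand, diag in diags:
        conv_seq = index.converted_sequence(contig, strand)
        exact = conv_seq[diag : diag + len(q)]
        if len(exact) == len(q) and exact == q:
            candidates.append(
                Candidate(contig, strand, pattern, diag, len(q) * scoring.match,
                          [(CIGAR_M, len(q))], len(q))
            )
            continue
        lo = max(0, diag - pad)
        hi = min(len(conv_seq), diag + len(q) + pad)
        window = conv_seq[lo:hi]
        if not window:
            continue
        alns = aligner.align(window, q)
        if len(alns) == 0:
            continue
        aln = alns[0]
        cigar, conv_pos, ref_span = _cigar_from_coordinates(aln.coordinates, len(q), lo)
        if ref_span == 0:
            continue
        candidates.append(Candidate(contig, strand, pattern, conv_pos, int(aln.score),
                                    cigar, ref_span))
    return candidates


def _exhaustive_candidates(q, index, aligner, pattern):
    candidates = []
    for contig in index.contig_names:
        for strand in (Strand.SENSE, Strand.ANTISENSE):
            conv_seq = index.converted_sequence(contig, strand)
            if not conv_seq:
                continue
            alns = aligner.align(conv_seq, q)
            if len(alns) == 0:
                continue
            aln = alns[0]
            cigar, conv_pos, ref_span = _cigar_from_coordinates(aln.coordinates, len(q), 0)
            if ref_span == 0:
                continue
            candidates.append(Candidate(contig, strand, pattern, conv_pos,
                                        int(aln.score), cigar, ref_span))
    return candidates


def score_mapq(
    best_score: int,
    second_score: int | None,
    second_other_strand: bool,
    scoring: ScoringScheme,
) -> int:
    """Mapping quality from alignment uniqueness plus the bisulfite-ambiguity penalty."""
    if best_score <= 0:
        return 0
    if second_score is None:
        mapq = 60
    else:
        mapq = max(0, min(60, round(60 * (best_score - second_score) / best_score)))
    if (
        second_score is not None
        and second_other_strand
        and second_score >= best_score - scoring.ambiguity_window
    ):
        mapq = max(0, mapq - scoring.ambiguity_penalty)
    return mapq


@dataclass
class NormalizedAlignment:
    """Candidate re-projected onto the unconverted sense reference."""

    contig: str
    pos: int  # 0-based on the sense reference
    reverse: bool  # mapping orientation of the stored (sense-oriented) sequence
    strand: Strand
    pattern: ConversionPattern
    cigar: list[tuple[int, int]]
    seq: str  # stored in sense-reference orientation
    quals: str
    score: int
    ref_span: int


def normalize_strand(
    cand: Candidate, index: BisulfiteIndex, read_seq: str, quals: str
) -> NormalizedAlignment:
    """Project a converted-space candidate onto sense-reference coordinates.

    Antisense-strand hits get pos' = contig_length - conv_pos - ref_span and
    reversed cigar; the stored sequence always matches sense orientation, and
    the bisulfite strand is carried separately (YS tag).
    """
    q_read = read_seq if cand.pattern == ConversionPattern.C2T else reverse_complement(read_seq)
    q_qual = quals if cand.pattern == ConversionPattern.C2T else quals[::-1]
    if cand.strand == Strand.SENSE:
        pos = cand.conv_pos
        cigar = cand.cigar
        seq, qv = q_read, q_qual
    else:
        pos = index.lengths[cand.contig] - cand.conv_pos - cand.ref_span
        cigar = cand.cigar[::-1]
        seq, qv = reverse_complement(q_read), q_qual[::-1]
    reverse = (cand.pattern == ConversionPattern.G2A) != (cand.strand == Strand.ANTISENSE)
    return NormalizedAlignment(
        cand.contig, pos, reverse, cand.strand, cand.pattern, cigar, seq, qv,
        cand.score, cand.ref_span,
    )


# --------------------------------------------------------------------------
# read-level methylation calling and conversion status
# --------------------------------------------------------------------------


class ReferenceContext:
    """Per-contig cache of reference sequence plus context code arrays."""

    def __init__(self, ref: GenomeReference):
        self.ref = ref
        self._cache: dict[str, tuple] = {}

    def get(self, contig: str):
        if contig not in self._cache:
            seq = self.ref.contigs[contig]
            sense_ctx, anti_ctx = context_code_arrays(seq)
            self._cache[contig] = (seq, sense_ctx, anti_ctx)
        return self._cache[contig]


@dataclass
class ReadMethylation:
    calls: list[str] = field(default_factory=list)  # per aligned query base
    variants: list[tuple[int, str, str]] = field(default_factory=list)  # (ref_pos, ref, read)
    cg_meth: int = 0
    cg_unmeth: int = 0
    ch_meth: int = 0
    ch_unmeth: int = 0

    @property
    def xb_string(self) -> str:
        out: list[str] = []
        run = 0
        for c in self.calls:
            if c in ("=", "."):
                run += 1
            else:
                if run:
                    out.append(str(run))
                    run = 0
                out.append(c)
        if run:
            out.append(str(run))
        return "".join(out)


def call_read_methylation(
    aln: NormalizedAlignment, ref_ctx: ReferenceContext
) -> ReadMethylation:
    """Walk cigar-aligned columns against the unconverted reference.

    Differences explainable by bisulfite conversion become methylation calls
    (sense reads at ref C: C methylated / T unmethylated; antisense reads at
    ref G: G methylated / A unmethylated); other mismatches are variants.
    """
    seq, sense_ctx, anti_ctx = ref_ctx.get(aln.contig)
    res = ReadMethylation()
    rpos = aln.pos
    qpos = 0
    sense = aln.strand == Strand.SENSE
    for op, length in aln.cigar:
        if op == CIGAR_S:
            qpos += length
        elif op == CIGAR_M:
            for i in range(length):
                rb = seq[rpos + i]
                qb = aln.seq[qpos + i]
                if sense and rb == "C":
                    ctx = sense_ctx[rpos + i]
                    if qb == "C":
                        res.calls.append("Y" if ctx == 1 else "X")
                        _bump(res, ctx, True)
                    elif qb == "T":
                        res.calls.append("y" if ctx == 1 else "x")
                        _bump(res, ctx, False)
                    else:
                        res.calls.append("Z" + qb)
                        res.variants.append((rpos + i, rb, qb))
                elif not sense and rb == "G":
                    ctx = anti_ctx[rpos + i]
                    if qb == "G":
                        res.calls.append("Y" if ctx == 1 else "X")
                        _bump(res, ctx, True)
                    elif qb == "A":
                        res.calls.append("y" if ctx == 1 else "x")
                        _bump(res, ctx, False)
                    else:
                        res.calls.append("Z" + qb)
                        res.variants.append((rpos + i, rb, qb))
                elif qb == rb and qb != "N":
                    res.calls.append("=")
                else:
                    res.calls.append("Z" + qb)
                    res.variants.append((rpos + i, rb, qb))
            rpos += length
            qpos += length
        elif op == CIGAR_I:
            for i in range(length):
                res.calls.append(".")
            res.variants.append((rpos, "-", aln.seq[qpos : qpos + length]))
            qpos += length
        elif op == CIGAR_D:
            res.variants.append((rpos, seq[rpos : rpos + length], "-"))
            rpos += length
    return res


def _bump(res: ReadMethylation, ctx: int, methylated: bool) -> None:
    if ctx == 1:
        if methylated:
            res.cg_meth += 1
        else:
            res.cg_unmeth += 1
    else:
        if methylated:
            res.ch_meth += 1
        else:
            res.ch_unmeth += 1


def assess_read_conversion(
    methylations: list[ReadMethylation],
    min_ch_sites: int = 3,
    max_ch_meth_fraction: float = 0.5,
) -> bool:
    """True = pass.  Pooled over the read or pair; too few CH sites passes."""
    ch_meth = sum(m.ch_meth for m in methylations)
    ch_total = ch_meth + sum(m.ch_unmeth for m in methylations)
    if ch_total < min_ch_sites:
        return True
    return ch_meth / ch_total <= max_ch_meth_fraction


# --------------------------------------------------------------------------
# driver: FASTQ in, tagged SAM/BAM out
# --------------------------------------------------------------------------


def _second_best(candidates: list[Candidate], best: Candidate, index: BisulfiteIndex):
    """First candidate at a genuinely different locus than the best."""
    bpos = _sense_pos(best, index)
    for c in candidates:
        if c is best:
            continue
        if (
            c.contig != best.contig
            or c.strand != best.strand
            or abs(_sense_pos(c, index) - bpos) > 30
        ):
            return c
    return None


def _pick_pair(c1: list[Candidate], c2: list[Candidate], index: BisulfiteIndex,
               max_insert: int):
    """Best properly oriented pair by summed score, else None."""
    best = None
    for a in c1[:10]:
        pa = _sense_pos(a, index)
        for b in c2[:10]:
            if a.contig != b.contig or a.strand != b.strand:
                continue
            pb = _sense_pos(b, index)
            if abs(pb - pa) > max_insert:
                continue
            total = a.score + b.score
            if best is None or total > best[0]:
                best = (total, a, b)
    return best


class BisulfiteAligner:
    """Stateful aligner over one index; aligns reads/pairs and emits records."""

    def __init__(
        self,
        index: BisulfiteIndex,
        scoring: ScoringScheme | None = None,
        undirectional: bool = False,
        ct_threshold: float = 0.1,
        seed_min_length: int | None = None,
        min_score: int = 20,
        min_ch_sites: int = 3,
        max_ch_meth_fraction: float = 0.5,
        max_insert: int = 1000,
    ):
        self.index = index
        self.scoring = scoring or ScoringScheme()
        self.undirectional = undirectional
        self.ct_threshold = ct_threshold
        self.seed_min_length = seed_min_length or index.seed_min_length
        self.min_score = min_score
        self.min_ch_sites = min_ch_sites
        self.max_ch_meth_fraction = max_ch_meth_fraction
        self.max_insert = max_insert
        self.ref_ctx = ReferenceContext(index.reference())
        self._aligner = self.scoring.make_aligner()

    # -- pattern planning --------------------------------------------------

    def _patterns(self, seq1: str, seq2: str | None) -> list[ConversionPattern]:
        if not self.undirectional:
            return [ConversionPattern.C2T]
        p = assess_conversion_pattern(seq1, seq2, self.ct_threshold)
        if p == ConversionPattern.BOTH:
            return [ConversionPattern.C2T, ConversionPattern.G2A]
        return [p]

    def _align_one(
        self, seq: str, pattern: ConversionPattern, rescue: bool = False
    ) -> list[Candidate]:
        return align_read(
            seq, self.index, self.scoring, pattern,
            seed_min_length=self.seed_min_length, min_score=self.min_score,
            rescue=rescue, _aligner=self._aligner,
        )

    def _align_patterns(self, seq: str, patterns) -> dict:
        """Candidates per pattern; the costly no-seed rescue runs only when no
        pattern produced anything."""
        out = {p: self._align_one(seq, p) for p in patterns}
        if not any(out.values()):
            out = {p: self._align_one(seq, p, rescue=True) for p in patterns}
        return out

    # -- single-end --------------------------------------------------------

    def align_single(self, name: str, seq: str, quals: str, comment: str | None = None):
        """Return a list with one SAM-ready record dict."""
        per_pattern = []
        cands_by_pattern = self._align_patterns(seq, self._patterns(seq, None))
        for p, cands in cands_by_pattern.items():
            per_pattern.append((cands[0].score if cands else -1, p, cands))
        per_pattern.sort(key=lambda t: -t[0])
        best_score, pattern, cands = per_pattern[0]
        forced_zero = (
            len(per_pattern) > 1 and per_pattern[0][0] == per_pattern[1][0] and best_score >= 0
        )
        if forced_zero:
            # equal best across patterns: deterministic C2T preference, mapq 0
            for s, p, c in per_pattern:
                if s == best_score and p == ConversionPattern.C2T:
                    pattern, cands = p, c
        if not cands:
            return [self._unmapped(name, seq, quals, comment)]
        all_cands = sorted(
            (c for _, _, cs in per_pattern for c in cs), key=lambda c: -c.score
        )
        best = cands[0]
        second = _second_best(all_cands, best, self.index)
        mapq = 0 if forced_zero else score_mapq(
            best.score, second.score if second else None,
            second is not None and second.strand != best.strand, self.scoring,
        )
        norm = normalize_strand(best, self.index, seq, quals)
        meth = call_read_methylation(norm, self.ref_ctx)
        conv_pass = assess_read_conversion([meth], self.min_ch_sites, self.max_ch_meth_fraction)
        return [
            self._record(name, norm, meth, mapq, second, conv_pass, comment,
                         paired=False, first=True, mate=None)
        ]

    # -- paired-end --------------------------------------------------------

    def align_pair(self, name, seq1, quals1, seq2, quals2, comment1=None, comment2=None):
        patterns = self._patterns(seq1, seq2)
        c1_by = self._align_patterns(seq1, patterns)
        mate_patterns = [
            ConversionPattern.G2A if p == ConversionPattern.C2T else ConversionPattern.C2T
            for p in patterns
        ]
        c2_by = self._align_patterns(seq2, mate_patterns)
        per_pattern = []
        for p, p2 in zip(patterns, mate_patterns):
            c1 = c1_by[p]
            c2 = c2_by[p2]
            pair = _pick_pair(c1, c2, self.index, self.max_insert)
            if pair is not None:
                total = pair[0]
            else:
                total = (c1[0].score if c1 else 0) + (c2[0].score if c2 else 0)
                total = total if (c1 or c2) else -1
            per_pattern.append((total, p, c1, c2, pair))
        per_pattern.sort(key=lambda t: -t[0])
        total, pattern, c1, c2, pair = per_pattern[0]
        forced_zero = len(per_pattern) > 1 and per_pattern[0][0] == per_pattern[1][0] and total >= 0
        if forced_zero:
            for t in per_pattern:
                if t[0] == total and t[1] == ConversionPattern.C2T:
                    total, pattern, c1, c2, pair = t
        all1 = sorted((c for t in per_pattern for c in t[2]), key=lambda c: -c.score)
        all2 = sorted((c for t in per_pattern for c in t[3]), key=lambda c: -c.score)
        if pair is not None:
            b1, b2 = pair[1], pair[2]
            proper = True
        else:
            b1 = c1[0] if c1 else None
            b2 = c2[0] if c2 else None
            proper = False

        norms, meths = {}, {}
        for key, best, seq, quals in (("1", b1, seq1, quals1), ("2", b2, seq2, quals2)):
            if best is not None:
                norms[key] = normalize_strand(best, self.index, seq, quals)
                meths[key] = call_read_methylation(norms[key], self.ref_ctx)
        conv_pass = assess_read_conversion(
            list(meths.values()), self.min_ch_sites, self.max_ch_meth_fraction
        ) if meths else True

        records = []
        for key, best, allc, seq, quals, comment, first in (
            ("1", b1, all1, seq1, quals1, comment1, True),
            ("2", b2, all2, seq2, quals2, comment2, False),
        ):
            other = norms.get("2" if key == "1" else "1")
            if best is None:
                rec = self._unmapped(name, seq, quals, comment, paired=True,
                                     first=first, mate=other)
            else:
                second = _second_best(allc, best, self.index)
                mapq = 0 if forced_zero else score_mapq(
                    best.score, second.score if second else None,
                    second is not None and second.strand != best.strand, self.scoring,
                )
                rec = self._record(name, norms[key], meths[key], mapq, second,
                                   conv_pass, comment, paired=True, first=first,
                                   mate=other, proper=proper)
            records.append(rec)
        return records

    # -- record assembly ---------------------------------------------------

    def _record(self, name, norm: NormalizedAlignment, meth: ReadMethylation, mapq,
                second, conv_pass, comment, paired, first, mate, proper=False):
        flag = 0
        if paired:
            flag |= 0x1 | (0x40 if first else 0x80)
            if proper:
                flag |= 0x2
            if mate is None:
                flag |= 0x8
            elif mate.reverse:
                flag |= 0x20
        if norm.reverse:
            flag |= 0x10
        tags = [
            ("AS", norm.score), ("XS", second.score if second else 0),
            ("YS", "W" if norm.strand == Strand.SENSE else "C"),
            ("YC", norm.pattern.value), ("XB", meth.xb_string),
            ("XF", 0 if conv_pass else 1),
        ]
        if comment:
            tags.append(("ZT", comment))
        rec = {
            "name": name, "flag": flag, "contig": norm.contig, "pos": norm.pos,
            "mapq": mapq, "cigar": norm.cigar, "seq": norm.seq, "quals": norm.quals,
            "tags": tags,
        }
        if paired and mate is not None:
            rec["mate_contig"] = mate.contig
            rec["mate_pos"] = mate.pos
            if mate.contig == norm.contig:
                lo = min(norm.pos, mate.pos)
                hi = max(norm.pos + norm.ref_span, mate.pos + mate.ref_span)
                rec["tlen"] = (hi - lo) if norm.pos <= mate.pos else -(hi - lo)
        return rec

    def _unmapped(self, name, seq, quals, comment, paired=False, first=True, mate=None):
        flag = 0x4
        if paired:
            flag |= 0x1 | (0x40 if first else 0x80)
            if mate is None:
                flag |= 0x8
            elif mate.reverse:
                flag |= 0x20
        tags = [("XF", 0)]
        if comment:
            tags.append(("ZT", comment))
        rec = {"name": name, "flag": flag, "contig": None, "pos": -1, "mapq": 0,
               "cigar": None, "seq": seq, "quals": quals, "tags": tags}
        if paired and mate is not None:
            rec["mate_contig"] = mate.contig
            rec["mate_pos"] = mate.pos
        return rec


# --------------------------------------------------------------------------
# SAM/BAM output
# --------------------------------------------------------------------------


def make_header(index: BisulfiteIndex, command: str = "") -> pysam.AlignmentHeader:
    from . import __version__

    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": index.lengths[name]} for name in index.contig_names
            ],
            "PG": [{"ID": "methylbolt", "PN": "methylbolt", "VN": __version__,
                    "CL": command or "methylbolt align"}],
        }
    )


def record_to_segment(rec: dict, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec["name"]
    seg.flag = rec["flag"]
    if rec["contig"] is not None:
        seg.reference_id = header.get_tid(rec["contig"])
        seg.reference_start = rec["pos"]
        seg.cigartuples = rec["cigar"]
    else:
        seg.reference_id = -1
        seg.reference_start = -1
    seg.mapping_quality = rec["mapq"]
    seg.query_sequence = rec["seq"]
    seg.query_qualities = pysam.qualitystring_to_array(rec["quals"])
    if "mate_contig" in rec:
        seg.next_reference_id = header.get_tid(rec["mate_contig"])
        seg.next_reference_start = rec["mate_pos"]
    elif rec["flag"] & 0x1:
        # mate unmapped: mirror own position per SAM convention
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = seg.reference_start
    seg.template_length = rec.get("tlen", 0)
    seg.set_tags(rec["tags"])
    return seg


def write_alignments(records, header: pysam.AlignmentHeader, out_path: str | Path,
                     out_format: str = "SAM") -> None:
    """Write SAM-ready record dicts (or AlignedSegments) to SAM or BAM."""
    mode = "wb" if out_format.upper() == "BAM" else "w"
    with pysam.AlignmentFile(str(out_path), mode, header=header) as fh:
        for rec in records:
            if isinstance(rec, dict):
                rec = record_to_segment(rec, header)
            fh.write(rec)


def align_fastq(
    index: BisulfiteIndex,
    fastq1: str | Path,
    fastq2: str | Path | None = None,
    out_path: str | Path = "out.bam",
    out_format: str = "BAM",
    command: str = "",
    **aligner_kwargs,
) -> dict:
    """Align a FASTQ (pair) end to end; returns summary counts."""
    aligner = BisulfiteAligner(index, **aligner_kwargs)
    header = make_header(index, command)
    n_reads = n_mapped = 0
    mode = "wb" if out_format.upper() == "BAM" else "w"
    with pysam.AlignmentFile(str(out_path), mode, header=header) as out:
        if fastq2 is None:
            with pysam.FastxFile(str(fastq1)) as fh:
                for entry in fh:
                    recs = aligner.align_single(
                        entry.name, entry.sequence.upper(), entry.quality, entry.comment
                    )
                    for rec in recs:
                        n_reads += 1
                        if not rec["flag"] & 0x4:
                            n_mapped += 1
                        out.write(record_to_segment(rec, header))
        else:
            with pysam.FastxFile(str(fastq1)) as f1, pysam.FastxFile(str(fastq2)) as f2:
                for e1, e2 in zip(f1, f2):
                    if e1.name != e2.name:
                        raise ValueError(
                            f"mate name mismatch: {e1.name!r} vs {e2.name!r}"
                        )
                    recs = aligner.align_pair(
                        e1.name, e1.sequence.upper(), e1.quality,
                        e2.sequence.upper(), e2.quality, e1.comment, e2.comment,
                    )
                    for rec in recs:
                        n_reads += 1
                        if not rec["flag"] & 0x4:
                            n_mapped += 1
                        out.write(record_to_segment(rec, header))
    return {"n_reads": n_reads, "n_mapped": n_mapped}


def sort_and_index(in_path: str | Path, out_path: str | Path) -> None:
    pysam.sort("-o", str(out_path), str(in_path))
    pysam.index(str(out_path))
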