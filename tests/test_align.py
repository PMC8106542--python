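import numpy as np
import pysam
import pytest

from methylbolt.align import (
    BisulfiteAligner,
    ScoringScheme,
    align_fastq,
    align_read,
    assess_conversion_pattern,
    assess_read_conversion,
    call_read_methylation,
    make_header,
    normalize_strand,
    record_to_segment,
    score_mapq,
    sort_and_index,
    write_alignments,
    NormalizedAlignment,
    ReadMethylation,
    ReferenceContext,
    CIGAR_M,
)
from methylbolt.index import build_index
from methylbolt.reference import (
    ConversionPattern,
    GenomeReference,
    Strand,
    convert_sequence,
    reverse_complement,
)
from methylbolt.simulate import SimulationParams, assign_profile, simulate_reads
from methylbolt.evaluate import evaluate_alignments

from conftest import random_sequence
from oracles import best_bisulfite_score

SCORING = ScoringScheme()


class TestAssessConversionPattern:
    def test_no_c_selects_c2t(self):
        assert assess_conversion_pattern("GGGGGGGG") == ConversionPattern.C2T

    def test_balanced_selects_both(self):
        assert assess_conversion_pattern("CCCCGGGG") == ConversionPattern.BOTH

    def test_no_c_no_g_is_both(self):
        assert assess_conversion_pattern("AATTAATT") == ConversionPattern.BOTH

    def test_pair_pooled_with_mate_complemented(self):
        # 1 C vs 19 G pooled over the pair -> 0.05 <= 0.1 -> C2T
        r1 = "C" + "G" * 9 + "A" * 10
        r2 = reverse_complement("G" * 10 + "T" * 10)  # contributes 10 G after revcomp
        assert assess_conversion_pattern(r1, r2) == ConversionPattern.C2T

    def test_low_g_selects_g2a(self):
        assert assess_conversion_pattern("CCCCCCCCCG" + "A" * 10) == ConversionPattern.G2A

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            assess_conversion_pattern("ACGT", threshold=0.6)


@pytest.fixture(scope="module")
def kb_genome():
    rng = np.random.default_rng(77)
    return GenomeReference({"chr1": random_sequence(rng, 1000)})


@pytest.fixture(scope="module")
def kb_index(kb_genome):
    return build_index(kb_genome, seed_min_length=19)


class TestAlignRead:
    def test_unique_error_free_read(self, kb_genome, kb_index):
        read = convert_sequence(kb_genome.contigs["chr1"][50:80], ConversionPattern.C2T)
        cands = align_read(read, kb_index, SCORING, ConversionPattern.C2T)
        assert cands
        best = cands[0]
        assert best.strand == Strand.SENSE
        assert best.conv_pos == 50
        assert best.cigar == [(CIGAR_M, 30)]
        assert best.score == 30
        # oracle: exhaustive affine-gap local alignment over both strands
        assert best.score == best_bisulfite_score(read, kb_index, ConversionPattern.C2T)

    def test_duplicated_region_on_other_bisulfite_strand(self, rng):
        x = random_sequence(rng, 120)
        ref = GenomeReference(
            {"a": random_sequence(rng, 200) + x + random_sequence(rng, 200),
             "b": random_sequence(rng, 150) + reverse_complement(x) + random_sequence(rng, 150)}
        )
        idx = build_index(ref, 19)
        read = convert_sequence(x[10:90], ConversionPattern.C2T)
        cands = align_read(read, idx, SCORING, ConversionPattern.C2T)
        top = [c for c in cands if c.score == cands[0].score]
        assert len(top) == 2
        assert {c.strand for c in top} == {Strand.SENSE, Strand.ANTISENSE}

    def test_absent_read_has_no_candidates(self, rng):
        ref = GenomeReference({"c": random_sequence(rng, 500)})
        idx = build_index(ref, 19)
        # a 30-mer over a disjoint alphabet pattern cannot align anywhere
        read = "AC" * 15
        cands = align_read(read, idx, SCORING, ConversionPattern.C2T)
        oracle = best_bisulfite_score(read, idx, ConversionPattern.C2T)
        if cands:
            assert cands[0].score == oracle
        else:
            assert oracle < 20  # below min_score: correctly unmapped

    def test_read_with_mismatch_scores_like_oracle(self, kb_genome, kb_index):
        frag = kb_genome.contigs["chr1"][200:280]
        read = convert_sequence(frag, ConversionPattern.C2T)
        read = read[:40] + ("A" if read[40] != "A" else "G") + read[41:]
        cands = align_read(read, kb_index, SCORING, ConversionPattern.C2T)
        assert cands[0].score == best_bisulfite_score(read, kb_index, ConversionPattern.C2T)

    def test_both_pattern_rejected(self, kb_index):
        with pytest.raises(ValueError):
            align_read("A" * 30, kb_index, SCORING, ConversionPattern.BOTH)


class TestScoreMapq:
    def test_unique_hit_is_60(self):
        assert score_mapq(100, None, False, SCORING) == 60

    def test_equal_scores_zero(self):
        assert score_mapq(100, 100, False, SCORING) == 0

    def test_bisulfite_ambiguity_penalized(self):
        same = score_mapq(100, 95, False, SCORING)
        other = score_mapq(100, 95, True, SCORING)
        assert other < same

    def test_monotone_in_second_score(self):
        qs = [score_mapq(100, s, False, SCORING) for s in range(50, 101, 5)]
        assert qs == sorted(qs, reverse=True)

    def test_clamped_range(self):
        for best, second in [(1, None), (100, 0), (5, 5)]:
            assert 0 <= score_mapq(best, second, True, SCORING) <= 60


class TestNormalizeStrand:
    def test_sense_hit_unchanged(self, kb_genome, kb_index):
        read = convert_sequence(kb_genome.contigs["chr1"][100:130], ConversionPattern.C2T)
        cand = align_read(read, kb_index, SCORING, ConversionPattern.C2T)[0]
        norm = normalize_strand(cand, kb_index, read, "I" * 30)
        assert norm.pos == cand.conv_pos == 100
        assert norm.seq == read
        assert not norm.reverse

    def test_antisense_projection_algebra(self, rng):
        ref = GenomeReference({"c": random_sequence(rng, 400)})
        idx = build_index(ref, 19)
        # read sampled from the antisense strand: C2T of revcomp(ref fragment)
        frag = ref.contigs["c"][0:40]  # maps at antisense converted offset 400-40
        read = convert_sequence(reverse_complement(frag), ConversionPattern.C2T)
        cand = align_read(read, idx, SCORING, ConversionPattern.C2T)[0]
        assert cand.strand == Strand.ANTISENSE
        norm = normalize_strand(cand, idx, read, "I" * 40)
        assert norm.pos == 400 - cand.conv_pos - cand.ref_span
        assert norm.pos == 0
        # the stored sequence must match the reference slice under G->A conversion
        ref_slice = ref.contigs["c"][norm.pos : norm.pos + norm.ref_span]
        assert norm.seq == convert_sequence(ref_slice, ConversionPattern.G2A)

    def test_projection_round_trip_many(self, rng):
        ref = GenomeReference({"c": random_sequence(rng, 2000)})
        idx = build_index(ref, 19)
        n_checked = 0
        for _ in range(100):
            start = int(rng.integers(0, 1950))
            length = int(rng.integers(25, 50))
            frag = ref.contigs["c"][start : start + length]
            if rng.random() < 0.5:
                read = convert_sequence(frag, ConversionPattern.C2T)
                want_strand = Strand.SENSE
            else:
                read = convert_sequence(reverse_complement(frag), ConversionPattern.C2T)
                want_strand = Strand.ANTISENSE
            cands = align_read(read, idx, SCORING, ConversionPattern.C2T)
            best = cands[0]
            if best.score < length:  # ambiguous placement by chance
                continue
            norm = normalize_strand(best, idx, read, "I" * length)
            if norm.strand == want_strand:
                assert norm.pos == start
                n_checked += 1
        assert n_checked > 60


class TestCallReadMethylation:
    def _norm(self, ref, seq, pos=0, strand=Strand.SENSE):
        return NormalizedAlignment(
            contig="c", pos=pos, reverse=False, strand=strand,
            pattern=ConversionPattern.C2T, cigar=[(CIGAR_M, len(seq))], seq=seq,
            quals="I" * len(seq), score=len(seq), ref_span=len(seq),
        )

    def test_retained_c_called_cg_methylated(self):
        ref = GenomeReference({"c": "ACGT"})
        res = call_read_methylation(self._norm(ref, "ACGT"), ReferenceContext(ref))
        assert res.calls[1] == "Y"
        assert res.cg_meth == 1 and res.cg_unmeth == 0

    def test_converted_c_called_cg_unmethylated(self):
        ref = GenomeReference({"c": "ACGT"})
        res = call_read_methylation(self._norm(ref, "ATGT"), ReferenceContext(ref))
        assert res.calls[1] == "y"
        assert res.cg_unmeth == 1

    def test_non_bisulfite_mismatch_is_variant(self):
        ref = GenomeReference({"c": "AAGT"})
        res = call_read_methylation(self._norm(ref, "ACGT"), ReferenceContext(ref))
        assert res.calls[1] == "ZC"
        assert res.variants == [(1, "A", "C")]

    def test_antisense_g_votes(self):
        ref = GenomeReference({"c": "ACGT"})
        res = call_read_methylation(
            self._norm(ref, "ACGT", strand=Strand.ANTISENSE), ReferenceContext(ref)
        )
        # G at offset 2 is a CG-context antisense cytosine, retained -> methylated
        assert res.calls[2] == "Y"
        res = call_read_methylation(
            self._norm(ref, "ACAT", strand=Strand.ANTISENSE), ReferenceContext(ref)
        )
        assert res.calls[2] == "y"

    def test_xb_run_length_encoding(self):
        ref = GenomeReference({"c": "TTACGTT"})
        res = call_read_methylation(self._norm(ref, "TTACGTT"), ReferenceContext(ref))
        assert res.xb_string == "3Y3"


class TestAssessReadConversion:
    def _m(self, meth, unmeth):
        r = ReadMethylation()
        r.ch_meth = meth
        r.ch_unmeth = unmeth
        return r

    def test_fully_converted_passes(self):
        assert assess_read_conversion([self._m(0, 10)])

    def test_unconverted_fails(self):
        assert not assess_read_conversion([self._m(10, 0)], max_ch_meth_fraction=0.5)

    def test_below_evidence_floor_passes(self):
        assert assess_read_conversion([self._m(2, 0)], min_ch_sites=3)

    def test_pair_pooled(self):
        assert not assess_read_conversion([self._m(2, 0), self._m(2, 0)], min_ch_sites=3)


@pytest.fixture(scope="module")
def sim_pipeline(tmp_path_factory):
    """Directional error-free simulation aligned end to end (module-shared)."""
    rng = np.random.default_rng(5150)
    ref = GenomeReference(
        {"chrA": random_sequence(rng, 6000), "chrB": random_sequence(rng, 4000)}
    )
    idx = build_index(ref, 19)
    profile = assign_profile(ref, seed=9)
    d = tmp_path_factory.mktemp("simpipe")
    params = SimulationParams(
        depth=6, paired=True, mutation_rate=0.0, error_rate=0.0, seed=13
    )
    simulate_reads(ref, profile, params, d / "r1.fq", d / "r2.fq", d / "truth.tsv")
    align_fastq(idx, d / "r1.fq", d / "r2.fq", d / "out.bam")
    sort_and_index(d / "out.bam", d / "out.s.bam")
    return ref, idx, d


class TestEndToEnd:
    def test_simulation_recovery(self, sim_pipeline):
        _ref, _idx, d = sim_pipeline
        ev = evaluate_alignments(d / "out.s.bam")
        assert ev.mappability >= 0.99
        assert ev.on_target >= 0.99

    def test_methylation_call_soundness_audit(self, sim_pipeline):
        """Re-reading the reference at every called column reproduces the call."""
        ref, _idx, d = sim_pipeline
        n_audited = 0
        with pysam.AlignmentFile(str(d / "out.s.bam")) as bam:
            for read in bam:
                if read.is_unmapped:
                    continue
                strand = read.get_tag("YS")
                seq = read.query_sequence
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    rb = ref.contigs[read.reference_name][rpos]
                    qb = seq[qpos]
                    if strand == "W" and rb == "C":
                        assert qb in "CT"  # error-free sim: only meth states
                        n_audited += 1
                    elif strand == "C" and rb == "G":
                        assert qb in "GA"
                        n_audited += 1
        assert n_audited > 1000

    def test_pattern_assessment_consistency(self, sim_pipeline, tmp_path):
        """All-unmethylated undirectional reads: assessed pattern == simulated."""
        ref, _idx, d2 = sim_pipeline
        profile = assign_profile(
            ref, cg_sampler=lambda r, s: np.zeros(s), ch_sampler=lambda r, s: np.zeros(s),
            seed=1,
        )
        params = SimulationParams(
            depth=3, paired=False, undirectional=True, mutation_rate=0.0,
            error_rate=0.005, seed=99,
        )
        simulate_reads(ref, profile, params, tmp_path / "u.fq", None, tmp_path / "t.tsv")
        from methylbolt.simulate import parse_truth_comment

        n = bad = 0
        with pysam.FastxFile(str(tmp_path / "u.fq")) as fh:
            for e in fh:
                seq = e.sequence
                if seq.count("C") + seq.count("G") < 10:
                    continue
                truth = parse_truth_comment(e.comment)
                n += 1
                if assess_conversion_pattern(seq) != truth["pattern"]:
                    bad += 1
        assert n > 100
        assert bad / n < 0.01


class TestWriteAlignments:
    def test_round_trip_and_mate_fields(self, sim_pipeline):
        _ref, idx, d = sim_pipeline
        with pysam.AlignmentFile(str(d / "out.s.bam")) as bam:
            reads = list(bam)
        assert reads
        by_name = {}
        for r in reads:
            if r.is_secondary or r.is_supplementary:
                continue
            by_name.setdefault(r.query_name, []).append(r)
        n_pairs = 0
        for name, pair in by_name.items():
            assert len(pair) == 2
            r1, r2 = sorted(pair, key=lambda r: r.is_read2)
            if r1.is_unmapped or r2.is_unmapped:
                continue
            assert r1.next_reference_start == r2.reference_start
            assert r2.next_reference_start == r1.reference_start
            assert r1.template_length == -r2.template_length
            for r in (r1, r2):
                for tag in ("AS", "YS", "YC", "XB", "XF"):
                    assert r.has_tag(tag)
                assert 0 <= r.mapping_quality <= 60
            n_pairs += 1
        assert n_pairs > 50

    def test_unmapped_read_retained(self, kb_index, tmp_path):
        aligner = BisulfiteAligner(kb_index)
        recs = aligner.align_single("noalign", "AC" * 25, "I" * 50, None)
        assert recs[0]["flag"] & 0x4
        header = make_header(kb_index)
        out = tmp_path / "u.sam"
        write_alignments(recs, header, out, "SAM")
        with pysam.AlignmentFile(str(out)) as fh:
            back = list(fh)
        assert len(back) == 1
        assert back[0].is_unmapped
        assert back[0].query_sequence == "AC" * 25
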