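from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from methylbolt.reference import GenomeReference


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    lut = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return lut[rng.integers(0, len(lut), length)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_ref(rng) -> GenomeReference:
    """Two-contig random toy genome, 3 kb total."""
    return GenomeReference(
        {"chr1": random_sequence(rng, 2000), "chr2": random_sequence(rng, 1000)}
    )


@pytest.fixture
def make_bam(tmp_path):
    """Build a sorted, indexed toy BAM from simple read dicts."""
    import pysam

    def _make(ref: GenomeReference, reads: list[dict], name="toy"):
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": c, "LN": n} for c, n in ref.lengths.items()],
            }
        )
        unsorted = tmp_path / f"{name}.unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as fh:
            for i, r in enumerate(reads):
                seg = pysam.AlignedSegment(header)
                seg.query_name = r.get("name", f"r{i}")
                seg.flag = r.get("flag", 0)
                seg.reference_id = header.get_tid(r.get("contig", next(iter(ref.contigs))))
                seg.reference_start = r["pos"]
                seg.mapping_quality = r.get("mapq", 60)
                seq = r["seq"]
                seg.cigartuples = r.get("cigar", [(0, len(seq))])
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(
                    r.get("quals", "I" * len(seq))
                )
                if "mate_pos" in r:
                    seg.next_reference_id = seg.reference_id
                    seg.next_reference_start = r["mate_pos"]
                tags = [("YS", r.get("ys", "W"))]
                tags += r.get("tags", [])
                seg.set_tags(tags)
                fh.write(seg)
        out = tmp_path / f"{name}.bam"
        pysam.sort("-o", str(out), str(unsorted))
        pysam.index(str(out))
        return out

    return _make


@pytest.fixture
def write_fasta(tmp_path):
    def _write(ref_or_text, name="ref.fa"):
        path = tmp_path / name
        if isinstance(ref_or_text, GenomeReference):
            ref_or_text.write_fasta(path)
        else:
            path.write_text(ref_or_text)
        return path

    return _write
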