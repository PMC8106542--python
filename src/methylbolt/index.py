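"""Dual-strand bisulfite index: C->T conversions of both reference strands
under one exact-substring seed structure (suffix array).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .reference import (
    ConversionPattern,
    GenomeReference,
    Strand,
    convert_sequence,
    load_reference,
    reverse_complement,
)

INDEX_VERSION = 1


def build_suffix_array(text: bytes) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    codes = np.frombuffer(text, dtype=np.uint8).astype(np.int64)
    n = len(codes)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = codes
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.ones(n, dtype=np.int64)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


@dataclass(frozen=True)
class IndexHit:
    contig: str
    offset: int  # 0-based offset on the indexed converted sequence
    strand: Strand


class BisulfiteIndex:
    """Searchable structure over C->T conversions of sense and antisense strands.

    The two converted sequence sets are concatenated with '#' sentinels; a
    suffix array over the concatenation provides exact-substring seed lookup,
    and segment bookkeeping maps global hits back to (contig, offset, strand).
    """

    def __init__(
        self,
        ref: GenomeReference,
        seed_min_length: int = 19,
        _precomputed: dict | None = None,
    ):
        if ref.total_length == 0:
            raise ValueError("cannot index an empty reference")
        if ref.total_length < seed_min_length:
            raise ValueError(
                f"total reference length {ref.total_length} < seed_min_length {seed_min_length}"
            )
        self.seed_min_length = seed_min_length
        self.contig_names = list(ref.contigs)
        self.lengths = dict(ref.lengths)
        self.reference_digest = ref.digest()

        self.sense_converted: dict[str, str] = {}
        self.antisense_converted: dict[str, str] = {}
        for name, seq in ref.contigs.items():
            self.sense_converted[name] = convert_sequence(seq, ConversionPattern.C2T)
            self.antisense_converted[name] = convert_sequence(
                reverse_complement(seq), ConversionPattern.C2T
            )

        # segment layout: for each contig, sense segment then antisense segment
        self._segments: list[tuple[str, Strand]] = []
        self._seg_starts: list[int] = []
        parts: list[str] = []
        pos = 0
        for name in self.contig_names:
            for strand, seq in (
                (Strand.SENSE, self.sense_converted[name]),
                (Strand.ANTISENSE, self.antisense_converted[name]),
            ):
                self._segments.append((name, strand))
                self._seg_starts.append(pos)
                parts.append(seq)
                parts.append("#")
                pos += len(seq) + 1
        self.text = "".join(parts).encode("ascii")
        self._seg_starts_arr = np.asarray(self._seg_starts, dtype=np.int64)

        if _precomputed is not None:
            self.suffix_array = _precomputed["suffix_array"]
        else:
            self.suffix_array = build_suffix_array(self.text)

    # ---- coordinate map ----------------------------------------------------

    def resolve(self, global_offset: int) -> IndexHit:
        """Map a global text offset to (contig, converted-space offset, strand)."""
        import bisect

        i = bisect.bisect_right(self._seg_starts, global_offset) - 1
        contig, strand = self._segments[i]
        off = global_offset - self._seg_starts[i]
        if off >= self.lengths[contig]:
            raise ValueError(f"offset {global_offset} falls on a sentinel")
        return IndexHit(contig, off, strand)

    def global_offset(self, contig: str, offset: int, strand: Strand) -> int:
        """Inverse of :meth:`resolve`."""
        i = self.contig_names.index(contig) * 2 + (0 if strand == Strand.SENSE else 1)
        if not 0 <= offset < self.lengths[contig]:
            raise ValueError(f"offset {offset} out of range for {contig}")
        return self._seg_starts[i] + offset

    def converted_sequence(self, contig: str, strand: Strand) -> str:
        if strand == Strand.SENSE:
            return self.sense_converted[contig]
        return self.antisense_converted[contig]

    def converted_array(self, contig: str, strand: Strand) -> np.ndarray:
        """uint8 view of a converted sequence (cached; used by alignment filters)."""
        if not hasattr(self, "_conv_arrays"):
            self._conv_arrays = {}
        key = (contig, strand)
        if key not in self._conv_arrays:
            self._conv_arrays[key] = np.frombuffer(
                self.converted_sequence(contig, strand).encode("ascii"), dtype=np.uint8
            )
        return self._conv_arrays[key]

    # ---- search ------------------------------------------------------------

    def search(
        self, query: str, max_hits: int | None = None, allow_short: bool = False
    ) -> list[IndexHit]:
        """All exact occurrences of ``query`` across both converted strands."""
        if len(query) < self.seed_min_length and not allow_short:
            raise ValueError(
                f"query length {len(query)} < seed_min_length {self.seed_min_length}"
            )
        if not query:
            raise ValueError("empty query")
        q = query.encode("ascii")
        sa, text = self.suffix_array, self.text
        m = len(q)

        lo, hi = 0, len(sa)
        while lo < hi:
            mid = (lo + hi) // 2
            if text[sa[mid] : sa[mid] + m] < q:
                lo = mid + 1
            else:
                hi = mid
        first = lo
        hi = len(sa)
        while lo < hi:
            mid = (lo + hi) // 2
            if text[sa[mid] : sa[mid] + m] <= q:
                lo = mid + 1
            else:
                hi = mid
        out = []
        positions = sa[first:lo]
        if max_hits is not None and len(positions) > max_hits:
            return []
        for p in positions:
            out.append(self.resolve(int(p)))
        return out

    # ---- persistence -------------------------------------------------------

    def save(self, index_dir: str | Path) -> None:
        index_dir = Path(index_dir)
        index_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "version": INDEX_VERSION,
            "seed_min_length": self.seed_min_length,
            "contigs": self.contig_names,
            "lengths": self.lengths,
            "reference_digest": self.reference_digest,
        }
        (index_dir / "meta.json").write_text(json.dumps(meta, indent=1))
        with open(index_dir / "reference.fa", "w") as fh:
            for name in self.contig_names:
                fh.write(f">{name}\n{self._reference_seq(name)}\n")
        np.save(index_dir / "suffix_array.npy", self.suffix_array)

    def reference(self) -> GenomeReference:
        """Reconstruct the unconverted sense reference bound to this index."""
        if not hasattr(self, "_reference_cache"):
            self._reference_cache = GenomeReference(
                {name: self._reference_seq(name) for name in self.contig_names}
            )
        return self._reference_cache

    def _reference_seq(self, name: str) -> str:
        # reconstruct the unconverted sense sequence: T in sense_converted that is
        # A in the reverse of antisense_converted was a C; similarly for G
        sense = self.sense_converted[name]
        anti_rc = reverse_complement(self.antisense_converted[name])
        out = []
        for a, b in zip(sense, anti_rc):
            if a == "T" and b == "C":
                out.append("C")
            else:
                out.append(a)
        return "".join(out)

    @classmethod
    def load(cls, index_dir: str | Path) -> "BisulfiteIndex":
        index_dir = Path(index_dir)
        meta = json.loads((index_dir / "meta.json").read_text())
        if meta["version"] != INDEX_VERSION:
            raise ValueError(f"unsupported index version {meta['version']}")
        ref = load_reference(index_dir / "reference.fa")
        sa = np.load(index_dir / "suffix_array.npy")
        idx = cls(ref, meta["seed_min_length"], _precomputed={"suffix_array": sa})
        if idx.reference_digest != meta["reference_digest"]:
            raise ValueError("index digest mismatch: corrupt index directory")
        return idx


def build_index(ref: GenomeReference, seed_min_length: int = 19) -> BisulfiteIndex:
    """Build the dual-strand bisulfite index for a reference."""
    return BisulfiteIndex(ref, seed_min_length)
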