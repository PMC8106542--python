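"""Reference genome loading, in-silico bisulfite conversion and methylation context.

All internal coordinates are 0-based half-open; 1-based coordinates appear
only at SAM/CGmap serialization boundaries.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes beyond N (upper-case); lower-case input is upper-cased first
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric base codes used by vectorized helpers
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_TABLE[ord(_b)] = _c


class ConversionPattern(str, Enum):
    """Bisulfite read conversion pattern."""

    C2T = "C2T"
    G2A = "G2A"
    BOTH = "BOTH"


class Strand(str, Enum):
    """Bisulfite reference strand (Watson/Crick)."""

    SENSE = "sense"
    ANTISENSE = "antisense"


# context codes: 0 = not a methylatable site, 4 = site with undefined context
CTX_NONE, CTX_CG, CTX_CHG, CTX_CHH, CTX_UNKNOWN = 0, 1, 2, 3, 4
CONTEXT_NAMES = {CTX_CG: "CG", CTX_CHG: "CHG", CTX_CHH: "CHH", CTX_UNKNOWN: "unknown"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def convert_sequence(seq: str, pattern: ConversionPattern) -> str:
    """In-silico bisulfite conversion: C2T replaces C with T, G2A replaces G with A."""
    if pattern == ConversionPattern.C2T:
        return seq.replace("C", "T")
    if pattern == ConversionPattern.G2A:
        return seq.replace("G", "A")
    raise ValueError("convert_sequence requires a concrete pattern (C2T or G2A), not BOTH")


def encode_bases(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class GenomeReference:
    """Named contigs of upper-case A/C/G/T/N with a length map."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains invalid bases: {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def digest(self) -> str:
        h = hashlib.md5()
        for name, seq in self.contigs.items():
            h.update(name.encode())
            h.update(b"\x00")
            h.update(seq.encode())
            h.update(b"\x00")
        return h.hexdigest()

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_reference(fasta_path: str | Path, strict: bool = False) -> GenomeReference:
    """Load and normalize a FASTA reference.

    Lower-case input is upper-cased.  IUPAC ambiguity codes other than N are
    replaced by N with a warning, or rejected when ``strict`` is set.
    """
    contigs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    n_ambiguous = 0

    def _flush():
        nonlocal n_ambiguous
        if name is None:
            return
        seq = "".join(parts).upper()
        cleaned = []
        for ch in seq:
            if ch in VALID_BASES:
                cleaned.append(ch)
            elif ch in _IUPAC_AMBIGUOUS:
                if strict:
                    raise ValueError(
                        f"contig {name!r} contains IUPAC ambiguity code {ch!r} (strict mode)"
                    )
                n_ambiguous += 1
                cleaned.append("N")
            else:
                raise ValueError(f"contig {name!r} contains invalid character {ch!r}")
        if name in contigs:
            raise ValueError(f"duplicate contig name {name!r}")
        contigs[name] = "".join(cleaned)

    with _open_text(fasta_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError(f"empty contig name at line {lineno}")
                parts = []
            else:
                if name is None:
                    raise ValueError(
                        f"malformed FASTA: sequence before first header at line {lineno}"
                    )
                parts.append(line)
        _flush()

    if not contigs:
        raise ValueError(f"empty FASTA: {fasta_path}")
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} IUPAC ambiguity bases replaced by N while loading {fasta_path}"
        )
    return GenomeReference(contigs)


@dataclass(frozen=True)
class MethylationContext:
    cytosine_strand: Strand
    context_class: str  # CG | CHG | CHH | unknown
    dinucleotide: str  # 2-mer downstream of the cytosine on its strand


def methylation_context(
    ref: GenomeReference, contig: str, position: int, cytosine_strand: Strand
) -> MethylationContext:
    """Context of a cytosine from the 2 bases downstream on its own strand.

    next base G -> CG; next base H then G -> CHG; both H -> CHH.
    Fewer than 2 in-bounds downstream bases, or a downstream N, yields
    context_class "unknown" (excluded from CG-only outputs).
    """
    seq = ref.contigs[contig]
    base = seq[position]
    if cytosine_strand == Strand.SENSE:
        if base != "C":
            raise ValueError(f"{contig}:{position} is {base}, not a sense-strand C")
        down = seq[position + 1 : position + 3]
    else:
        if base != "G":
            raise ValueError(f"{contig}:{position} is {base}, not an antisense-strand C (ref G)")
        down = reverse_complement(seq[max(0, position - 2) : position])
    dinuc = (down + "NN")[:2]
    # CG needs only the first downstream base; CHG/CHH need both
    if down[:1] == "G":
        cls = "CG"
    elif len(down) < 2 or "N" in down[:2]:
        cls = "unknown"
    elif down[1] == "G":
        cls = "CHG"
    else:
        cls = "CHH"
    return MethylationContext(cytosine_strand, cls, dinuc)


def context_code_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-position context codes for one contig.

    Returns (sense_ctx, antisense_ctx): int8 arrays of length len(seq).
    sense_ctx[i] is nonzero iff seq[i] == 'C'; antisense_ctx[i] nonzero iff
    seq[i] == 'G'.  Codes: 1 CG, 2 CHG, 3 CHH, 4 unknown context.
    """
    codes = encode_bases(seq)
    n = len(codes)
    sense = np.zeros(n, dtype=np.int8)
    anti = np.zeros(n, dtype=np.int8)

    is_c = codes == 1
    is_g = codes == 2
    is_h = (codes == 0) | (codes == 1) | (codes == 3)  # A, C or T

    # sense strand: downstream = i+1, i+2
    d1 = np.full(n, 4, dtype=np.uint8)
    d2 = np.full(n, 4, dtype=np.uint8)
    d1[: n - 1] = codes[1:]
    d2[: n - 2] = codes[2:]
    sense[is_c & (d1 == 2)] = CTX_CG
    sense[is_c & _h(d1) & (d2 == 2)] = CTX_CHG
    sense[is_c & _h(d1) & _h(d2)] = CTX_CHH
    sense[is_c & (sense == 0)] = CTX_UNKNOWN

    # antisense strand: downstream on antisense = complement of i-1, i-2
    u1 = np.full(n, 4, dtype=np.uint8)
    u2 = np.full(n, 4, dtype=np.uint8)
    u1[1:] = _comp_codes(codes[:-1])
    u2[2:] = _comp_codes(codes[:-2])
    anti[is_g & (u1 == 2)] = CTX_CG
    anti[is_g & _h(u1) & (u2 == 2)] = CTX_CHG
    anti[is_g & _h(u1) & _h(u2)] = CTX_CHH
    anti[is_g & (anti == 0)] = CTX_UNKNOWN
    return sense, anti


def _h(codes: np.ndarray) -> np.ndarray:
    return (codes == 0) | (codes == 1) | (codes == 3)


def _comp_codes(codes: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[codes]
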