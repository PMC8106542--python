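"""Methylation-aware bisulfite read simulation (WGSIM-style).

Reads are sampled from a haplotype copy of the reference carrying random
variation, bisulfite-converted according to per-site methylation states drawn
from a methylation profile, and written as FASTQ with a lossless truth
comment.  Realized per-site methylated/total counts are emitted as a sorted
TSV (the acceptance oracle for downstream calling).

Truth comment grammar (one token, FASTQ comment field):

    contig:start:end:strand:pattern:methstring

with ``start``/``end`` the 0-based half-open reference interval the read was
sampled from, ``strand`` the origin bisulfite strand (W sense / C antisense),
``pattern`` the read conversion pattern (C2T/G2A) and ``methstring`` a
read-position-aligned string over {M, U, .}.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import (
    CTX_UNKNOWN,
    CONTEXT_NAMES,
    ConversionPattern,
    GenomeReference,
    Strand,
    context_code_arrays,
    encode_bases,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# --------------------------------------------------------------------------
# methylation profile
# --------------------------------------------------------------------------


def uniform_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size)


def low_level_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    """Default CH profile: mostly-unmethylated Beta(1, 19) draws (mean 0.05)."""
    return rng.beta(1.0, 19.0, size)


@dataclass
class MethylationProfile:
    """Per-site methylation levels over every methylatable reference site.

    A site is methylatable when it is a sense-strand C or antisense-strand G
    whose context is defined (two in-bounds, non-N downstream bases on the
    cytosine strand; CG needs only one).  Levels are stored as full-length
    per-contig arrays with NaN at non-sites.
    """

    levels_sense: dict[str, np.ndarray]
    levels_anti: dict[str, np.ndarray]
    provenance: str = "random_by_context"

    def level(self, contig: str, position: int, strand: Strand) -> float:
        arr = self.levels_sense if strand == Strand.SENSE else self.levels_anti
        v = float(arr[contig][position])
        if math.isnan(v):
            raise KeyError(f"{contig}:{position}:{strand.value} is not a methylatable site")
        return v

    def has_site(self, contig: str, position: int, strand: Strand) -> bool:
        arr = self.levels_sense if strand == Strand.SENSE else self.levels_anti
        return bool(np.isfinite(arr[contig][position]))

    @property
    def n_sites(self) -> int:
        return int(
            sum(np.isfinite(a).sum() for a in self.levels_sense.values())
            + sum(np.isfinite(a).sum() for a in self.levels_anti.values())
        )

    def sites(self):
        """Yield (contig, position, strand, level) in reference order."""
        for contig in self.levels_sense:
            s = self.levels_sense[contig]
            a = self.levels_anti[contig]
            for pos in np.nonzero(np.isfinite(s) | np.isfinite(a))[0]:
                if np.isfinite(s[pos]):
                    yield contig, int(pos), Strand.SENSE, float(s[pos])
                if np.isfinite(a[pos]):
                    yield contig, int(pos), Strand.ANTISENSE, float(a[pos])


def assign_profile(
    ref: GenomeReference,
    cg_sampler=uniform_sampler,
    ch_sampler=low_level_sampler,
    cgmap_path: str | Path | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MethylationProfile:
    """Draw a methylation level for every methylatable site; CGmap entries override."""
    if rng is None:
        rng = np.random.default_rng(seed)
    levels_sense: dict[str, np.ndarray] = {}
    levels_anti: dict[str, np.ndarray] = {}
    for contig, seq in ref.contigs.items():
        sense_ctx, anti_ctx = context_code_arrays(seq)
        for ctx, store in ((sense_ctx, levels_sense), (anti_ctx, levels_anti)):
            arr = np.full(len(seq), np.nan)
            cg = (ctx == 1) & (ctx != CTX_UNKNOWN)
            ch = (ctx == 2) | (ctx == 3)
            arr[cg] = cg_sampler(rng, int(cg.sum()))
            arr[ch] = ch_sampler(rng, int(ch.sum()))
            store[contig] = arr
    provenance = "random_by_context"
    if cgmap_path is not None:
        from .call import read_cgmap

        n_skipped = 0
        for rec in read_cgmap(cgmap_path):
            strand = Strand.SENSE if rec.ref_nucleotide == "C" else Strand.ANTISENSE
            arr = levels_sense if strand == Strand.SENSE else levels_anti
            pos = rec.position_1based - 1
            if rec.contig not in arr or not (0 <= pos < len(arr[rec.contig])) or not np.isfinite(
                arr[rec.contig][pos]
            ):
                n_skipped += 1
                continue
            arr[rec.contig][pos] = rec.methylation_level
        if n_skipped:
            warnings.warn(f"{n_skipped} CGmap sites absent from reference were skipped")
        provenance = "from_cgmap"
    return MethylationProfile(levels_sense, levels_anti, provenance)


# --------------------------------------------------------------------------
# simulation parameters
# --------------------------------------------------------------------------


@dataclass
class SimulationParams:
    read_length: int = 100
    mean_insert: int = 400
    insert_sd: int = 30
    depth: float | None = 20.0
    read_count: int | None = None
    mutation_rate: float = 0.005
    indel_fraction: float = 0.15
    error_rate: float = 0.005
    paired: bool = True
    undirectional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "indel_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.paired and self.mean_insert < self.read_length:
            raise ValueError("mean_insert must be >= read_length for paired simulation")
        if (self.depth is None) == (self.read_count is None):
            raise ValueError("exactly one of depth / read_count must be set")

    def n_fragments(self, total_ref_length: int) -> int:
        per_frag = self.read_length * (2 if self.paired else 1)
        if self.read_count is not None:
            n_reads = self.read_count
            return (n_reads + (2 if self.paired else 1) - 1) // (2 if self.paired else 1)
        return math.ceil(self.depth * total_ref_length / per_frag)

    @property
    def quality_char(self) -> str:
        if self.error_rate <= 0:
            q = 40
        else:
            q = min(40, max(2, round(-10 * math.log10(self.error_rate))))
        return chr(33 + q)


# --------------------------------------------------------------------------
# haplotype variation
# --------------------------------------------------------------------------


def mutate_haplotype(
    seq: str, rng: np.random.Generator, mutation_rate: float, indel_fraction: float
) -> tuple[str, np.ndarray, np.ndarray]:
    """Apply random variation to one contig once per simulation run.

    Returns (mutant_seq, ref_coord, inserted) where ref_coord maps each mutant
    base to a reference coordinate (monotone non-decreasing) and inserted
    marks bases with no reference counterpart.
    """
    n = len(seq)
    if mutation_rate <= 0:
        return seq, np.arange(n, dtype=np.int64), np.zeros(n, dtype=bool)
    mut_pos = np.nonzero(rng.random(n) < mutation_rate)[0]
    is_indel = rng.random(len(mut_pos)) < indel_fraction
    is_del = rng.random(len(mut_pos)) < 0.5
    sub_bases = rng.integers(0, 3, len(mut_pos))
    ins_bases = rng.integers(0, 4, len(mut_pos))

    codes = encode_bases(seq)
    chunks: list[str] = []
    coords: list[np.ndarray] = []
    inserted: list[np.ndarray] = []
    prev = 0
    for j, p in enumerate(mut_pos):
        p = int(p)
        if p > prev:
            chunks.append(seq[prev:p])
            coords.append(np.arange(prev, p, dtype=np.int64))
            inserted.append(np.zeros(p - prev, dtype=bool))
        if is_indel[j]:
            if is_del[j]:
                pass  # reference base dropped
            else:
                ins = chr(_BASES[ins_bases[j]])
                chunks.append(seq[p] + ins)
                coords.append(np.array([p, p], dtype=np.int64))
                inserted.append(np.array([False, True]))
        else:
            old = codes[p]
            new = sub_bases[j]
            if old <= 3 and new >= old:
                new += 1  # substitution to one of the 3 other bases
            chunks.append(chr(_BASES[new % 4]))
            coords.append(np.array([p], dtype=np.int64))
            inserted.append(np.zeros(1, dtype=bool))
        prev = p + 1
    if prev < n:
        chunks.append(seq[prev:])
        coords.append(np.arange(prev, n, dtype=np.int64))
        inserted.append(np.zeros(n - prev, dtype=bool))
    return (
        "".join(chunks),
        np.concatenate(coords) if coords else np.empty(0, dtype=np.int64),
        np.concatenate(inserted) if inserted else np.empty(0, dtype=bool),
    )


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------


@dataclass
class _MutantContig:
    name: str
    seq: str
    ref_coord: np.ndarray
    lev_sense: np.ndarray  # level of each mutant base that is a surviving sense-C site
    lev_anti: np.ndarray  # ... antisense-G site
    codes: np.ndarray = field(default=None)


def _prepare_mutants(
    ref: GenomeReference, profile: MethylationProfile, params: SimulationParams,
    rng: np.random.Generator,
) -> list[_MutantContig]:
    out = []
    for name, seq in ref.contigs.items():
        mut, coord, ins = mutate_haplotype(seq, rng, params.mutation_rate, params.indel_fraction)
        codes = encode_bases(mut)
        ref_codes = encode_bases(seq)
        surv = (~ins) & (ref_codes[coord] == codes)
        lev_s = np.full(len(mut), np.nan)
        lev_a = np.full(len(mut), np.nan)
        m = surv & (codes == 1)
        lev_s[m] = profile.levels_sense[name][coord[m]]
        m = surv & (codes == 2)
        lev_a[m] = profile.levels_anti[name][coord[m]]
        out.append(_MutantContig(name, mut, coord, lev_s, lev_a, codes))
    return out


def _open_out(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _apply_errors(read: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return read
    mask = np.nonzero(rng.random(len(read)) < error_rate)[0]
    if len(mask) == 0:
        return read
    chars = list(read)
    offs = rng.integers(1, 4, len(mask))
    lut = "ACGT"
    for p, o in zip(mask, offs):
        b = chars[p]
        i = lut.find(b)
        chars[p] = lut[(i + int(o)) % 4] if i >= 0 else b
    return "".join(chars)


def simulate_reads(
    ref: GenomeReference,
    profile: MethylationProfile,
    params: SimulationParams,
    out_fastq1: str | Path,
    out_fastq2: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> dict:
    """Simulate bisulfite reads; write FASTQ(s) with truth comments and a truth TSV.

    Returns a summary dict with ``reads_emitted`` and ``sites_touched``.
    """
    if params.paired and out_fastq2 is None:
        raise ValueError("paired simulation requires out_fastq2")
    rng = np.random.default_rng(params.seed)
    mutants = _prepare_mutants(ref, profile, params, rng)
    weights = np.array([len(m.seq) for m in mutants], dtype=float)
    weights /= weights.sum()
    n_frags = params.n_fragments(ref.total_length)
    rl = params.read_length
    qual = params.quality_char * rl

    truth: dict[tuple[str, int, str], list[int]] = {}
    fq1 = _open_out(out_fastq1)
    fq2 = _open_out(out_fastq2) if params.paired else None
    try:
        for i in range(n_frags):
            for _attempt in range(50):
                ci = int(rng.choice(len(mutants), p=weights))
                mc = mutants[ci]
                if params.paired:
                    insert = int(round(rng.normal(params.mean_insert, params.insert_sd)))
                    insert = max(insert, rl)
                else:
                    insert = rl
                if len(mc.seq) >= insert:
                    break
            else:
                raise RuntimeError("could not place fragment: contigs shorter than insert size")
            start = int(rng.integers(0, len(mc.seq) - insert + 1))
            end = start + insert
            origin = Strand.SENSE if rng.random() < 0.5 else Strand.ANTISENSE

            if origin == Strand.SENSE:
                tmpl = mc.seq[start:end]
                levels = mc.lev_sense[start:end]
                refpos = mc.ref_coord[start:end]
            else:
                tmpl = reverse_complement(mc.seq[start:end])
                levels = mc.lev_anti[start:end][::-1]
                refpos = mc.ref_coord[start:end][::-1]

            site_mask = np.isfinite(levels)
            states = np.zeros(insert, dtype=bool)
            idx = np.nonzero(site_mask)[0]
            if len(idx):
                states[idx] = rng.random(len(idx)) < levels[idx]

            conv = np.frombuffer(tmpl.encode("ascii"), dtype=np.uint8).copy()
            c_mask = conv == ord("C")
            conv[c_mask & ~states] = ord("T")
            conv_tmpl = conv.tobytes().decode("ascii")

            flip = params.undirectional and rng.random() < 0.5
            strand_label = "W" if origin == Strand.SENSE else "C"

            def read_record(tmpl_lo, tmpl_hi, rc, pattern):
                if rc:
                    seq = reverse_complement(conv_tmpl[tmpl_lo:tmpl_hi])
                else:
                    seq = conv_tmpl[tmpl_lo:tmpl_hi]
                seq = _apply_errors(seq, rng, params.error_rate)
                rp = refpos[tmpl_lo:tmpl_hi]
                lo, hi = int(rp.min()), int(rp.max()) + 1
                # truth reflects the bases actually emitted: a sequencing error
                # that corrupts the informative base removes the site from this
                # read's truth, a C<->T (G<->A) error is recorded as flipped
                meth_base, unmeth_base = ("G", "A") if rc else ("C", "T")
                calls = []
                rng_t = range(tmpl_hi - 1, tmpl_lo - 1, -1) if rc else range(tmpl_lo, tmpl_hi)
                for j, t in enumerate(rng_t):
                    if not site_mask[t]:
                        calls.append(".")
                        continue
                    b = seq[j]
                    if b == meth_base:
                        observed = True
                    elif b == unmeth_base:
                        observed = False
                    else:
                        calls.append(".")
                        continue
                    calls.append("M" if observed else "U")
                    key = (mc.name, int(refpos[t]), strand_label)
                    rec = truth.get(key)
                    if rec is None:
                        rec = truth[key] = [0, 0]
                    rec[1] += 1
                    if observed:
                        rec[0] += 1
                comment = f"{mc.name}:{lo}:{hi}:{strand_label}:{pattern}:{''.join(calls)}"
                return seq, comment

            name = f"sim_{i}"
            if params.paired:
                if not flip:
                    s1, c1 = read_record(0, rl, False, "C2T")
                    s2, c2 = read_record(insert - rl, insert, True, "G2A")
                else:
                    s1, c1 = read_record(insert - rl, insert, True, "G2A")
                    s2, c2 = read_record(0, rl, False, "C2T")
                fq1.write(f"@{name} {c1}\n{s1}\n+\n{qual}\n")
                fq2.write(f"@{name} {c2}\n{s2}\n+\n{qual}\n")
            else:
                if not flip:
                    s1, c1 = read_record(0, rl, False, "C2T")
                else:
                    s1, c1 = read_record(0, rl, True, "G2A")
                fq1.write(f"@{name} {c1}\n{s1}\n+\n{qual}\n")
    finally:
        fq1.close()
        if fq2 is not None:
            fq2.close()

    if out_truth is not None:
        write_truth_counts(truth, ref, out_truth)
    reads = n_frags * (2 if params.paired else 1)
    return {"reads_emitted": reads, "sites_touched": len(truth)}


# --------------------------------------------------------------------------
# truth counts serialization
# --------------------------------------------------------------------------

TRUTH_HEADER = ["contig", "pos0", "strand", "context", "meth_count", "total_count"]


def write_truth_counts(
    truth: dict[tuple[str, int, str], list[int]], ref: GenomeReference, path: str | Path
) -> None:
    ctx_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order = {name: i for i, name in enumerate(ref.contigs)}
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_HEADER) + "\n")
        for (contig, pos, strand) in sorted(
            truth, key=lambda k: (order[k[0]], k[1], k[2])
        ):
            if contig not in ctx_cache:
                ctx_cache[contig] = context_code_arrays(ref.contigs[contig])
            sense_ctx, anti_ctx = ctx_cache[contig]
            code = int(sense_ctx[pos] if strand == "W" else anti_ctx[pos])
            meth, total = truth[(contig, pos, strand)]
            fh.write(
                f"{contig}\t{pos}\t{strand}\t{CONTEXT_NAMES.get(code, 'unknown')}\t{meth}\t{total}\n"
            )


def read_truth_counts(path: str | Path) -> dict[tuple[str, int, str], tuple[str, int, int]]:
    """Parse a truth TSV into {(contig, pos0, strand): (context, meth, total)}."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_HEADER:
            raise ValueError(f"unexpected truth header in {path}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            out[(f[0], int(f[1]), f[2])] = (f[3], int(f[4]), int(f[5]))
    return out


def parse_truth_comment(comment: str) -> dict:
    """Parse the simulator's truth comment into a dict."""
    parts = comment.split(":")
    if len(parts) != 6:
        raise ValueError(f"unparseable truth comment: {comment!r}")
    contig, start, end, strand, pattern, meth = parts
    if strand not in ("W", "C") or pattern not in ("C2T", "G2A"):
        raise ValueError(f"unparseable truth comment: {comment!r}")
    return {
        "contig": contig,
        "start": int(start),
        "end": int(end),
        "strand": Strand.SENSE if strand == "W" else Strand.ANTISENSE,
        "pattern": ConversionPattern(pattern),
        "methstring": meth,
    }


# --------------------------------------------------------------------------
# tiled simulation reference
# --------------------------------------------------------------------------


def build_simulation_reference(
    ref: GenomeReference,
    per_contig_target: int,
    tile_length: int = 50,
    max_ambiguous: int = 10,
    duplicate_head: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenomeReference:
    """Concatenate randomly sampled tiles per contig; optionally duplicate the
    head of the first output contig as an extra contig."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for name, seq in ref.contigs.items():
        if len(seq) < tile_length:
            raise ValueError(f"contig {name!r} shorter than tile_length {tile_length}")
        tiles: list[str] = []
        total = 0
        rejects = 0
        while total < per_contig_target:
            start = int(rng.integers(0, len(seq) - tile_length + 1))
            tile = seq[start : start + tile_length]
            if tile.count("N") >= max_ambiguous:
                rejects += 1
                if rejects > 10000:
                    raise ValueError(f"no acceptable tile found in contig {name!r}")
                continue
            tiles.append(tile)
            total += tile_length
        out[name] = "".join(tiles)
    if duplicate_head > 0:
        first = next(iter(out))
        out[f"{first}_dup"] = out[first][:duplicate_head]
    return GenomeReference(out)
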