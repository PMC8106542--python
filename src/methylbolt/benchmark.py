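"""Desk-scale end-to-end benchmark: tiled reference, simulated library grid,
alignment, CpG calling and truth-based metrics.

The default grid mirrors the simulated-library parameter table at read
length 100: depths 30 (undirectional), 20 and 8 (directional), each single-
and paired-end, with mutation and sequencing-error rates of 0.005.  The
duplicated leading segment is scaled with the reference so the ambiguous
fraction of the genome matches the full-scale benchmark (10 kb of ~44 Mb
there, 200 bp of ~200 kb here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import align_fastq, sort_and_index
from .call import CallFilters, call_and_write
from .evaluate import evaluate_alignments, evaluate_methylation
from .index import build_index
from .reference import GenomeReference
from .simulate import (
    SimulationParams,
    assign_profile,
    build_simulation_reference,
    simulate_reads,
)


@dataclass(frozen=True)
class GridCondition:
    depth: float
    paired: bool
    undirectional: bool
    mutation_rate: float = 0.005
    error_rate: float = 0.005

    @property
    def label(self) -> str:
        return (
            f"depth{self.depth:g}_{'pe' if self.paired else 'se'}_"
            f"{'undir' if self.undirectional else 'dir'}"
        )


DEFAULT_GRID = [
    GridCondition(30, True, True),
    GridCondition(30, False, True),
    GridCondition(20, True, False),
    GridCondition(20, False, False),
    GridCondition(8, True, False),
    GridCondition(8, False, False),
]


def random_genome(
    rng: np.random.Generator,
    n_contigs: int = 10,
    contig_length: int = 200_000,
    n_blocks: int = 4,
    n_block_length: int = 60,
) -> GenomeReference:
    """Random A/C/G/T toy genome with a few N blocks per contig."""
    contigs = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_contigs):
        codes = rng.integers(0, 4, contig_length)
        arr = bases[codes].copy()
        for _ in range(n_blocks):
            start = int(rng.integers(0, contig_length - n_block_length))
            arr[start : start + n_block_length] = ord("N")
        contigs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return GenomeReference(contigs)


def run_condition(
    index, simref: GenomeReference, profile, cond: GridCondition, workdir: Path,
    read_length: int, seed: int,
) -> dict:
    workdir.mkdir(parents=True, exist_ok=True)
    fq1 = workdir / "r1.fastq"
    fq2 = workdir / "r2.fastq" if cond.paired else None
    truth = workdir / "truth.tsv"
    params = SimulationParams(
        read_length=read_length,
        depth=cond.depth,
        paired=cond.paired,
        undirectional=cond.undirectional,
        mutation_rate=cond.mutation_rate,
        error_rate=cond.error_rate,
        seed=seed,
    )
    sim = simulate_reads(simref, profile, params, fq1, fq2, truth)

    raw_bam = workdir / "aligned.bam"
    sorted_bam = workdir / "aligned.sorted.bam"
    align_fastq(index, fq1, fq2, raw_bam, out_format="BAM",
                undirectional=cond.undirectional)
    sort_and_index(raw_bam, sorted_bam)

    aln_eval = evaluate_alignments(sorted_bam)
    call_and_write(
        sorted_bam, simref, workdir / "calls",
        CallFilters(min_mapq=20, cg_only=True),
    )
    meth_eval = evaluate_methylation(workdir / "calls.CGmap", truth)
    return {
        "condition": cond.label,
        "reads": sim["reads_emitted"],
        **aln_eval.as_dict(),
        **meth_eval.as_dict(),
    }


def run_desk_benchmark(
    seed: int,
    workdir: str | Path,
    grid: list[GridCondition] | None = None,
    read_length: int = 100,
    n_toy_contigs: int = 10,
    toy_contig_length: int = 200_000,
    per_contig_target: int = 20_000,
    tile_length: int = 50,
    duplicate_head: int = 200,
    seed_min_length: int = 19,
) -> dict:
    """Run the full grid and return per-condition metrics plus grid averages."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)

    toy = random_genome(rng, n_toy_contigs, toy_contig_length)
    simref = build_simulation_reference(
        toy, per_contig_target=per_contig_target, tile_length=tile_length,
        max_ambiguous=10, duplicate_head=duplicate_head, rng=rng,
    )
    index = build_index(simref, seed_min_length)
    profile = assign_profile(simref, rng=rng)

    conditions = []
    for i, cond in enumerate(grid):
        res = run_condition(
            index, simref, profile, cond, workdir / cond.label, read_length,
            seed=seed * 1000 + i,
        )
        conditions.append(res)

    n = len(conditions)
    summary = {
        "t1": 100.0 * sum(c["mappability"] for c in conditions) / n,
        "t2": 100.0 * sum(c["on_target"] for c in conditions) / n,
        "t3": sum(c["coverage_mae"] for c in conditions) / n,
        "t4": sum(c["level_mae"] for c in conditions) / n,
    }
    return {
        "seed": seed,
        "reference_length": simref.total_length,
        "conditions": conditions,
        "summary": summary,
    }
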