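"""Consensus methylation matrix assembly from CGmap files.

Two-pass iterative method: pass 1 counts, per site, the files where the site
is covered at or above the coverage threshold; sites observed in at least the
required proportion of files are retained; pass 2 fills the matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .call import read_cgmap

SiteKey = tuple[str, int, str]  # (contig, position_1based, ref_nucleotide)


@dataclass
class ConsensusMatrix:
    site_index: list[SiteKey]
    sample_names: list[str]
    values: np.ndarray  # sites x samples, NaN = missing
    meth_counts: np.ndarray  # int, 0 where missing
    total_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = [f"{c}:{p}:{n}" for c, p, n in self.site_index]
        return pd.DataFrame(self.values, index=rows, columns=self.sample_names)


def _sample_name(path: str | Path) -> str:
    name = Path(path).name
    for suffix in (".gz", ".CGmap", ".cgmap", ".txt", ".tsv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name or str(path)


def _scan_file(path: str | Path, min_coverage: int):
    """Yield (site_key, meth, total) for covered sites; reject duplicate sites."""
    seen: set[SiteKey] = set()
    for rec in read_cgmap(path):
        key = (rec.contig, rec.position_1based, rec.ref_nucleotide)
        if key in seen:
            raise ValueError(f"duplicate site {key} in {path}")
        seen.add(key)
        if rec.total_count >= min_coverage:
            yield key, rec.methylated_count, rec.total_count


def aggregate(
    cgmap_paths: list[str | Path],
    min_coverage: int = 10,
    min_sample_proportion: float = 0.9,
    sample_names: list[str] | None = None,
) -> ConsensusMatrix:
    """Assemble a consensus matrix across CGmap files.

    A site is retained when it is covered >= min_coverage in at least
    min_sample_proportion of the files (proportion compared as an exact
    rational).  Cells below min_coverage are missing, not zero.
    """
    if not cgmap_paths:
        raise ValueError("at least one CGmap path is required")
    if not 0 < min_sample_proportion <= 1:
        raise ValueError("min_sample_proportion must be in (0, 1]")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    names = sample_names or [_sample_name(p) for p in cgmap_paths]
    if len(names) != len(cgmap_paths):
        raise ValueError("sample_names length must match cgmap_paths")

    n_files = len(cgmap_paths)
    counts: Counter[SiteKey] = Counter()
    contig_order: dict[str, int] = {}
    for path in cgmap_paths:
        for key, _m, _t in _scan_file(path, min_coverage):
            counts[key] += 1
            contig_order.setdefault(key[0], len(contig_order))

    # exact rational comparison; str() gives the shortest decimal so a user's
    # 0.4 means 2/5, not the slightly-larger binary float
    threshold = Fraction(str(min_sample_proportion))
    retained = sorted(
        (k for k, c in counts.items() if Fraction(c, n_files) >= threshold),
        key=lambda k: (contig_order[k[0]], k[1], k[2]),
    )
    row = {k: i for i, k in enumerate(retained)}

    values = np.full((len(retained), n_files), np.nan)
    meth = np.zeros((len(retained), n_files), dtype=np.int64)
    total = np.zeros((len(retained), n_files), dtype=np.int64)
    for j, path in enumerate(cgmap_paths):
        for key, m, t in _scan_file(path, min_coverage):
            i = row.get(key)
            if i is None:
                continue
            meth[i, j] = m
            total[i, j] = t
            values[i, j] = m / t
    return ConsensusMatrix(retained, list(names), values, meth, total)


def write_matrix(
    matrix: ConsensusMatrix, out_prefix: str | Path, include_counts: bool = False
) -> list[str]:
    """TSV with a sample-name header row and `contig:pos:nucleotide` site keys;
    missing cells serialized as NA."""
    paths = []

    def _write(path, array, fmt):
        with open(path, "w") as fh:
            fh.write("site\t" + "\t".join(matrix.sample_names) + "\n")
            for i, (c, p, n) in enumerate(matrix.site_index):
                cells = []
                for j in range(len(matrix.sample_names)):
                    if matrix.total_counts[i, j] == 0:
                        cells.append("NA")
                    else:
                        cells.append(fmt(array[i, j]))
                fh.write(f"{c}:{p}:{n}\t" + "\t".join(cells) + "\n")
        paths.append(str(path))

    _write(f"{out_prefix}.values.tsv", matrix.values, lambda v: f"{v:.6g}")
    if include_counts:
        _write(f"{out_prefix}.meth.tsv", matrix.meth_counts, lambda v: str(int(v)))
        _write(f"{out_prefix}.total.tsv", matrix.total_counts, lambda v: str(int(v)))
    return paths


def read_matrix(values_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA"])
    return df
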