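# methylbolt

Desk-scale bisulfite sequencing toolkit: methylation-aware read simulation,
3-base alignment over a single dual-strand converted index, strand-aware
per-site methylation calling, consensus matrix aggregation, and truth-based
benchmark metrics.

## What it does

- **`methylbolt index`** — loads a FASTA reference, builds C→T conversions of
  both genome strands, and indexes them together in one exact-substring seed
  structure (suffix array) with a coordinate map back to
  (contig, position, bisulfite strand).
- **`methylbolt simulate`** — WGSIM-style read simulator with per-site
  methylation: a methylation level is drawn for every methylatable site
  (CG/CH context, or overlaid from a CGmap file), haplotype variation and
  sequencing error are applied, and every read carries a lossless truth
  comment (`contig:start:end:strand:pattern:methstring`). Realized per-site
  methylated/total counts are written as a sorted TSV. A tiled simulation
  reference builder (random 50 bp tiles, ambiguous-base rejection,
  duplicated leading segment as an extra contig) is included.
- **`methylbolt align`** — reads (or pairs) are fully in-silico converted and
  aligned in converted space: undirectional libraries get a base-composition
  conversion-pattern assessment (C:G proportion, default threshold 0.1; both
  patterns are aligned when unclear and the best total score wins), seeds are
  exact suffix-array matches extended with affine-gap local alignment,
  alignments are reported on the unconverted sense reference with the
  bisulfite strand in a tag, mapping quality is penalized for hits ambiguous
  across bisulfite strands, read-level methylation calls and a conversion
  QC status are computed, and tagged SAM/BAM is written
  (`YS` strand, `YC` pattern, `XB` call string, `XF` conversion status,
  `AS`/`XS` scores).
- **`methylbolt call-methylation`** — strand-aware pileup calling from a
  coordinate-sorted indexed BAM: sense reads vote at reference C (C/T),
  antisense reads at reference G (G/A), reads at mapping quality ≤ 20 are
  excluded by default (strict threshold), overlapping mates count once.
  Output is CGmap and optionally Bismark-style bedGraph coverage.
- **`methylbolt aggregate`** — two-pass consensus matrix over many CGmap
  files: sites covered ≥ `--min-coverage` in ≥ `--min-proportion` of files
  are retained (exact rational comparison); below-coverage cells are missing
  (`NA`), not zero.
- **`methylbolt evaluate`** — mappability, on/off-target classification
  (≥ 95 % of aligned bases inside the truth interval on the correct origin
  strand, no QC failure), and per-CpG coverage / methylation-level mean
  absolute error against the simulator's truth counts.

## CLI walk-through

```bash
methylbolt index -G ref.fa -O idx
methylbolt simulate -G ref.fa -O sim -PE --depth 20 --seed 1
methylbolt align -DB idx -F1 sim_1.fastq -F2 sim_2.fastq -O out.bam --sort
methylbolt call-methylation -I out.bam -DB idx -O calls --CG-only
methylbolt aggregate -I a.CGmap -I b.CGmap -O matrix --min-coverage 10 --min-proportion 0.9
methylbolt evaluate --bam out.bam --truth sim.truth.tsv --cgmap calls.CGmap -O report.json
```

## Acceptance benchmark

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Builds a ~200 kb tiled simulation reference from a synthetic 2 Mb toy
genome, simulates the library grid at read length 100 (depths 30/20/8,
directional and undirectional, single- and paired-end, mutation and error
rates 0.005), aligns, calls CpG methylation, and reports grid-averaged
metrics: `t1` mappability (%), `t2` on-target (%), `t3` coverage MAE
(reads), `t4` methylation level MAE. Runs in about 4 minutes on one CPU.

## Notes on defaults

- Alignment scoring: match +1, mismatch 4, gap open 6, gap extend 1;
  mapq = round(60·(best−second)/best), minus 20 points when a near-equal hit
  exists on the other bisulfite strand; configurable.
- Conversion QC: a read/pair fails when > 50 % of ≥ 3 observed CH sites are
  methylated; failed reads are flagged, not dropped.
- Context at contig edges or next to N is "unknown": such cytosines are not
  simulated as methylatable and are excluded from CG-only output.
- Coordinates are 0-based half-open internally; 1-based only in SAM/CGmap.
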