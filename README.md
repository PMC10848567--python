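# museumharvest

Tiled-amplicon COI barcode recovery and taxonomic assignment for
natural-history-collection specimens.

Natural history collections hold millions of authoritatively identified
specimens whose DNA is old and fragmented. "Museum harvesting" arrays
pinned specimens in 96-well-format grids (95 specimens + one negative
control per array), amplifies multiple short, overlapping fragments of the
658-bp cytochrome c oxidase subunit I (COI) barcode region, tags each
sample with a unique forward/reverse index pair, pools everything for
high-accuracy amplicon sequencing, and reassembles per-specimen barcodes
informatically. `museumharvest` implements that informatics pipeline for
collection managers and barcoding labs, plus the downstream statistics a
harvesting campaign reports.

## What it does

* **Plate data model** — 8×12 specimen arrays, canonical sample IDs
  (`CCDB-31120-A01`), specimen metadata TSV I/O.
* **Panel/tag configuration** — amplicon tiling schemes on the 658-bp
  barcode frame (presets: `sanger2`, two amplicons of 307/407 bp;
  `ngs_tiled`, six short overlapping amplicons) and validated 96+96
  sample-tag sets with guaranteed unique decoding under a mismatch
  tolerance.
* **Simulator** — seeded synthetic barcodes on a genus/species hierarchy,
  age-dependent amplicon loss (`survival = 2^(−age/half_life)`), and
  error-bearing tagged reads, so the whole pipeline is testable offline.
* **Assembler** — the six-stage pipeline: quality filter (mean QV ≥ 20,
  ≥ 100 bp) → tag demultiplexing → order-level taxonomy screen → primer
  based amplicon assignment → alignment-free positioning at known amplicon
  coordinates → per-column majority consensus, with uncovered internal
  columns filled with `N` so the barcode stays contiguous.
* **Classifier** — p-distance (ambiguity- and gap-excluded), a documented
  single-linkage proxy for barcode-cluster membership, and the two-route
  taxonomy assignment: cluster ("BIN") taxonomy match first, then
  nearest-match thresholds (species < 2%, genus < 5%, strict) truncated to
  the lowest conflict-free rank.
* **Reporting** — recovery (> 0 non-N bp) and success (> 300 non-N bp)
  percentages, per-genus success, failure-tracking accounting with count
  conservation, age–length OLS regression, and method × rank assignment
  tables.

## Worked example

Simulate one small array, assemble it, and summarise success — everything
below is real output:

```bash
museumharvest simulate --n 12 --depth 3 --seed 11 --out sim
# build an id→taxonomy TSV for the simulated specimens (sim/ref_tax.tsv),
# then:
museumharvest assemble --fastq sim/reads.fastq --plate sim/plate.tsv \
    --ref sim/true_barcodes.fasta --ref-tax sim/ref_tax.tsv --out asm
museumharvest report --consensus asm/consensus.fasta --plate sim/plate.tsv \
    --flags asm/flags.tsv --out rep
```

```
specimens	12
recovered	9	75.0%
acceptable	5	41.7%
flagged	0
genera	12
genera_acceptable	5	41.7%
age_length_slope	-2.4003	R2=0.1552	p=0.294
```

Reading this: of 12 simulated specimens (collection years drawn over
1901–2017, amplicon survival halving every 40 years), 9 recovered some
sequence (75.0%), 5 recovered an *acceptable* barcode of more than 300
non-N bases (41.7%), and recovered length declines by ~2.4 bp per year of
specimen age (not significant at n = 9 — expected for so few points).
Old specimens lose whole amplicons, so their consensus barcodes are short
or gap-filled with `N`; fresh specimens assemble to the full 658 bp.

The same operations are importable as a library
(`museumharvest.run_pipeline`, `museumharvest.assign_all`, ...), which is
how the test suite drives them.

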