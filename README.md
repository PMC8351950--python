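# oligomux

Multiplexed Oligopaint FISH probe design for whole-chromosome and
sub-chromosomal paints, built around the silkworm (*Bombyx mori*) paint
libraries but applicable to any assembly.

Oligopaints are computationally designed DNA FISH probes: each oligo carries
a genomic homology region (here 80 nt) that must map to the genome exactly
once, flanked by non-genomic handles. `oligomux` covers the dry-lab side of
a multiplexed design end to end:

- **Probe mining** — discover genome-unique 80-mers inside a paint interval
  (exact both-strand occurrence counting via a seed k-mer index, GC/Tm/
  homopolymer filters, nearest-neighbor Tm), then **thin** to a nominal
  density of 1 or 1.5 probes/kb on an ideal uniform grid.
- **Barcoding** — generate orthogonal 20-nt barcode sets (pairwise Hamming
  floor, reverse complements included) and assemble primary oligos:
  `universal_5p | sub1? | homology | sub2? | universal_3p`, 120/140/160 nt,
  with a modeled barcode-selective PCR that appends the secondary-oligo
  binding site.
- **Sub-libraries** — partition a paint into tel1/mid/tel2 stripes, or into
  transcriptionally active (CENP-T depleted) vs inactive (CENP-T enriched)
  chromatin domains by averaging 10-kb ChIP signal over 50-kb windows,
  thresholding, and subtracting the negative interval set from the positive
  one; assign probes to partitions by full containment.
- **Manifests** — per-chromosome library summaries and domain reports that
  reproduce the published tables' arithmetic (`size = stop − start` for
  paints, `stop − start + 1` for domains) and two-decimal Mb stripe sizes.
- **Pairing statistics** — exact two-sided Fisher (integer point-probability
  summation), exact binomial orientation test against 50:50, and
  configuration-frequency summaries across replicate gonads.
- **Synthetic fixtures** — seeded genomes with planted repeats, ChIP-like
  tracks with planted domains, and multinomial count tables, each with a
  ground-truth record.

The published coordinate tables for the seven silkworm libraries (paints,
stripes, ch7/15/16 chromatin domains) ship as package data under
`oligomux.tables`.

## Worked example

Mine a 50-kb synthetic chromosome at 1.5 probes/kb:

```bash
python - <<'EOF'
from oligomux.fixtures import SyntheticGenomeSpec, make_genome
from oligomux.genome_io import write_fasta
asm, _ = make_genome(SyntheticGenomeSpec(lengths={"chr1": 50_000}, seed=7))
write_fasta(asm, "demo.fa")
EOF
oligomux mine --genome demo.fa --paint chr1:0-50000 --density 1.5 --out demo
```

```
INFO oligomux: mined 622 unique probes in chr1:0-50000
INFO oligomux: thinned to 75 probes (1.50/kb target)
```

622 windows passed the uniqueness and composition filters (~12/kb of
candidates); thinning keeps exactly `round(1.5 × 50) = 75`, evenly spread.
The manifest records the printed-coordinate size convention and the
achieved density:

```
chrom  chromosome_size_bp  size_painted_bp  paint_start  paint_stop  density_probes_per_kb  achieved_density_probes_per_kb  total_oligos
chr1   50000               49999            1            50000       1.5                    1.5                             75
```

Barcodes and statistics:

```bash
oligomux barcode --n 4 --seed 11        # orthogonal 20-mers, Hamming >= 8
oligomux stats fisher 44 6 22 28        # p=5.38789e-06
oligomux stats orientation 171 186      # n=357 tel1_paired=48% p=0.458766
```

The Fisher example asks whether single-domain pairing is enriched at a
telomere stripe versus the middle stripe; the orientation example tests a
metaphase-I tel1/tel2 count against the 50:50 expectation (here,
indistinguishable from random — both chromosome ends are equally able to
face the spindle pole).

Library code mirrors the CLI: see `oligomux.mine_probes`,
`thin_to_density`, `generate_barcodes`, `assemble_primary`,
`define_stripes`, `average_track`, `call_domains`, `assign_probes`,
`summarize`, `fisher_exact_2x2`, `orientation_fraction`.

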