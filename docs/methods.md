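# Methods

`oligomux` implements the computational side of a multiplexed Oligopaint
FISH probe-design workflow for the silkworm *Bombyx mori* (the packaged
coordinate tables describe that genome's paint libraries, but every
operation accepts any assembly). This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Coordinate model

All computation uses 0-based half-open intervals. The published coordinate
tables print 1-based inclusive-looking integers; table import subtracts 1
from starts, and the manifest writers re-apply each table's printing
convention. Two printed size conventions coexist and are reproduced rather
than unified:

- whole-chromosome paint manifest: `size_painted = paint_stop − paint_start`
  on printed coordinates (one less than the interval length);
- chromatin-domain report: `size = stop − start + 1` (the interval length).

Each writer names its convention in a header comment.

## Probe mining

A homology probe (default 80 nt) is accepted only if its exact sequence
occurs once in the union of the assembly's plus strands and their reverse
complements. Uniqueness is decided exactly: a seed k-mer index (default
k = 18, 2-bit encoded, sorted arrays) proposes candidate sites; every site
is verified against the full probe. This is strictly stronger than
alignment-heuristic specificity screens, and at desk scale it is affordable.
Probes are placed greedily left to right without overlap — the leftmost
position passing every filter is taken and the scan resumes after it — so
output is deterministic with no hidden randomness.

Default filters (all configurable and recorded in the run config): GC
0.25–0.75, Tm 37–85 °C, homopolymer runs ≤ 6, no N, optional exclusion of
soft-masked bases. These are typical ranges for oligo-pool FISH mining; the
workflow being reproduced does not publish its exact filter set, so Table-1
style oligo totals against a real assembly are not a reproduction surface.

Melting temperature uses unified nearest-neighbor thermodynamics
(SantaLucia & Hicks 2004 table) with duplex initiation and terminal-A·T
penalties, monovalent-salt entropy correction `0.368·(N−1)·ln[Na+]` at
50 mM Na+, and effective duplex concentration CT/4 for non-self-complementary
strands at 25 nM each. The implementation is cross-checked in the test suite
against an independent nearest-neighbor implementation with the same
published table.

### Thinning

Whole-chromosome paints mined at the ~3 probes/kb ceiling are thinned to a
nominal 1 or 1.5 probes/kb. The rule: lay an ideal uniform grid of
`round(target × paint kb)` points over the paint; each grid point, in
order, claims the unselected candidate whose midpoint is nearest (ties to
the leftmost). When candidates saturate, the output count equals the target
exactly; when they do not, all candidates are returned with a warning. The
grid rule maximizes spacing uniformity without any global optimization and
keeps the max inter-probe gap within twice the ideal spacing whenever every
1-kb bin holds a candidate.

## Barcoding and oligo anatomy

A primary oligo is `universal_5p | sub1? | homology | sub2? | universal_3p`
with all barcodes exactly 20 nt, so lengths are 120, 140 or 160 nt and
never exceed 160. A single sub-library barcode is placed 5′ of the homology;
the published design does not state the single-barcode side, so one side
was fixed for determinism (the caller can pass an explicit pair to get the
other). Barcode sets are rejection-sampled from a seeded generator under a
pairwise Hamming floor (default 8 for 20-mers, a standard orthogonality
margin for PCR-index-like barcodes) applied to every pair *and* every
reverse-complement pair, including each barcode against its own reverse
complement. At library assembly, every barcode is additionally checked not
to occur as an exact substring (either orientation) of any homology region.
Amplification is modeled textually: forward primer = sub-library barcode,
reverse primer = secondary-oligo binding site + reverse complement of the
universal 3′ barcode; no thermodynamic primer optimization is attempted.

## Stripe schemes

A stripe scheme labels the first (tel1), middle (mid) and last (tel2)
segment of a paint. Explicit coordinates (e.g. the published stripe table)
pass through unmodified; their nominal size defaults to the mean of the
three stripe sizes, against which the 15% size-deviation invariant is
checked (the literal 3 Mb / 1.5 Mb class values deviate by up to 22% from
the published stripes, so the class value is a label, not the validation
reference). Automatic placement anchors tel1 at the paint start, tel2 at
the paint end, centers mid on the paint midpoint, and snaps internal
boundaries to the nearest probe start/end when probes are supplied (1-bp
resolution otherwise). The published middle stripes sit 20–60 kb off exact
midpoints on some chromosomes and the original snapping rule is not
recoverable, so automatic placement is approximate and explicit coordinates
are authoritative.

## Chromatin-state domains

Input is CENP-T ChIP-seq signal in fixed 10-kb bins (bedGraph). The track
is averaged over 50-kb windows (arithmetic mean ignoring no-data bins; an
all-missing window stays no-data; a trailing partial window averages what
exists). Windows above the threshold are CENP-T enriched → transcriptionally
inactive; windows at or below it are depleted → active. Runs of at least
`min_run` like windows become domains; the negative interval set is then
subtracted from the positive set to give the final inactive domains, and
the negative set gives the active domains. Domains are clipped to the
paint, which automatically produces the published edge behavior: when the
window containing a paint edge has data, the edge domain ends at the exact
paint coordinate; a no-data edge window leaves a gap (the published ch7
table itself stops ~55 kb short of the paint end, consistent with trailing
missing data).

Open parameters, stated honestly: the positive/negative threshold is not
published; the default 0 suits a log2-enrichment-like signal and is a
required, manifest-recorded choice for anything else. `min_run` defaults to
1 window because the published tables contain 50-kb domains, i.e. no
smoothing beyond the 50-kb averaging was applied.

Probe → partition assignment is by full containment; probes straddling a
boundary or in gaps are reported unassigned. Gene density is
(gene midpoints in interval) / (interval length in Mb); midpoint membership
makes densities additive across a partition.

## Pairing statistics

The cytological statistics operate on manually scored counts:

- **Fisher's exact test (2×2, two-sided)** by the point-probability method —
  the sum over tables with the observed margins of hypergeometric point
  probabilities no larger than the observed one. Implemented with exact
  integer binomial coefficients, so ties at the observed probability are
  resolved exactly; any zero margin gives p = 1.
- **Orientation fraction**: tel1/(tel1+tel2), displayed as a half-up-rounded
  integer percent, with an exact two-sided binomial test against 1/2
  (again exact integers; at p = 1/2 point probabilities are proportional to
  binomial coefficients).
- **Configuration frequencies**: per-replicate category fractions (each
  summing to 1), mean and sample SD (ddof = 1) across replicate gonads; a
  single replicate has no defined SD and reports zeros with a flag.

No multiple-testing correction is applied by default (per-comparison
reporting); a Bonferroni helper exists. Published metaphase orientation
percentages (≈ 47–50% tel1-paired) are observational image counts, not
recomputable outputs; the statistic is validated instead by closed forms,
enumeration oracles and simulation.

## Synthetic data

The generators emulate the study's inputs with known truth:

- **Genomes**: i.i.d. bases at a target GC (default 0.40, silkworm-like),
  with exact repeat units pasted at chosen positions; the truth record lists
  every repeat copy (no interior probe can be unique). Default scale
  2 × 500 kb keeps tests sub-second while exercising 50-kb windowing.
- **Tracks**: planted active/inactive domains tiling a chromosome, state
  means ±2.0 around a zero threshold, additive Gaussian noise SD 0.5 per
  10-kb bin — a 4:1 signal-to-noise ratio (|state mean| / noise SD). Equal
  state means are flagged as unidentifiable.
- **Counts**: seeded multinomial draws per replicate.

Each generator draws from an independent substream keyed by (master seed,
generator name), so adding one generator never perturbs another's output.

What the synthetic data does **not** model: real repeat landscapes
(tandem/divergent families, soft-masked heterochromatin), GC heterogeneity
and mappability structure, ChIP-seq coverage biases and fragment-level
noise, or any image-formation process. Passing tests therefore demonstrate
algorithmic correctness under the stated model, not performance on a real
assembly.

## Problem sizes

The test suite and the acceptance script run the simulation studies at the
scale the toolkit's own fixtures define: 40-kb genomes with a planted
duplicated kilobase for the uniqueness/oracle comparison (10–20 seeds),
1-Mb chromosomes with 200-kb planted blocks for boundary recovery
(100 seeds), full enumeration of 2×2 tables with total ≤ 30 for the exact
test, and 10,000-cell multinomial draws for the orientation statistic.

## Known limitations

- Uniqueness is exact-match only; near-identical repeats (one mismatch)
  pass, unlike alignment-based off-target screens with mismatch tolerance.
- Greedy left-to-right placement is not globally optimal for probe count;
  it is chosen for determinism and simplicity.
- Automatic stripe placement approximates the published coordinates only
  up to probe-boundary snapping.
- The domain caller has no HMM/segmentation model; it is deliberately the
  threshold-average-subtract procedure, parameterized transparently.
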