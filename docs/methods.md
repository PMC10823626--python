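# Methods

## Scope and model

`masiso` is a closed-loop benchmark for concatemer-array long-read isoform
sequencing: it generates a fully known reference transcriptome, simulates
the library chemistry and sequencing down to per-base errors, and then runs
the complete analysis chain (split → refine → collapse → classify →
compare → filter) whose outputs can be scored against the hidden truth
carried by every simulated read. All internal coordinates are 0-based
half-open; GTF output is 1-based inclusive; BED12 blocks are 0-based
half-open.

## Reference synthesis

Each gene locus gets a master exon skeleton (5–9 exons; terminal exons
300–700 bp, internal 80–350 bp, introns 60–300 bp). An isoform selects a
subset of master exons — internal exons keep master coordinates so splice
sites are shared across isoforms — and receives alternative start/stop
positions on its terminal exons so that its spliced length lands uniformly
inside the requested range. Splice sites are stamped as GT..AG on the
transcript strand. One gene per module (when ≥ 2 genes are requested) is
placed antisense, fully inside the first gene's span, so the antisense
category is exercised. Candidate isoforms that share an intron chain with
an existing isoform of the locus *and* have both ends within 130 bp of it
are resampled: such pairs would be indistinguishable under the collapse
rule (< 100 bp 5′, < 30 bp 3′) once alignment end jitter (≤ 20 bp) is
added, and a benchmark truth set must be distinguishable by construction.
The long module emits mono-exonic transcripts within ±2 % of their nominal
sizes ("roughly" 4–12 kb), one contig each. The background module reuses
the isoform generator (default 50 genes / 150 isoforms, 300–5,000 bp) as a
stand-in for transcriptome complexity.

## Library simulation

* **Expression.** Spike-ins are equimolar and take a configurable fraction
  of the pool (default 2 %); background transcripts get log-normal weights
  (σ = 1.5 by default). TPM sums to 10⁶ exactly; molecule counts are one
  multinomial draw.
* **cDNA.** A molecule is 5′ primer + transcript + 30-base poly(A) + 3′
  primer, error-free at this stage. TSO artifacts (default rate 2 %, a free
  parameter of the protocol) carry an internal transcript fragment and no
  poly(A); they are produced at a binomial rate per real molecule.
* **Capture.** Retention is 1 up to a 2,000 bp knee, then declines as a
  logistic in log-length with midpoint 8,600 bp and steepness 42, floor 0.
  These defaults place retention at ~0.95 for 8 kb, ~2·10⁻³ for 10 kb and
  ~10⁻⁶ for 12 kb — i.e. 10 kb molecules survive at a low but nonzero rate
  while 12 kb molecules effectively never do, reproducing the observed
  loss of the longest spike-ins to steric hindrance during bead capture.
  TSO artifacts are removed outright here (that is the capture step's
  purpose).
* **Size selection** is exact on total molecule length: > 2,000 bp to the
  dimer fraction, 500–2,000 bp to the tetramer fraction, < 500 bp
  discarded. 2,000 bp itself goes to the short fraction (the published
  boundaries leave the point ambiguous; an inclusive upper bound was
  chosen and is asserted in tests).
* **Concatenation.** An arity-k array is B0 seg B1 … seg Bk with 16 bp
  junction barcodes (minimum pairwise edit distance 5, generated — real
  barcode sets are proprietary and only distinguishability matters). With
  probability `full_array_rate` (defaults 0.777 dimer / 0.727 tetramer) an
  array takes its full arity; otherwise it truncates to a uniform
  1..arity−1 segments. Truncated arrays draw only as many molecules as
  they hold, so every captured, size-selected molecule lands in exactly
  one array (exact molecule conservation; only aggregate efficiencies are
  published, not a truncation-length distribution).
* **Errors.** Substitution:insertion:deletion at 2:1:1 (configurable; the
  published accuracy figure fixes only the total rate, 10⁻³/base). Truth
  segment offsets are carried through indels, with per-segment injected
  edit counts recorded for oracle tests.

## Deconcatenation

Barcodes are located by bounded edit distance (edlib, default `max_edit` 3
≈ 19 % of a 16 bp barcode). Overlapping hits resolve by lowest distance
then leftmost position; the surviving hits are filtered to the best
subsequence whose barcode indices strictly increase in design order
(maximising count, then total match quality). This ladder constraint is
what suppresses chance 16-mer matches inside segments, which would
otherwise over-split reads at this edit allowance. Orientation (forward vs
reverse complement) and the best-matching design are chosen once per read
by total barcode score. Inter-barcode intervals become s-reads; terminal
slop ≤ `max_edit` around an end barcode is treated as matching jitter, not
a segment. A read with no barcode hits is one s-read. A full array is one
whose segment count equals its design arity with the complete ladder in
order. Segments under 50 bp are flagged short rather than dropped.

## Refinement

The best 5′/3′ primer pair is sought at the read termini in both
orientations (edit distance ≤ 3, terminal slop 8 bp); multiple pairs are
supported with per-pair accounting. The poly(A) trimmer removes the
trailing A-rich run (≥ 20 A's, at most 1 interior non-A; IsoSeq-style
defaults, not published). Residual concatemers are detected by internal
primer occurrences at edit distance ≤ 1 plus exact internal barcodes — a
missed junction always leaves intact primers behind, while the corrupted
barcode that caused the miss is undetectable anyway; the asymmetric
allowance keeps chance-match false positives negligible. Inserts under
80 bp after trimming are statused `short` (no spike-in is that small).
Poly(A) is required for FLNC status by default (`require_polya=False`
disables it). TSO artifacts that leak past capture fall out at the
no-poly(A) step.

## Collapse and classification

Collapse is single-linkage over the merge relation (< 100 bp 5′ /
< 30 bp 3′ strand-aware end difference, per-junction wobble ≤ 10 bp — 10
passes, 11 fails, reading "gaps that exceed ten bp" as exclusive).
Connected components are computed in a deterministic sorted order, and
transitive chaining of near-identical reads is documented, tested
behaviour. Ends are compared in genomic, strand-aware coordinates.
Alignment itself is out of scope: simulation mode places each FLNC read on
its source transcript's chain with an inward end jitter (≤ 20 bp at 5′,
≤ 8 bp at 3′) emulating aligner end uncertainty; real-data mode consumes
BED12 exon chains produced externally.

Classification uses a fixed precedence: FSM (identical intron chain;
among references sharing the chain, closest ends win; mono-exon FSM is
containment in a mono-exon reference ± 50 bp), then ISM (contiguous
sub-chain), then fusion (exonic overlap with ≥ 2 same-strand loci), then
NIC/NNC by splice-site novelty (intron retention bounded by annotated
junctions classifies NIC), then the overlap classes
(genic-genomic / genic-intronic / antisense / intergenic). Opposite-strand
intron-only overlap is classed genic-intronic; antisense requires exonic
overlap on the opposite strand. Intergenic isoforms receive novel gene ids,
one per overlap cluster, so unique-gene counts are well defined. An empty
annotation classifies everything intergenic.

## Comparison metrics and filters

Cross-sample merging reuses the collapse merge rule (a deliberate
unification; the external tool's tolerance is not published), summing
per-sample support over merged members and optionally dropping intergenic
("unknown") rows. Percentages and folds are rounded half-up to one
decimal; whole-number folds ≥ 1000 are reported without decimals. Fold
changes replace zero operands with a pseudocount of one. The differential
filter is a single conjunctive pass (FSM, tumor reads ≥ 10, tumor TPM
≥ 10, both folds ≥ 5 inclusive, thresholds compared on the exact ratio,
not the rounded display value); the novel filter keeps NIC/NNC isoforms
with ≥ 10 tumor reads and zero comparator reads, ignoring TPM (novel
isoforms have none). Fusion candidates need ≥ 2 loci, ≥ 5 % of the read
per locus, ≥ 99 % combined coverage and ≥ 5 FLNC reads; passing fusions
with a spike-in partner are flagged as deconcatenation artifacts.

## Study defaults and problem sizes

The packaged studies run at desk scale, chosen to finish in seconds to
tens of seconds on one CPU while keeping binomial uncertainties a few per
mille to a few per cent:

* mixed-run study: 20,000 arrays, 20 % dimer / 80 % tetramer. The
  tetramer-weighted mix reflects that most expressed transcripts fall in
  the short (500–2,000 bp) fraction; at the default efficiencies it yields
  an expected 3.1 segments per read, versus 2.6 for an equal mix.
* capture study: 10,000 molecules per length cohort.
* error-free recall: 69 isoforms × ~30 copies, minimum isoform length
  500 bp so both size fractions are populated and nothing is discarded;
  recall is 100 % by construction of a distinguishable truth set.
* two-condition study: 40 genes / 120 isoforms, 20,000 molecules per
  condition, σ = 0.8, the four lowest-abundance genes spiked 10-fold.
  Spiking low-abundance genes keeps the renormalised TPM fold well above
  the 5-fold threshold (a heavily-expressed spike set would dilute its own
  fold change). Both conditions share one abundance profile and RNG
  stream, so only the spike and sampling noise differ. Sensitivity is
  measured over truth groups the workflow can distinguish (isoforms
  deduplicated by shared intron chain or near-coincident mono-exon spans).

## What the simulation does and does not capture

The generator reproduces expression abundance structure, TSO artifacts,
length-dependent capture loss, incomplete array ligation, and HiFi-scale
error rates. It does **not** model PCR duplicates (no UMIs in the
protocol), polymerase-kinetics/subread-level consensus, 5′ degradation
beyond the truncation flag, intron-length or exon-count distributions of
any real spike-in product, or real genome complexity (repeats, paralogy,
alignment ambiguity — simulation-mode "alignment" is truth-based by
design). Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under these conditions, not performance on
real libraries; the real-data entry points (BED12 chains, expression TSVs)
exist precisely so the same code can be applied outside the simulation.

## Numerical and degenerate-input choices

Deterministic tie-breaks everywhere: barcode conflicts by (distance,
position), cluster representatives by (span, id), FSM by (end shift, id),
component order by (contig, strand, position, id). All randomness descends
from one integer seed through named substreams, so any stage can be re-run
independently and byte-identically. Empty inputs return empty outputs
(size selection, collapse, concatenation); zero-denominator folds use the
pseudocount; an empty truth set or empty TPM table set is an error rather
than a silent zero.
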