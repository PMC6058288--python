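# Methods

## Generative model of the screen

The synthetic-data module (`simlib`) emulates a saturating transposon
mutagenesis screen under phage selection.

**Genome.** The chromosome is laid out as alternating intergenic and gene
blocks: `n_genes` genes of fixed length `gene_length_bp`, separated (and
flanked) by intergenic spacers of `intergenic_length_bp`, with uniform random
bases. The first `ceil(n_genes × essential_fraction)` genes are flagged
essential. The layout is deliberately regular — gene length variation adds
nothing to the logic being assayed — and the genome is treated as circular for
read generation so that junctions near the origin produce no edge artifacts.

**Library.** Each base hosts an insertion with probability
1/`insertion_density_bp`, so the number of sites is Binomial(L, 1/d) with mean
L/d (Poisson to excellent approximation), matching a library density of one
insertion per d bp. Each insertion gets a uniform random orientation; the two
orientations at one coordinate are distinct mutants. Insertions landing in
essential genes are **rejected** at construction — the mutant is never
recovered — rather than zeroed afterwards; essential genes therefore end the
pipeline as unassayable (< `min_reads` control reads) exactly as they would in
a real library. Note the realised genome-wide density is slightly sparser than
nominal (≈ 47.7 bp/UIS at d = 47 with 5% essential genes) because essential
territory contributes length but no sites.

**Selection.** A gene's mutants have relative fitness w (w = 1 neutral, w > 1
susceptibility, w < 1 resistance; intergenic insertions grow at `default_w`).
One selection multiplies each insertion's abundance by w^t, where t =
`generations` is the effective number of growth cycles, then renormalises to
total 1. The step is deterministic; all sampling noise enters at read
generation. A gene's expected read-share log2 fold change is t·log2(w) minus a
common compression term log2(Σ shares·w^t) from renormalisation; with many
strong expanders this compression is material (≈ 1.1 log2 units in the default
benchmark) and is a property of real competitive selections too, not an
artifact.

Dose and exposure time both act on kill-off through the same mechanism, so the
four replicates of a two-dose × two-time-point design are modelled as four
values of `generations`. The default benchmark holds the four equal (t = 4) so
each replicate has per-gene effect |t·log2 w| = 4; replicates then differ only
by multinomial sampling noise, the weakest (most conservative) form of
replication for a consensus-by-intersection rule.

**Reads.** `depth_per_sample` reads are drawn multinomially over insertions by
abundance. A read is the transposon tag (default: the 10 terminal bases of the
Tn5 mosaic end) followed by the genomic bases downstream of the junction in
the insertion's orientation, 50 bp total. Base qualities are constant and no
sequencing-error model is applied: the assayed logic is counting, and errors
would only dilute mapped fractions without exercising any additional code
path. FASTQ output is deterministic byte-for-byte given the configuration and
seed.

## Read processing

Tag recognition is exact Hamming matching of the read prefix against the tag,
with `max_mismatches` defaulting to 0 (no tolerance is needed for error-free
synthetic reads; real data can relax it). Mapping is exact-match lookup of the
trimmed read in a k-mer table over both strands of the (circular) reference,
k = trimmed length — not a reimplementation of a general-purpose aligner.
Synthetic reads are error-free, so exact lookup is lossless; real, already
mapped data enter through SAM or BED ingestion instead. Reads whose k-mer
occurs at more than one (position, strand) are discarded as ambiguous rather
than randomly placed, preventing phantom insertion sites.

The insertion coordinate is the first genomic base after the transposon
junction in the forward reference frame; for a reverse-strand read this is the
last reference base of its match. Same-coordinate opposite-strand sites count
as two unique insertion sites (UIS). Every sample satisfies the exact
partition total = rejected + unmapped + ambiguous + mapped.

## Gene counting and assayability

A site (p, s) belongs to gene g iff start_g ≤ p < end_g (0-based half-open;
GFF3's 1-based inclusive coordinates are converted at the I/O boundary).
Assignment ignores both read strand and gene strand — an insertion disrupts a
gene regardless of orientation. Sites outside all genes accumulate in an
intergenic bucket so counts are conserved exactly. Full gene spans are
counted; no 3′-end trimming is applied (a gene-span option would be a
straightforward extension, but the default keeps the counting rule minimal).

Genes with fewer than 10 reads in the pooled unselected control are flagged
unassayable and excluded from testing (inclusive at exactly 10). In a
saturating library this captures essential genes: the chance that a
non-essential gene of length L is insertion-free is exp(−L/d) (Poisson zero
class), below 3 × 10⁻⁶ for a typical 600-bp gene at d = 47, and the exact
finite-N form (1 − L/G)^N agrees with the Poisson form to < 1% whenever
N ≥ 1000 and L ≪ G.

## Statistics

**logFC** uses counts per million with a symmetric pseudocount of 0.5 CPM on
both sides, keeping the statistic finite at zero counts and antisymmetric
under swapping samples. For CPM ≥ 100 the pseudocount perturbs logFC by
< 0.01.

**p-values** come from an exact conditional binomial test. Conditioning on a
gene's total count across the two samples removes the nuisance scale, and the
null puts the selected count at Binomial(n, π) with π the selected library's
share of the summed library sizes. Two-sided tails use the minimum-likelihood
rule — sum all outcomes with pmf ≤ pmf(observed) — with ties admitted at
relative tolerance 1e-12. This is a deliberate, fully specified choice: count
screens are often analysed with moderated-dispersion GLMs, but with a single
library per condition per contrast there is no replicate dispersion to
estimate, and the exact test is transparent and oracle-checkable (the test
suite verifies it against exhaustive rational enumeration for all totals
n ≤ 12 and against an independent implementation at larger n).

**q-values** are Benjamini–Hochberg step-up, computed via
`statsmodels.stats.multitest` and verified in tests against a brute-force
implementation of the step-up definition.

**Cutoffs and consensus.** A contrast calls a gene susceptibility when
logFC ≥ 2, resistance when logFC ≤ −2, each requiring p < 0.05 and q < 0.01;
|logFC| is inclusive at the boundary, p and q strict. The consensus requires
the same non-none class in **all four** replicates — sign consistency is
demanded explicitly, since averaging opposite signs is meaningless — and
reports the arithmetic mean of the four logFC values (algebraically identical
to averaging per-dose means for four replicates). Significance filters apply
per comparison, before intersection, so each replicate implicates a gene
independently.

## Phenotyping

Plaque-assay outcomes are ordinal: 0 (full resistance, '−'), 1 (partial
lysis, '(+)'), 2 (full lysis, '+'), graded from a spot-dilution series
(2 = cleared through the reference depth, 0 = no clearing, 1 otherwise), with
the dilution depth available as a refinement. A knockout of a called
resistance gene is predicted to show increased lysis; a susceptibility-gene
knockout decreased lysis. Per phage the knockout-vs-wild-type change is
increased/decreased/no_change, and phages where the wild type already sits at
the relevant end of the scale (fully lytic for a predicted increase, fully
resistant for a predicted decrease) are scored unobservable and excluded from
the agreement denominator. The three-level scale is canonical because plate
photographs resolve direction and completeness of lysis, not a continuum.

## Benchmark scenario and problem sizes

The default `ScreenScenario` is the package's standard benchmark: 200 genes of
600 bp with 150-bp spacers (≈ 150 kb), 5% essential, density 47 bp/UIS
(≈ 3,200 insertions), 20 susceptibility genes at w = 2 and 10 resistance genes
at w = 0.5 chosen uniformly among non-essential genes, four equal replicates
at t = 4, and 2 × 10⁵ reads per sample. These sizes give per-gene control
depths of ~800 reads, ample for the ±2 cutoffs, and a full simulate-analyse
cycle completes in under a second, so the test suite and the acceptance script
average over 20 independent screens. The acceptance script reports sensitivity
and precision of consensus calls under this scenario, and the zero-call
fraction of the corresponding all-neutral null.

## What the simulation does and does not show

Passing tests demonstrate that the pipeline's counting, statistics, and
consensus logic recover planted effects and control false calls under
multinomial sampling noise. The generator does not model sequencing errors,
PCR duplicates, GC or AT insertion bias, adsorption kinetics, lysogeny, or
between-culture biological variability; real screens add those noise sources,
so sensitivity/precision here are upper bounds on field performance, not
predictions of it. Reproducing any particular real screen's gene lists is out
of scope.

## Numerical and degenerate-input choices

- All randomness flows from one integer seed through separate named streams
  (genome / library / reads / effect-gene assignment), so regenerating one
  stage never perturbs another; identical seeds give byte-identical FASTQ.
- `n_genes = 0` yields a single intergenic block; an all-essential genome
  yields an empty library; read generation from an empty library, selection
  that zeroes all abundance, and zero library sizes raise errors rather than
  propagating NaN.
- Extreme counts can underflow the binomial pmf to 0.0; the returned p-value
  is then 0.0, which only ever strengthens an already-astronomical call.
- Ambiguous-mapping and tag-rejection tallies are carried through the
  insertion profile so the read partition can be asserted exactly.
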