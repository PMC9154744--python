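# Methods

This note documents the models, conventions and design choices behind
the package, in the spirit of a methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and strand conventions

All internal coordinates are 0-based half-open on the forward genomic
strand; GFF3 (1-based inclusive) and BED/bedGraph (0-based half-open)
are converted at the I/O boundary. A transcription unit carries its
strand, so TSS and poly(A) positions are derived, and all windows
("upstream", "downstream") are strand-aware.

NET-seq reads the 3' end of the nascent RNA: the 5'-most aligned base
of the sequencing read is recorded as one count. Under the default
`fr-firststrand` library orientation the read aligns antisense to the
nascent RNA, so the transcript strand is the opposite of the alignment
strand; `fr-secondstrand` is available because protocols vary.

RT mispriming produces reads whose hexamer molecular barcode equals the
genomic sequence adjacent to the recorded 3' end. "Adjacent" is taken
on the transcript-downstream side of the 3' end (the side an internal
RT priming event is forced to copy), read in the transcript
orientation; minus-strand loci are reverse-complemented accordingly.
Reads whose comparison window runs off the chromosome are retained and
flagged rather than guessed at.

PCR duplicates are deliberately **not** removed: deduplication of
single-nucleotide count data distorts the very pileups the pause caller
needs, and duplicate-tolerant counting is the convention this assay
family uses.

## Pause calling

A gene is eligible when its mean coverage strictly exceeds 2 reads/bp
in both replicates. Within an eligible gene, position *i* is a pause
when its count exceeds mu + 3·sigma of the local background **and** is
at least 2 reads. The background is the surrounding 200 nt (±100,
truncated at gene bounds, candidate excluded), restricted to positions
not currently called as pauses, fit by a method-of-moments negative
binomial: mu = sample mean, sigma² = sample variance (ddof = 1),
r = mu²/(var − mu); when var ≤ mu the fit falls back to Poisson
(sigma = √mu); an all-zero window degenerates to mu = sigma = 0 so the
threshold reduces to the 2-read floor. Method-of-moments was chosen
over maximum likelihood because it is closed-form and deterministic,
and a 3-sigma cut is insensitive to the difference.

Because the background definition excludes pauses, calling iterates:
call with an empty exclusion set, refit excluding the calls, repeat
until the call set is a fixed point (cap 10 iterations; genes hitting
the cap keep the last iterate and are flagged). A sliding per-position
window is used rather than disjoint 200-nt segments. Windows with
fewer than 50 informative positions produce no call — moments on fewer
points are too unstable. The caller runs on raw per-replicate tracks
since the IDR stage consumes per-replicate pause strengths.

A consequence worth stating: a 3-sigma rule on NB-distributed counts
has an irreducible per-position false-call tail of roughly half a
percent, so per-replicate call sets are expected to contain calls every
~30–40 bp in well-covered genes. This matches the call density the
assay literature reports and is precisely why the replicate/IDR stage
exists: coincident false calls require the same position in both
replicates and are two to three orders of magnitude rarer.

## IDR

Matched pairs (exact chromosome/position/strand identity — these are
single-nucleotide events, so no positional slop is allowed) are scored
by log10 read count. The reproducibility model is the Gaussian-copula
two-component mixture of Li, Brown, Huang & Bickel (2011): ranks
(average ranks for ties, which are common for log counts of small
integers) are mapped through the inverse mixture marginal CDF to
pseudo-values, and EM alternates pseudo-value refresh, posterior
computation, and weighted-moment updates of (mu, sigma, rho, p) from
the standard initialization mu=3, sigma=1, rho=0.9, p=0.5, until the
pseudo-log-likelihood changes by less than 1e-6 (cap 200 iterations;
the last iterate is returned with a flag if the cap is hit — with a
rank-based pseudo-likelihood the objective can keep drifting at the
1e-6 level without affecting any pair's idr materially).

The local idr of a pair is the posterior probability of the
irreproducible component. The global IDR is the running mean of local
idr over pairs ranked by increasing local idr (the ENCODE convention);
tied local values share the value at the end of their tie block so
equal evidence maps to equal global IDR, keeping the quantity monotone
along the ranking. The 1% threshold is applied to the global IDR
(`use_local=True` switches to local). Because the model sees only
ranks, any strictly monotone transform of the scores leaves every idr
unchanged — a property the tests assert to 1e-10.

## Region indices, metagenes, splicing

The pausing index windows are TSS (−50, +150), poly(A) (±100), and
splice sites (±10), inclusive of both endpoints. The "remainder of the
gene" is the set of gene-body positions not inside the window; window
positions outside the annotated gene (e.g. upstream of the TSS)
contribute to the numerator only. PI is therefore scale-invariant,
equal to 1 under uniform coverage, and undefined (flagged, never zero)
when the remainder carries no signal. The antisense pausing index
anchors a TSS-style (−50, +150) window at the antisense-unit start
opposite the host gene's poly(A) region — the exact anchoring is a
package choice, exposed as a parameter.

Metagene profiles use non-overlapping genes only, windows of −100/+600
around the TSS, −500/+200 around poly(A) sites and ±25 around splice
sites, per-gene normalization to unit sum (`--norm max` alternative),
the across-gene mean per offset, loess smoothing with span 0.01 (never
fewer than 3 points), and a normal-approximation 95% CI.

The splicing index is SI = 2·spliced/(unspliced5' + unspliced3') per
intron, undefined when the denominator is zero (excluded from paired
comparisons with a tally). Two samples are compared with a Wilcoxon
signed-rank test paired by intron — chosen over a paired t-test because
SI is a ratio with heavy right tails.

## Antisense transcription

Each gene yields a mirror "anti<gene>" unit on the opposite strand;
units overlapping any sense unit on their own strand, by any number of
base pairs, are dropped. Position matrices cover −250…+4000 relative
to the sense TSS (4251 columns), values are per-position RPKM on the
antisense strand with a pseudocount of 1 added **before** the log2;
offsets beyond the annotated unit or the chromosome are missing, never
zero-filled. Differential matrices are element-wise
log2((mut+1)/(wt+1)) on linear RPKM, antisymmetric by construction.

## Pause features and classification

Control loci are drawn uniformly from the non-pause positions of each
gene, count-matched per gene — this conditions the null on gene
identity and hence on expression. Features: center trinucleotide,
per-position base identities over ±10 nt (one-hot encoded for the
model), nearest-neighbor duplex melting temperature of the 21-mer
(Biopython's thermodynamic tables), DNA-shape values averaged over the
pentamers covering the locus from a user-supplied lookup table (shape
tables are published data, not something this package recomputes),
mean signal of arbitrary tracks in configurable windows, relative
position in gene, and distances to TSS, poly(A) site and nearest
nucleosome dyad. Loci within half a window of a chromosome end keep
their row with missing features and an edge flag. Real-vs-control
distributional tests are two-sample t-tests with Bonferroni correction
over the tested (numeric, non-degenerate) features; categorical
sequence features are reported as skipped.

The forest uses 2500 trees and 20 features per split at full scale.
The legacy setting "ncat = 4" from the original R implementation is not
a scikit-learn concept; it is interpreted as the largest category
cardinality kept categorical, which after one-hot encoding of
four-letter sequence columns is a no-op, and is documented rather than
emulated. The 75/25 split is stratified by gene (all loci of a gene on
one side) — stricter than label stratification, preventing gene-level
leakage. Permutation importance follows the out-of-bag definition:
per tree, accuracy on that tree's out-of-bag samples is compared
before and after permuting one feature column, and the drop is averaged
over trees. The transfer matrix trains on 100% of one strain's loci
and tests on another's; diagonal cells are each strain's own 75/25
evaluation.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale:

- **Genome**: 2 chromosomes, i.i.d. nucleotides at GC 0.38 (AT-rich,
  yeast-like). Chromosomes are auto-sized to the gene budget with a
  150 kb floor; a fixed chromosome length raises a sizing error when
  the budget overflows.
- **Genes**: 200 units of 0.8–3 kb on both strands with 200 bp gaps;
  30% carry one 80–300 bp intron. The intron fraction is enriched
  over a real yeast genome (~5%) so splicing analyses have usable
  numbers of introns at toy scale.
- **Background**: per-gene expression uniform on 1–12 reads/bp;
  per-position counts NB(mean = expression, size r = 10) i.i.d. per
  replicate — moderate overdispersion of the kind local NB fits are
  meant to absorb.
- **Pauses**: planted uniformly at 30 per kb — chosen to reproduce the
  wild-type call regime the assay shows (about one call per 33 bp of
  well-expressed gene). Pause signal is a Poisson draw with mean
  expression × strength **added** to the background draw (multiplying
  the background draw itself would erase pauses wherever the background
  sampled zero); strengths are uniform 2–12 fold. 35% of pauses are
  reproducible: present in both replicates with strengths sharing a
  latent value times i.i.d. log-normal noise (sd 0.25 in log space),
  which produces the rank-correlated structure the IDR model assumes.
  The remainder appear in one replicate only.
- **Antisense**: half the genes carry an independent NB track at 15%
  of host expression on the opposite strand over their 3'-terminal
  half, mirroring the 3'-origin antisense pattern.
- **Junctions**: per intron, multinomial (spliced, unspliced5',
  unspliced3') counts with spliced proportion psi and the unspliced
  mass split evenly.
- **Mispriming**: simulated reads carry hexamer barcodes; a configured
  fraction are misprimed (barcode equals the transcript-downstream
  genomic hexamer), the rest random — chance collisions (4⁻⁶) are left
  in, as in real data.

What the generator does **not** emulate: sequence-dependent pause
preference (planted positions are uniform, so sequence features carry
no signal on synthetic data), reads spanning positions (each read is a
single 3'-end count), mappability structure, PCR duplication, and
library-specific biases. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery, not that
real yeast pauses are recoverable at these rates.

## Problem sizes and determinism

Tests and the acceptance script run at the generator's default scale
(200 genes, ~0.4 Mb of gene body, ~3M reads per replicate), which keeps
any single stage under a few seconds and the full suite at roughly a
minute; recovery and power statements aggregate 8–100 seeds as noted
per check. Every stochastic step takes an explicit seed; generators
derive per-stage streams from the config seed, so identical configs
give byte-identical outputs.

## Known limitations

- The iterative pause-exclusion fixed point is not guaranteed to be
  unique; the iteration from an empty exclusion set is the defined
  behavior, and the naive-oracle equivalence test pins it.
- The EM for the copula mixture can sit at its iteration cap with
  log-likelihood drift at the tolerance level; idr values are stable
  to well below the acceptance tolerance, and the convergence flag is
  reported.
- On matched pause sets that are nearly pure reproducible pairs the
  mixing proportion p is weakly identified; the global-IDR threshold
  then behaves conservatively (it can drop a tail of weak but genuine
  pairs), which shows up as a few-point downward bias in the surviving
  fraction.
- Gene-stratified splitting makes the held-out AUC slightly
  pessimistic relative to a per-locus split when gene-level covariates
  carry signal; this is intentional.
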