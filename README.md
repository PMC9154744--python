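# netseq

Analysis toolkit for NET-seq (native elongating transcript sequencing)
data: strand-specific, single-nucleotide RNA polymerase II occupancy in
budding yeast and similar compact genomes. The package implements the
full quantitative pipeline downstream of alignment — 3'-end recording,
RT-mispriming removal, replicate handling, single-nucleotide pause
calling, IDR reproducibility filtering, region pausing indices,
metagene profiles, splicing indices, antisense quantification, and
feature-based random-forest classification of pause sites — together
with a synthetic-data generator that provides ground truth for every
stage, so the whole analysis runs and is tested without any external
download.

It is written for computational biologists who work with nascent
transcription data (NET-seq, PRO-seq and relatives) and want a tested,
scriptable implementation of these analyses rather than a collection of
one-off notebooks.

## The statistics at the core

**Pause calling.** A position *i* in a well-expressed gene (mean
coverage > 2 reads/bp in both replicates) is a pause when its read
count *x<sub>i</sub>* satisfies

    x_i > mu + 3*sigma   and   x_i >= 2

where mu and sigma come from a negative-binomial fit (method of
moments; Poisson fallback when the sample variance does not exceed the
mean) to the surrounding 200 nucleotides that do not themselves contain
pauses. Since the background must exclude pauses, calling iterates to
a fixed point: call, refit excluding calls, repeat.

**Reproducibility.** Pauses called in both replicates at the same
coordinate are scored by log10 read count and passed to the
Gaussian-copula two-component mixture model of Li et al. (2011): an EM
fit from (mu=3, sigma=1, rho=0.9, p=0.5) yields each pair's posterior
probability of belonging to the irreproducible component (local idr);
the global IDR is the running mean of local idr down the ranked list.
Pairs with IDR < 1% form the reproducible pause set.

**Pausing index.** For a region anchored at the TSS (-50, +150 bp),
poly(A) site (±100 bp) or splice sites (±10 bp),

    PI = (region reads / region length) / (remainder reads / remainder length)

with the remainder being the gene-body positions outside the region.

**Splicing index.** Per intron, SI = 2·spliced / (unspliced5' +
unspliced3'), compared across samples with a paired Wilcoxon test.

**Classification.** Reproducible pauses and per-gene count-matched
shuffled control loci get per-locus features (trinucleotide and flank
sequence, duplex melting temperature, pentamer DNA-shape lookups,
signal-track windows, positional features); a random forest (2500
trees, 20 features per split, 75/25 gene-stratified split) reports
held-out AUC, out-of-bag permutation importance, and a cross-strain
transfer-of-learning AUC matrix.

## Worked example

```python
from netseq.simulate import SimulationConfig, generate_toy_genome, simulate_occupancy
from netseq.pause_calling import select_well_expressed, call_pauses
from netseq.idr import match_pauses, assign_idr, reproducible_pauses

cfg = SimulationConfig(seed=1)          # 200 genes, NB background,
genome, ann = generate_toy_genome(cfg)  # planted pauses, 2 replicates
rep1, rep2, truth = simulate_occupancy(ann, cfg)

filt = select_well_expressed(rep1, rep2, ann)
calls1 = call_pauses(rep1, ann, filt)
calls2 = call_pauses(rep2, ann, filt)
pairs, params = assign_idr(match_pauses(calls1, calls2))
kept = reproducible_pauses(pairs, threshold=0.01)
print(len(calls1), len(calls2), len(kept))
```

prints

```
11075 10916 3731
```

— about one call every 32 bp of well-expressed gene in each replicate,
of which 34% survive the 1% IDR filter (the planted reproducible
fraction is 35%; the remainder of the initial calls are
single-replicate pauses and the unavoidable tail of the 3-sigma
criterion).

The same workflow as a sequence of narrative scripts lives under
`analysis/` (`01_simulate.py` … `08_classify.py`); each writes its
tables under `results/` and its bulky intermediates (tracks, BED files)
under `scratch/`. A one-call end-to-end demonstration is
`netseq.pipeline.run_demo(seed=0, outdir="demo_out")`.

## Scope

Upstream read processing (adapter trimming, quality filtering,
alignment) is out of scope: the pipeline starts from aligned reads
(BAM/SAM) or strand-split per-nucleotide bedGraph tracks. Differential
expression is consumed or exported (count tables), not computed; motif
discovery is supported only by exporting pause-flank FASTA for external
tools.
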