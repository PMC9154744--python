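"""Synthetic NET-seq-like data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: strand-specific per-nucleotide 3'-end counts with a
negative-binomial background, planted stereotypical pause sites whose
strengths are rank-correlated between two replicates plus irreproducible
one-replicate pauses, antisense transcription units over the 3'-terminal
half of host genes, exon-junction read counts, and read records carrying
hexamer molecular barcodes including deliberate RT-mispriming artifacts.

Defaults emulate a budding-yeast-like wild-type regime: AT-rich genome
(GC 0.38), gene bodies of 0.8-3 kb, expression of a few reads per base
pair, a high density of modest stereotypical pauses of which roughly a
third are shared between replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotationSet
from .genome import GenomeSequence, chrom_lengths as genome_lengths
from .occupancy import (OccupancyTrack, adjacent_hexamer, BARCODE_LENGTH,
                        make_reads)

NUCLEOTIDES = np.array(list("ACGT"))

#: standard deviation of the log-normal replicate noise applied to the
#: shared latent strength of reproducible planted pauses
REPLICATE_LOG_SD = 0.25

#: antisense units transcribe at this fraction of their host gene's level
ANTISENSE_EXPRESSION_RATIO = 0.15


class SizingError(ValueError):
    """Gene budget does not fit on the configured chromosomes."""


@dataclass
class SimulationConfig:
    """Parameters of the toy genome and occupancy simulation.

    ``nb_dispersion`` is the negative-binomial size parameter r of the
    background counts (variance = mean + mean^2 / r).  ``pause_rate`` is
    planted pauses per kb of gene body; ``pause_strength_range`` is the
    fold-over-background range of planted pause strengths.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (800, 3000)
    intergenic_gap: int = 200
    intron_fraction: float = 0.3
    expression_mean_range: tuple[float, float] = (1.0, 12.0)
    nb_dispersion: float = 10.0
    pause_rate: float = 30.0
    pause_strength_range: tuple[float, float] = (2.0, 12.0)
    reproducible_fraction: float = 0.35
    antisense_fraction: float = 0.5
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int | None = None  # None: auto-size (>= 150 kb)
    gc_content: float = 0.38

    def __post_init__(self) -> None:
        for name in ("intron_fraction", "reproducible_fraction",
                     "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gene_length_range[0] < 600:
            raise ValueError("minimum gene length must be >= 600 bp "
                             "(largest index window)")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (min, max)")
        if self.pause_rate < 0:
            raise ValueError("pause_rate must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), stage])


# ------------------------------------------------------------------ genome

def generate_toy_genome(config: SimulationConfig,
                        ) -> tuple[GenomeSequence, GeneAnnotationSet]:
    """Toy genome with i.i.d. nucleotides and non-overlapping genes.

    Genes are laid out sequentially on both strands with a fixed
    intergenic gap; ``intron_fraction`` of genes carry one intron.
    Chromosomes are auto-sized to the gene budget (at least 150 kb each)
    unless ``chromosome_length`` is fixed, in which case an overful
    budget raises :class:`SizingError`.
    """
    rng = _rng(config, 0)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    has_intron = rng.random(config.n_genes) < config.intron_fraction

    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    genes: list[Gene] = []
    chrom_sizes: dict[str, int] = {}
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = config.intergenic_gap
        for _ in range(min(per_chrom, config.n_genes - idx)):
            L = int(lengths[idx])
            g_intron = None
            if has_intron[idx]:
                i_len = int(rng.integers(80, 301))
                i_start = int(rng.integers(1, L - i_len - 1))
                g_intron = (cursor + i_start, cursor + i_start + i_len)
            genes.append(Gene(gene_id=f"g{idx:04d}", chrom=chrom,
                              start=cursor, end=cursor + L,
                              strand=str(strands[idx]), intron=g_intron))
            cursor += L + config.intergenic_gap
            idx += 1
        needed = cursor
        if config.chromosome_length is None:
            chrom_sizes[chrom] = max(needed, 150_000)
        else:
            if needed > config.chromosome_length:
                raise SizingError(
                    f"{chrom}: gene budget needs {needed} bp but "
                    f"chromosome_length is {config.chromosome_length}")
            chrom_sizes[chrom] = config.chromosome_length

    p_gc = config.gc_content / 2.0
    probs = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]  # A, C, G, T
    genome = {chrom: "".join(rng.choice(NUCLEOTIDES, size=size, p=probs))
              for chrom, size in chrom_sizes.items()}
    return genome, GeneAnnotationSet(genes, chrom_sizes)


# --------------------------------------------------------------- occupancy

TRUTH_COLUMNS = ["chrom", "position", "strand", "gene_id",
                 "planted_strength", "reproducible", "replicate",
                 "gene_expression"]


def simulate_occupancy(annotation: GeneAnnotationSet,
                       config: SimulationConfig,
                       ) -> tuple[OccupancyTrack, OccupancyTrack,
                                  pd.DataFrame]:
    """Two replicate occupancy tracks plus the planted-pause truth table.

    Per-gene background counts are NB(mean = gene expression, size =
    ``nb_dispersion``) i.i.d. per position and replicate.  Planted pause
    positions are uniform within genes at ``pause_rate`` per kb; the
    pause signal is a Poisson draw with mean expression x strength added
    on top of the background, so the expected count at a pause is the
    background mean multiplied by (1 + strength).  A
    ``reproducible_fraction`` of planted pauses appears in both
    replicates with rank-correlated strengths (shared latent strength
    plus i.i.d. log-normal replicate noise); the rest appear in one
    replicate only.
    """
    rng = _rng(config, 1)
    r = config.nb_dispersion
    tracks = [OccupancyTrack(annotation.chrom_lengths) for _ in range(2)]
    truth_rows: list[tuple] = []
    antisense_hosts: list[str] = []

    e_lo, e_hi = config.expression_mean_range
    for g in annotation:
        expr = float(rng.uniform(e_lo, e_hi))
        for t in tracks:
            bg = rng.negative_binomial(r, r / (r + expr), size=g.length)
            arr = t.get(g.chrom, g.strand)
            arr[g.start:g.end] += bg

        n_pauses = rng.poisson(config.pause_rate * g.length / 1000.0)
        n_pauses = min(n_pauses, g.length)
        if n_pauses:
            positions = rng.choice(g.length, size=n_pauses, replace=False)
            strengths = rng.uniform(*config.pause_strength_range,
                                    size=n_pauses)
            repro = rng.random(n_pauses) < config.reproducible_fraction
            which_rep = rng.integers(1, 3, size=n_pauses)  # for irreproducible
            for pos_off, S, is_rep, one_rep in zip(
                    positions, strengths, repro, which_rep):
                pos = g.start + int(pos_off)
                reps = (0, 1) if is_rep else (int(one_rep) - 1,)
                for rep_idx in reps:
                    s_rep = S * float(np.exp(
                        rng.normal(0.0, REPLICATE_LOG_SD)))
                    signal = rng.poisson(expr * s_rep)
                    tracks[rep_idx].get(g.chrom, g.strand)[pos] += signal
                truth_rows.append((g.chrom, pos, g.strand, g.gene_id,
                                   float(S), bool(is_rep),
                                   0 if is_rep else int(one_rep), expr))

        if rng.random() < config.antisense_fraction:
            antisense_hosts.append(g.gene_id)
            a_expr = expr * ANTISENSE_EXPRESSION_RATIO
            # antisense transcription over the 3'-terminal half of the host
            half = g.length // 2
            if g.strand == "+":
                a_start, a_end = g.start + half, g.end
            else:
                a_start, a_end = g.start, g.end - half
            a_strand = "-" if g.strand == "+" else "+"
            for t in tracks:
                bg = rng.negative_binomial(
                    r, r / (r + a_expr), size=a_end - a_start)
                t.get(g.chrom, a_strand)[a_start:a_end] += bg

    for t in tracks:
        t.library_size = t.total()
        t.meta["antisense_hosts"] = list(antisense_hosts)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if len(truth):
        dup = truth.duplicated(["chrom", "position", "strand"])
        truth = truth.loc[~dup].reset_index(drop=True)
    return tracks[0], tracks[1], truth


# ---------------------------------------------------------------- splicing

def simulate_junction_counts(annotation: GeneAnnotationSet, psi,
                             depth: int, seed: int) -> pd.DataFrame:
    """Multinomial junction-read counts per intron.

    ``psi`` (scalar or mapping gene_id -> proportion) is the spliced
    proportion; unspliced reads split evenly between the 5' and 3'
    splice sites.
    """
    introns = annotation.introns
    if not introns:
        raise ValueError("annotation has no introns")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    rows = []
    for g in introns:
        p = float(psi[g.gene_id]) if hasattr(psi, "__getitem__") \
            and not np.isscalar(psi) else float(psi)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"psi must be in [0, 1], got {p}")
        spliced, u5, u3 = rng.multinomial(
            depth, [p, (1 - p) / 2, (1 - p) / 2])
        rows.append((f"{g.gene_id}.i1", g.gene_id, int(spliced),
                     int(u5), int(u3)))
    return pd.DataFrame(rows, columns=["intron_id", "gene_id", "spliced",
                                       "unspliced5", "unspliced3"])


# -------------------------------------------------------------- mispriming

def simulate_misprimed_reads(genome: GenomeSequence,
                             annotation: GeneAnnotationSet,
                             misprime_fraction: float, seed: int,
                             n_reads: int = 10_000,
                             read_length: int = 30) -> pd.DataFrame:
    """Read records with hexamer barcodes, a fraction misprimed.

    Misprimed reads carry a barcode equal to the six genomic bases
    immediately transcript-downstream of the recorded 3' end; other
    barcodes are random hexamers (chance collisions with the genomic
    sequence are left in, matching real-data behavior).
    """
    if not 0.0 <= misprime_fraction <= 1.0:
        raise ValueError("misprime_fraction must be in [0, 1]")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    lengths = genome_lengths(genome)
    genes = annotation.genes
    gene_idx = rng.integers(0, len(genes), size=n_reads)
    misprimed = rng.random(n_reads) < misprime_fraction
    rows = []
    for i in range(n_reads):
        g = genes[int(gene_idx[i])]
        pos = g.start + int(rng.integers(0, g.length))
        if g.strand == "+":
            aln_strand = "-"
            end = pos + 1
            start = max(0, end - read_length)
        else:
            aln_strand = "+"
            start = pos
            end = min(lengths[g.chrom], start + read_length)
        hexamer = adjacent_hexamer(genome, g.chrom, pos, g.strand)
        if misprimed[i] and hexamer is not None:
            barcode = hexamer
        else:
            barcode = "".join(rng.choice(NUCLEOTIDES, size=BARCODE_LENGTH))
        rows.append((g.chrom, start, end, aln_strand, barcode))
    return make_reads(rows)


# ---------------------------------------------------------------- recovery

def recovery_stats(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame,
                   truth: pd.DataFrame, min_strength: float = 8.0,
                   min_expression: float = 3.0) -> dict:
    """Sensitivity and false-discovery proportion of replicate-matched calls.

    A prediction is the exact-coordinate intersection of the two
    per-replicate call sets.  Sensitivity is measured over planted
    reproducible pauses with strength >= ``min_strength`` in genes with
    background expression >= ``min_expression`` reads/bp; a predicted
    site counts as a false discovery when it is at no planted position.
    """
    key = ["chrom", "position", "strand"]
    k1 = set(map(tuple, calls_rep1[key].itertuples(index=False)))
    k2 = set(map(tuple, calls_rep2[key].itertuples(index=False)))
    predicted = k1 & k2
    planted = set(map(tuple, truth[key].itertuples(index=False)))
    target = truth[(truth["reproducible"])
                   & (truth["planted_strength"] >= min_strength)
                   & (truth["gene_expression"] >= min_expression)]
    target_keys = set(map(tuple, target[key].itertuples(index=False)))
    tp = len(predicted & target_keys)
    fp = len(predicted - planted)
    sensitivity = tp / len(target_keys) if target_keys else float("nan")
    fdp = fp / len(predicted) if predicted else 0.0
    return {"sensitivity": sensitivity, "fdp": fdp,
            "n_target": len(target_keys), "n_predicted": len(predicted),
            "n_false": fp}
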