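"""Antisense transcription units and quantification.

Each protein-coding transcription unit gets a mirror "antiXXXX" unit
with identical coordinates on the opposite strand; antisense units that
overlap any annotated sense unit on their own strand (any overlap, any
extent) are dropped.  Antisense signal is summarized as position
matrices over a fixed window from 250 bp upstream to 4000 bp downstream
of the sense TSS, on a log2(RPKM + 1) scale with the pseudocount added
before the log; differential matrices are element-wise
log2((mutant + 1) / (wild-type + 1)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .annotation import Gene, GeneAnnotationSet
from .occupancy import OccupancyTrack

ANTISENSE_WINDOW = (-250, 4000)  # offsets relative to the sense TSS

#: a single-position RPKM from a per-million track: reads per million
#: over a 1-bp (0.001 kb) feature
PER_POSITION_RPKM_SCALE = 1000.0


def build_antisense_annotation(annotation: GeneAnnotationSet,
                               ) -> tuple[GeneAnnotationSet, list[str]]:
    """One antisense unit per gene, minus those overlapping a sense unit
    on the antisense unit's own strand.  Returns (units, removed ids)."""
    units: list[Gene] = []
    removed: list[str] = []
    for g in annotation:
        anti = g.antisense_unit()
        clash = any(
            s.chrom == anti.chrom and s.strand == anti.strand
            and s.start < anti.end and anti.start < s.end
            for s in annotation
        )
        if clash:
            removed.append(anti.gene_id)
        else:
            units.append(anti)
    return GeneAnnotationSet(units, annotation.chrom_lengths), removed


def antisense_position_matrix(track: OccupancyTrack,
                              annotation: GeneAnnotationSet,
                              window: tuple[int, int] = ANTISENSE_WINDOW,
                              log: bool = True) -> pd.DataFrame:
    """Genes x offsets matrix of antisense-strand signal.

    ``track`` must be per-million normalized; values are per-position
    RPKM on the strand opposite each gene, at offsets relative to the
    sense TSS (positive offsets run downstream of the sense gene).
    Offsets past the annotated gene end or off the chromosome are
    missing (NaN).  With ``log=True`` values are log2(RPKM + 1).
    """
    if not track.normalized:
        raise ValueError("antisense matrices require a normalized track")
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    rows = {}
    for g in annotation:
        anti_strand = "-" if g.strand == "+" else "+"
        arr = track.get(g.chrom, anti_strand)
        if g.strand == "+":
            genomic = g.tss + offsets
        else:
            genomic = g.tss - offsets
        valid = (genomic >= 0) & (genomic < arr.size)
        # mask offsets beyond the annotated unit (gene shorter than window)
        in_scope = offsets < g.length
        values = np.full(offsets.size, np.nan)
        take = valid & in_scope
        values[take] = arr[genomic[take]] * PER_POSITION_RPKM_SCALE
        rows[g.gene_id] = values
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=offsets)
    mat.index.name = "gene_id"
    if log:
        mat = np.log2(mat + 1.0)
    return mat


def differential_matrix(matrix_mutant: pd.DataFrame,
                        matrix_wt: pd.DataFrame) -> pd.DataFrame:
    """Element-wise log2((mutant + 1) / (wt + 1)) on linear RPKM
    matrices; missing values stay missing."""
    if not matrix_mutant.index.equals(matrix_wt.index):
        raise ValueError("gene rows differ between matrices")
    if not matrix_mutant.columns.equals(matrix_wt.columns):
        raise ValueError("offset columns differ between matrices")
    return np.log2((matrix_mutant + 1.0) / (matrix_wt + 1.0))


def sense_antisense_correlation(
        fold_changes: dict[str, tuple[pd.Series, pd.Series]],
        ) -> pd.DataFrame:
    """Pearson r between sense and antisense per-gene fold changes.

    ``fold_changes`` maps strain -> (sense log2FC, antisense log2FC)
    indexed by gene.  Returns one row per strain plus a pooled row over
    all strain-gene pairs.
    """
    rows = []
    pooled_s, pooled_a = [], []
    for strain, (fc_sense, fc_anti) in fold_changes.items():
        shared = fc_sense.index.intersection(fc_anti.index)
        paired = pd.DataFrame({"s": fc_sense[shared],
                               "a": fc_anti[shared]}).dropna()
        if len(paired) < 3:
            raise ValueError(f"{strain}: fewer than 3 matched pairs")
        r, p = pearsonr(paired["s"], paired["a"])
        rows.append((strain, float(r), float(p), len(paired)))
        pooled_s.append(paired["s"])
        pooled_a.append(paired["a"])
    s = pd.concat(pooled_s)
    a = pd.concat(pooled_a)
    r, p = pearsonr(s, a)
    rows.append(("pooled", float(r), float(p), len(s)))
    return pd.DataFrame(rows, columns=["strain", "pearson_r", "p_value",
                                       "n_genes"])
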