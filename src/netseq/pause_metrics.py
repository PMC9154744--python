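"""Summaries of reproducible pause sets.

Pause density normalizes the pause count to the summed length of the
well-expressed genes the caller actually examined.  The positional
distribution assigns each pause a TSS-relative fractional position in
its host gene and bins it into the first 15% of gene length (5'), the
15th-85th percentile (mid), and the final 15% ending at the poly(A)
site (3').  Scrambled controls redraw every pause uniformly within its
host gene, preserving per-gene counts exactly — the null used for
positional and feature enrichment.  The cross-strain shared-pause
matrix is tri-state: pause / no-pause / insufficient-coverage, where
coverage status comes from the per-strain expression filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneAnnotationSet

BIN_EDGES = (0.15, 0.85)


def pause_density(pauses: pd.DataFrame, considered_length: int) -> float:
    """Pauses per kb of considered (well-expressed) gene length."""
    if considered_length <= 0:
        raise ValueError("considered_length must be positive")
    return 1000.0 * len(pauses) / considered_length


def considered_length(expression_filter: pd.DataFrame,
                      annotation: GeneAnnotationSet) -> int:
    """Summed length of genes passing the expression filter."""
    passing = expression_filter.loc[expression_filter["passes"], "gene_id"]
    return int(sum(annotation[g].length for g in passing))


def relative_positions(pauses: pd.DataFrame,
                       annotation: GeneAnnotationSet) -> pd.Series:
    """TSS-relative fractional position of each pause in its host gene."""
    rel = []
    for row in pauses.itertuples(index=False):
        gene = annotation[row.gene_id]
        rel.append(gene.relative_position(row.position))
    return pd.Series(rel, index=pauses.index, name="relative_position")


def positional_distribution(pauses: pd.DataFrame,
                            annotation: GeneAnnotationSet,
                            ) -> pd.DataFrame:
    """Mean fraction of pauses per positional bin with 95% CIs over genes.

    Each gene with at least one pause contributes one fraction triple;
    the mean and a normal-approximation 95% CI are taken across genes.
    """
    rel = relative_positions(pauses, annotation)
    df = pauses.assign(rel=rel)
    lo, hi = BIN_EDGES
    rows = []
    for _gid, grp in df.groupby("gene_id", sort=False):
        n = len(grp)
        f5 = (grp["rel"] < lo).sum() / n
        f3 = (grp["rel"] >= hi).sum() / n
        rows.append((f5, 1.0 - f5 - f3, f3))
    per_gene = np.asarray(rows, dtype=float)
    mean = per_gene.mean(axis=0)
    sem = per_gene.std(axis=0, ddof=1) / np.sqrt(len(per_gene)) \
        if len(per_gene) > 1 else np.zeros(3)
    out = pd.DataFrame({
        "bin": ["five_prime", "mid", "three_prime"],
        "fraction": mean,
        "ci_lo": mean - 1.96 * sem,
        "ci_hi": mean + 1.96 * sem,
        "n_genes": len(per_gene),
    })
    return out


def scramble_pauses(pauses: pd.DataFrame, annotation: GeneAnnotationSet,
                    seed: int) -> pd.DataFrame:
    """Uniformly redraw each pause within its host gene (same strand),
    preserving per-gene pause counts; positions are deduplicated by
    resampling."""
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    rows = []
    for gid, grp in pauses.groupby("gene_id", sort=False):
        gene = annotation[gid]
        k = len(grp)
        if k > gene.length:
            raise ValueError(f"{gid}: more pauses than positions")
        offsets = rng.choice(gene.length, size=k, replace=False)
        for off in offsets:
            rows.append((gene.chrom, gene.start + int(off), gene.strand,
                         gid))
    out = pd.DataFrame(rows, columns=["chrom", "position", "strand",
                                      "gene_id"])
    return out.reset_index(drop=True)


def shared_pause_matrix(pause_sets: dict[str, pd.DataFrame],
                        expression_filters: dict[str, pd.DataFrame],
                        min_strains: int = 8) -> pd.DataFrame:
    """Tri-state locus x strain matrix of shared pauses.

    A locus enters the matrix when it is a pause in at least
    ``min_strains`` strains.  Cells are "pause", "no-pause", or
    "insufficient-coverage" (the locus's host gene failed that strain's
    expression filter); missing coverage is stored explicitly, never
    coerced to absence.
    """
    if set(pause_sets) != set(expression_filters):
        raise ValueError("strain sets differ between pauses and filters")
    loci: dict[tuple, dict] = {}
    for strain, calls in pause_sets.items():
        for row in calls.itertuples(index=False):
            key = (row.chrom, row.position, row.strand)
            loci.setdefault(key, {"gene_id": row.gene_id, "strains": set()})
            loci[key]["strains"].add(strain)
    passing = {
        strain: set(filt.loc[filt["passes"], "gene_id"])
        for strain, filt in expression_filters.items()
    }
    strains = sorted(pause_sets)
    rows, index = [], []
    for key in sorted(loci):
        info = loci[key]
        if len(info["strains"]) < min_strains:
            continue
        cells = []
        for strain in strains:
            if info["gene_id"] not in passing[strain]:
                cells.append("insufficient-coverage")
            elif strain in info["strains"]:
                cells.append("pause")
            else:
                cells.append("no-pause")
        rows.append(cells)
        index.append("{}:{}:{}".format(*key))
    return pd.DataFrame(rows, index=index, columns=strains)
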