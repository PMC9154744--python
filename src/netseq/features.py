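"""Per-locus features around pause sites and matched shuffled controls.

For every reproducible pause (and a per-gene count-matched shuffled
control locus, controlling for differential gene expression) the module
assembles a feature vector: the trinucleotide centered on the locus,
per-position base identities over a +/-10 nt flank, nearest-neighbor
duplex melting temperature of the flank, DNA-shape values averaged from
a user-supplied pentamer lookup table, mean signal of arbitrary
genomic tracks in configurable windows, and positional features
(relative position in gene, distances to TSS and poly(A) site, distance
to the nearest annotated nucleosome dyad).  Sequence extraction is
strand-aware: minus-strand loci are reverse-complemented into
transcript orientation.

Numeric feature distributions are compared real-vs-control with
two-sample t-tests under Bonferroni correction; categorical sequence
features are skipped with a note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from Bio.SeqUtils import MeltingTemp

from .annotation import GeneAnnotationSet
from .genome import GenomeSequence, revcomp
from .occupancy import OccupancyTrack

DEFAULT_FLANK = 10
PENTAMER_FLANK = 2


@dataclass
class FeatureSpec:
    """A track-window feature: mean of ``track`` within +/-``window`` bp."""

    name: str
    track: OccupancyTrack | None = None
    window: int = 25
    kind: str = "track-window"


def shuffled_control_loci(pauses: pd.DataFrame,
                          annotation: GeneAnnotationSet,
                          seed: int) -> pd.DataFrame:
    """Uniform random non-pause positions, count-matched per gene."""
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    rows = []
    for gid, grp in pauses.groupby("gene_id", sort=False):
        gene = annotation[gid]
        taken = set(grp["position"] - gene.start)
        free = np.setdiff1d(np.arange(gene.length), sorted(taken))
        if len(grp) > free.size:
            raise ValueError(f"{gid}: gene saturated by pauses")
        offsets = rng.choice(free, size=len(grp), replace=False)
        for off in offsets:
            rows.append((gene.chrom, gene.start + int(off), gene.strand,
                         gid))
    return pd.DataFrame(rows, columns=["chrom", "position", "strand",
                                       "gene_id"])


def labeled_loci(pauses: pd.DataFrame, annotation: GeneAnnotationSet,
                 seed: int) -> pd.DataFrame:
    """Stack real pauses and shuffled controls with a label column."""
    controls = shuffled_control_loci(pauses, annotation, seed)
    cols = ["chrom", "position", "strand", "gene_id"]
    real = pauses[cols].assign(label="real")
    ctrl = controls[cols].assign(label="control")
    return pd.concat([real, ctrl], ignore_index=True)


def _oriented_flank(genome: GenomeSequence, chrom: str, pos: int,
                    strand: str, flank: int) -> str | None:
    seq = genome[chrom]
    lo, hi = pos - flank, pos + flank + 1
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    return window if strand == "+" else revcomp(window)


def read_shape_table(path) -> pd.DataFrame:
    """Pentamer DNA-shape lookup: column 'pentamer' plus one column per
    shape parameter (e.g. twist, roll, propeller, mgw)."""
    table = pd.read_csv(path, sep="\t")
    return table.set_index("pentamer")


def assemble_features(loci: pd.DataFrame, genome: GenomeSequence,
                      annotation: GeneAnnotationSet,
                      shape_table: pd.DataFrame | None = None,
                      track_specs: list[FeatureSpec] = (),
                      nucleosome_dyads: dict[str, np.ndarray] | None = None,
                      flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Complete per-locus feature table.

    Loci within half a window of a chromosome end keep their row with
    the affected features set to missing and ``edge_flag`` True.
    """
    rows = []
    for row in loci.itertuples(index=False):
        gene = annotation[row.gene_id]
        feats: dict = {"chrom": row.chrom, "position": row.position,
                       "strand": row.strand, "gene_id": row.gene_id,
                       "label": getattr(row, "label", "real"),
                       "edge_flag": False}
        seq = _oriented_flank(genome, row.chrom, row.position, row.strand,
                              flank)
        if seq is None:
            feats["edge_flag"] = True
            feats["trinucleotide"] = pd.NA
            feats["melting_tm"] = np.nan
        else:
            center = flank
            feats["trinucleotide"] = seq[center - 1:center + 2]
            for i, base in enumerate(seq):
                feats[f"base_{i - flank:+d}"] = base
            feats["melting_tm"] = float(MeltingTemp.Tm_NN(seq))
        if shape_table is not None:
            pent = _oriented_flank(genome, row.chrom, row.position,
                                   row.strand, flank)
            for shape in shape_table.columns:
                if pent is None:
                    feats[f"shape_{shape}"] = np.nan
                    continue
                vals = [shape_table.at[pent[i:i + 5], shape]
                        for i in range(len(pent) - 4)
                        if pent[i:i + 5] in shape_table.index]
                feats[f"shape_{shape}"] = float(np.mean(vals)) if vals \
                    else np.nan
        for spec in track_specs:
            arr = spec.track.get(row.chrom, row.strand)
            lo = max(0, row.position - spec.window)
            hi = min(arr.size, row.position + spec.window + 1)
            feats[spec.name] = float(arr[lo:hi].mean())
        feats["relative_position"] = gene.relative_position(row.position)
        feats["dist_tss"] = abs(row.position - gene.tss)
        feats["dist_polya"] = abs(row.position - gene.polya)
        if nucleosome_dyads is not None:
            dyads = nucleosome_dyads.get(row.chrom)
            feats["dist_dyad"] = (
                float(np.min(np.abs(dyads - row.position)))
                if dyads is not None and len(dyads) else np.nan)
        rows.append(feats)
    return pd.DataFrame(rows)


def feature_distribution_tests(table: pd.DataFrame,
                               ) -> pd.DataFrame:
    """Two-sample t-tests of every numeric feature, real vs control,
    Bonferroni-adjusted over the tested features.  Categorical and
    zero-variance features are reported as skipped."""
    meta = {"chrom", "position", "strand", "gene_id", "label", "edge_flag"}
    real = table[table["label"] == "real"]
    ctrl = table[table["label"] == "control"]
    candidates = [c for c in table.columns if c not in meta]
    results = []
    for col in candidates:
        if not pd.api.types.is_numeric_dtype(table[col]):
            results.append((col, np.nan, np.nan, "categorical"))
            continue
        x = real[col].dropna()
        y = ctrl[col].dropna()
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            results.append((col, np.nan, np.nan, "zero-variance"))
            continue
        stat, p = ttest_ind(x, y)
        results.append((col, float(stat), float(p), "tested"))
    df = pd.DataFrame(results, columns=["feature", "t", "p", "status"])
    m = int((df["status"] == "tested").sum())
    if m < 2:
        raise ValueError("need >= 2 testable numeric features")
    df["p_bonferroni"] = np.where(df["status"] == "tested",
                                  np.minimum(df["p"] * m, 1.0), np.nan)
    return df


def write_flank_fasta(loci: pd.DataFrame, genome: GenomeSequence, path,
                      flank: int = DEFAULT_FLANK) -> None:
    """Export +/-flank sequences around loci for external motif tools."""
    with open(path, "w") as fh:
        for i, row in enumerate(loci.itertuples(index=False)):
            seq = _oriented_flank(genome, row.chrom, row.position,
                                  row.strand, flank)
            if seq is None:
                continue
            fh.write(f">{row.chrom}:{row.position}:{row.strand}\n{seq}\n")
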