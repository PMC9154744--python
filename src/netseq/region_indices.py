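"""Per-gene pausing indices, metagene profiles, and splicing indices.

The pausing index (PI) of a gene at an anchor (TSS, poly(A) site,
splice site, or antisense start) is the length-normalized Pol II
density in a strand-aware window around the anchor divided by the
length-normalized density over the remainder of the gene body.  Window
positions falling outside the annotated gene (e.g. 50 bp upstream of
the TSS) contribute to the numerator only; the remainder is the set of
gene-body positions not inside the window, so PI is scale-invariant and
equals 1 under uniform coverage.

The splicing index of an intron is 2 x spliced junction reads divided
by the sum of 5'- and 3'-splice-site unspliced reads; two samples are
compared with a Wilcoxon signed-rank test paired by intron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
import statsmodels.api as sm

from .annotation import Gene, GeneAnnotationSet
from .occupancy import OccupancyTrack

#: default anchor windows, (upstream, downstream) bp, strand-aware
DEFAULT_WINDOWS = {
    "TSS": (50, 150),
    "polyA": (100, 100),
    "SS5": (10, 10),
    "SS3": (10, 10),
    "antisense-TSS": (50, 150),
}

METAGENE_WINDOWS = {
    "TSS": (100, 600),
    "polyA": (500, 200),
    "SS5": (25, 25),
    "SS3": (25, 25),
}


@dataclass(frozen=True)
class RegionSpec:
    """Anchor and strand-aware (upstream, downstream) window in bp."""

    anchor: str
    upstream: int
    downstream: int

    def __post_init__(self) -> None:
        if self.upstream + self.downstream <= 0:
            raise ValueError("window must be non-empty")

    @classmethod
    def default(cls, anchor: str) -> "RegionSpec":
        up, down = DEFAULT_WINDOWS[anchor]
        return cls(anchor, up, down)


def _anchor_position(gene: Gene, anchor: str) -> int | None:
    if anchor in ("TSS", "antisense-TSS"):
        return gene.tss
    if anchor == "polyA":
        return gene.polya
    if anchor == "SS5":
        return gene.five_ss
    if anchor == "SS3":
        return gene.three_ss
    raise ValueError(f"unknown anchor {anchor!r}")


def _window_positions(gene: Gene, anchor_pos: int, spec: RegionSpec,
                      chrom_length: int) -> np.ndarray:
    """Genomic positions of the window, clipped to the chromosome."""
    if gene.strand == "+":
        lo = anchor_pos - spec.upstream
        hi = anchor_pos + spec.downstream
    else:
        lo = anchor_pos - spec.downstream
        hi = anchor_pos + spec.upstream
    return np.arange(max(0, lo), min(chrom_length, hi + 1))


def pausing_index(track: OccupancyTrack, annotation: GeneAnnotationSet,
                  region: RegionSpec) -> pd.DataFrame:
    """PI per gene for one region; PI is NaN (flagged undefined) when
    the remainder of the gene carries no signal.  Genes lacking the
    anchor (e.g. intronless genes for splice-site regions) or shorter
    than the in-gene window are skipped."""
    rows = []
    for g in annotation:
        anchor_pos = _anchor_position(g, region.anchor)
        if anchor_pos is None:
            continue
        chrom_len = track.chrom_lengths[g.chrom]
        win = _window_positions(g, anchor_pos, region, chrom_len)
        arr = track.get(g.chrom, g.strand)
        region_sum = float(arr[win].sum())
        region_len = len(win)
        in_gene = (win >= g.start) & (win < g.end)
        body = np.arange(g.start, g.end)
        remainder = np.setdiff1d(body, win[in_gene], assume_unique=True)
        if remainder.size == 0:
            continue  # gene shorter than the window
        rem_sum = float(arr[remainder].sum())
        region_density = region_sum / region_len
        body_density = rem_sum / remainder.size
        pi = region_density / body_density if body_density > 0 \
            else float("nan")
        rows.append((g.gene_id, region.anchor, pi, region_density,
                     body_density, body_density > 0))
    return pd.DataFrame(rows, columns=["gene_id", "region", "PI",
                                       "region_density", "body_density",
                                       "defined"])


def antisense_pausing_index(track: OccupancyTrack,
                            antisense_annotation: GeneAnnotationSet,
                            spec: RegionSpec | None = None) -> pd.DataFrame:
    """PI at the antisense start (opposite the host gene's 3' end),
    computed on the antisense strand with a TSS-style window."""
    if spec is None:
        spec = RegionSpec("antisense-TSS", *DEFAULT_WINDOWS["antisense-TSS"])
    return pausing_index(track, antisense_annotation, spec)


def region_index_table(track: OccupancyTrack,
                       annotation: GeneAnnotationSet,
                       regions: tuple[str, ...] = ("TSS", "polyA",
                                                   "SS5", "SS3"),
                       ) -> pd.DataFrame:
    """Stacked PI table over several regions."""
    parts = [pausing_index(track, annotation, RegionSpec.default(r))
             for r in regions]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=["gene_id", "region", "PI",
                                     "region_density", "body_density",
                                     "defined"])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------- metagene

def metagene_profile(track: OccupancyTrack, annotation: GeneAnnotationSet,
                     anchor: str = "TSS",
                     window: tuple[int, int] | None = None,
                     norm: str = "sum", span: float = 0.01,
                     min_genes: int = 10) -> pd.DataFrame:
    """Per-offset mean signal with loess smoothing and a 95% CI.

    Only non-overlapping genes contribute (each gene's window must also
    lie within its chromosome).  Each gene's window signal is
    normalized to sum 1 (``norm='sum'``) or to max 1 (``norm='max'``);
    the across-gene mean at each offset is loess-smoothed with the
    given span and bracketed by a normal-approximation 95% CI.
    """
    if window is None:
        window = METAGENE_WINDOWS[anchor]
    up, down = window
    usable = annotation.nonoverlapping()
    profiles = []
    for g in usable:
        anchor_pos = _anchor_position(g, anchor)
        if anchor_pos is None:
            continue
        if g.strand == "+":
            lo, hi = anchor_pos - up, anchor_pos + down
        else:
            lo, hi = anchor_pos - down, anchor_pos + up
        if lo < 0 or hi + 1 > track.chrom_lengths[g.chrom]:
            continue
        sig = track.get(g.chrom, g.strand)[lo:hi + 1].astype(float)
        if g.strand == "-":
            sig = sig[::-1]
        total = sig.sum() if norm == "sum" else sig.max()
        if total <= 0:
            continue
        profiles.append(sig / total)
    if len(profiles) < min_genes:
        raise ValueError(f"only {len(profiles)} contributing genes "
                         f"(< {min_genes})")
    mat = np.vstack(profiles)
    offsets = np.arange(-up, down + 1)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    frac = max(span, 3.0 / len(offsets))
    smoothed = sm.nonparametric.lowess(mean, offsets, frac=frac,
                                       return_sorted=False)
    return pd.DataFrame({
        "offset": offsets, "mean": mean, "smoothed": smoothed,
        "ci_lo": mean - 1.96 * sem, "ci_hi": mean + 1.96 * sem,
        "n_genes": mat.shape[0],
    })


# ---------------------------------------------------------------- splicing

def splicing_index(junctions: pd.DataFrame) -> pd.DataFrame:
    """SI = 2 * spliced / (unspliced5 + unspliced3) per intron.

    SI is NaN (undefined) when the denominator is zero; undefined
    records are tallied in ``result.attrs['n_undefined']``.
    """
    out = junctions.copy()
    denom = out["unspliced5"] + out["unspliced3"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["SI"] = np.where(denom > 0, 2.0 * out["spliced"] / denom,
                             np.nan)
    out.attrs["n_undefined"] = int((denom == 0).sum())
    return out


def compare_splicing(junctions_a: pd.DataFrame, junctions_b: pd.DataFrame,
                     ) -> dict:
    """Paired Wilcoxon signed-rank test of SI across shared introns."""
    a = splicing_index(junctions_a).set_index("intron_id")["SI"]
    b = splicing_index(junctions_b).set_index("intron_id")["SI"]
    shared = a.index.intersection(b.index)
    paired = pd.DataFrame({"a": a[shared], "b": b[shared]}).dropna()
    n_excluded = len(shared) - len(paired)
    if len(paired) < 2:
        raise ValueError("fewer than two introns with defined SI in both")
    diff = paired["a"] - paired["b"]
    if np.allclose(diff, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = wilcoxon(paired["a"], paired["b"])
    return {"statistic": float(stat), "p_value": float(p),
            "n_introns": len(paired), "n_excluded_undefined": n_excluded,
            "median_si_a": float(paired["a"].median()),
            "median_si_b": float(paired["b"].median())}
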