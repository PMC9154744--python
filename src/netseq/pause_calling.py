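"""Single-nucleotide Pol II pause calling.

A pause is a position within a well-expressed gene (mean coverage > 2
reads/bp in both replicates) whose read count exceeds the mean of the
surrounding 200 non-pause nucleotides by more than three standard
deviations, with the local background modeled as a negative binomial
fit by the method of moments (Poisson fallback when the sample variance
does not exceed the mean).  Because the background must exclude pauses,
calling iterates to a fixed point: call, refit excluding called
positions, repeat (capped at 10 iterations).  Every pause must carry at
least two reads regardless of coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotationSet
from .occupancy import OccupancyTrack

CALL_COLUMNS = ["chrom", "position", "strand", "gene_id", "reads", "z"]


@dataclass
class BackgroundFit:
    """Moment fit of the local background window."""

    mu: float
    sd: float
    distribution: str  # "NB" | "Poisson-fallback" | "degenerate"
    nb_size: float | None
    n_positions: int

    @property
    def threshold(self) -> float:
        return self.mu + 3.0 * self.sd


def select_well_expressed(track_rep1: OccupancyTrack,
                          track_rep2: OccupancyTrack,
                          annotation: GeneAnnotationSet,
                          min_coverage: float = 2.0) -> pd.DataFrame:
    """Per-gene expression filter: mean coverage strictly above
    ``min_coverage`` reads/bp in BOTH replicates."""
    rows = []
    for g in annotation:
        m1 = track_rep1.gene_sum(g) / g.length
        m2 = track_rep2.gene_sum(g) / g.length
        rows.append((g.gene_id, m1, m2,
                     bool(m1 > min_coverage and m2 > min_coverage)))
    return pd.DataFrame(rows, columns=["gene_id", "mean_rep1", "mean_rep2",
                                       "passes"])


def fit_background(counts: np.ndarray) -> BackgroundFit:
    """Method-of-moments negative-binomial fit to non-pause positions.

    r = mu^2 / (var - mu) and sd = sqrt(var) under NB; when the sample
    variance (ddof=1) does not exceed the mean the fit falls back to
    Poisson (sd = sqrt(mu)).  An all-zero window degenerates to
    mu = sd = 0, so the call threshold reduces to the 2-read floor.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if n == 0 or not counts.any():
        return BackgroundFit(0.0, 0.0, "degenerate", None, n)
    mu = float(counts.mean())
    var = float(counts.var(ddof=1)) if n > 1 else 0.0
    if var > mu:
        r = mu * mu / (var - mu)
        return BackgroundFit(mu, float(np.sqrt(var)), "NB", r, n)
    return BackgroundFit(mu, float(np.sqrt(mu)), "Poisson-fallback", None, n)


def _call_gene(counts: np.ndarray, window: int, z: float, min_reads: int,
               min_informative: int, max_iter: int,
               ) -> tuple[np.ndarray, bool]:
    """Fixed-point pause mask for one gene's count vector.

    Windows are +/- window/2 centered on the candidate, truncated at
    gene bounds; the candidate and currently called pauses are excluded
    from the moment fit.  Returns (mask, converged).
    """
    L = counts.size
    half = window // 2
    idx = np.arange(L)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(L, idx + half + 1)  # candidate's own slot removed below
    eligible = counts >= min_reads
    mask = np.zeros(L, dtype=bool)
    converged = False
    for _ in range(max_iter):
        informative = ~mask
        c = np.where(informative, counts, 0.0)
        s1 = np.concatenate(([0.0], np.cumsum(c)))
        s2 = np.concatenate(([0.0], np.cumsum(c * c)))
        cnt = np.concatenate(([0], np.cumsum(informative)))
        n = (cnt[hi] - cnt[lo]).astype(float)
        w1 = s1[hi] - s1[lo]
        w2 = s2[hi] - s2[lo]
        # exclude the candidate itself where it is informative
        self_in = informative
        n = n - self_in
        w1 = w1 - np.where(self_in, counts, 0.0)
        w2 = w2 - np.where(self_in, counts * counts, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, w1 / np.maximum(n, 1), 0.0)
            var = np.where(n > 1,
                           (w2 - n * mean * mean) / np.maximum(n - 1, 1),
                           0.0)
        nonzero = w1 > 0
        sd = np.where(var > mean, np.sqrt(np.maximum(var, 0.0)),
                      np.sqrt(np.maximum(mean, 0.0)))
        sd = np.where(nonzero, sd, 0.0)
        mean = np.where(nonzero, mean, 0.0)
        new_mask = eligible & (n >= min_informative) \
            & (counts > mean + z * sd)
        if np.array_equal(new_mask, mask):
            converged = True
            break
        mask = new_mask
    return mask, converged


def _gene_fit_at(counts: np.ndarray, pos: int, mask: np.ndarray,
                 window: int) -> BackgroundFit:
    half = window // 2
    lo, hi = max(0, pos - half), min(counts.size, pos + half + 1)
    sel = ~mask[lo:hi]
    sel[pos - lo] = False
    return fit_background(counts[lo:hi][sel])


def call_pauses(track: OccupancyTrack, annotation: GeneAnnotationSet,
                expression_filter: pd.DataFrame, window: int = 200,
                z: float = 3.0, min_reads: int = 2,
                min_informative: int = 50, max_iter: int = 10,
                ) -> pd.DataFrame:
    """Call pauses in one replicate over genes passing the filter.

    Returns a call table with raw read count ("pause strength") and the
    z-score against the final background fit at each called position.
    Genes whose iterative exclusion does not converge are kept at the
    last iterate and listed in ``result.attrs['non_converged']``.
    """
    passing = set(expression_filter.loc[expression_filter["passes"],
                                        "gene_id"])
    rows: list[tuple] = []
    non_converged: list[str] = []
    for g in annotation:
        if g.gene_id not in passing:
            continue
        counts = track.get(g.chrom, g.strand)[g.start:g.end].astype(float)
        mask, ok = _call_gene(counts, window, z, min_reads,
                              min_informative, max_iter)
        if not ok:
            non_converged.append(g.gene_id)
        for pos in np.flatnonzero(mask):
            fit = _gene_fit_at(counts, int(pos), mask, window)
            zval = ((counts[pos] - fit.mu) / fit.sd) if fit.sd > 0 \
                else float("inf")
            rows.append((g.chrom, g.start + int(pos), g.strand, g.gene_id,
                         int(counts[pos]), float(zval)))
    if non_converged:
        warnings.warn(f"{len(non_converged)} gene(s) hit the iteration cap")
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls.attrs["non_converged"] = non_converged
    return calls


def write_bed(calls: pd.DataFrame, path) -> None:
    """BED6: name = gene_id, score = pause reads."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                     f"{row.gene_id}\t{row.reads}\t{row.strand}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name, score, strand = \
                line.rstrip("\n").split("\t")[:6]
            rows.append((chrom, int(start), strand, name, int(score),
                         float("nan")))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
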