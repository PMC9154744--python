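"""Irreproducible discovery rate (IDR) for replicate pause calls.

Pause scores (log10 of the read count at the pause) from two replicates
are modeled with the Gaussian-copula mixture of Li, Brown, Huang &
Bickel (2011): ranks are converted to pseudo-values through the inverse
of the mixture marginal CDF, and an EM algorithm fits a two-component
bivariate normal mixture — a reproducible component N(mu, sigma^2) in
both coordinates with correlation rho and mixing proportion p, and an
irreproducible standard-normal independent component.  The local idr of
a pair is the posterior probability of the irreproducible component;
the global IDR of a pair is the running mean of local idr over pairs
ranked by increasing local idr (the ENCODE convention), which is
non-decreasing down the ranked list.  Because the model acts on ranks,
IDR is invariant to strictly monotone transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

PAIR_KEY = ["chrom", "position", "strand"]


@dataclass
class IdrModelParams:
    """Mixture parameters: reproducible-component mean, sd, correlation,
    and mixing proportion."""

    mu: float = 3.0
    sigma: float = 1.0
    rho: float = 0.9
    p: float = 0.5

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")


def match_pauses(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame,
                 ) -> pd.DataFrame:
    """Pair pauses by exact (chrom, position, strand) identity.

    Scores are log10 of the per-replicate read counts.  Unmatched call
    counts are reported in ``pairs.attrs['unmatched_rep1'/'rep2']``.
    """
    a = calls_rep1[PAIR_KEY + ["gene_id", "reads"]].rename(
        columns={"reads": "reads_rep1"})
    b = calls_rep2[PAIR_KEY + ["reads"]].rename(
        columns={"reads": "reads_rep2"})
    pairs = a.merge(b, on=PAIR_KEY, how="inner")
    pairs["score_rep1"] = np.log10(pairs["reads_rep1"].astype(float))
    pairs["score_rep2"] = np.log10(pairs["reads_rep2"].astype(float))
    pairs.attrs["unmatched_rep1"] = len(calls_rep1) - len(pairs)
    pairs.attrs["unmatched_rep2"] = len(calls_rep2) - len(pairs)
    return pairs


def _pseudo_values(u: np.ndarray, params: IdrModelParams,
                   grid_size: int = 8192) -> np.ndarray:
    """Invert the mixture marginal CDF G at the rank quantiles u."""
    lo = min(-8.0, params.mu - 8.0 * params.sigma)
    hi = max(8.0, params.mu + 8.0 * params.sigma)
    grid = np.linspace(lo, hi, grid_size)
    cdf = params.p * norm.cdf((grid - params.mu) / params.sigma) \
        + (1.0 - params.p) * norm.cdf(grid)
    return np.interp(u, cdf, grid)


def _bivariate_logpdf(z1, z2, mu, sigma, rho):
    s2 = sigma * sigma
    det = 1.0 - rho * rho
    d1 = (z1 - mu) / sigma
    d2 = (z2 - mu) / sigma
    quad = (d1 * d1 - 2.0 * rho * d1 * d2 + d2 * d2) / det
    return -np.log(2.0 * np.pi * s2 * np.sqrt(det)) - 0.5 * quad


def estimate_idr(score_rep1: np.ndarray, score_rep2: np.ndarray,
                 init: IdrModelParams | None = None, tol: float = 1e-6,
                 max_iter: int = 200,
                 ) -> tuple[np.ndarray, np.ndarray, IdrModelParams, bool]:
    """Fit the copula mixture and compute per-pair local idr / global IDR.

    Returns ``(local_idr, global_idr, fitted_params, converged)``.  Ties
    in either score vector receive average ranks, so log-scores of small
    integer read counts are handled gracefully.
    """
    if init is None:
        init = IdrModelParams()
    init.validate()
    s1 = np.asarray(score_rep1, dtype=float)
    s2 = np.asarray(score_rep2, dtype=float)
    n = s1.size
    if n < 20:
        raise ValueError(f"need >= 20 pairs, got {n}")
    if s2.size != n:
        raise ValueError("score vectors differ in length")
    u1 = rankdata(s1, method="average") / (n + 1.0)
    u2 = rankdata(s2, method="average") / (n + 1.0)

    mu, sigma, rho, p = init.mu, init.sigma, init.rho, init.p
    last_ll = -np.inf
    converged = False
    w = np.full(n, p)
    for _ in range(max_iter):
        z1 = _pseudo_values(u1, IdrModelParams(mu, sigma, rho, p))
        z2 = _pseudo_values(u2, IdrModelParams(mu, sigma, rho, p))
        log_f1 = _bivariate_logpdf(z1, z2, mu, sigma, rho)
        log_f0 = norm.logpdf(z1) + norm.logpdf(z2)
        a = np.log(p) + log_f1
        b = np.log1p(-p) + log_f0
        m = np.maximum(a, b)
        log_total = m + np.log(np.exp(a - m) + np.exp(b - m))
        w = np.exp(a - log_total)
        ll = float(log_total.sum())
        # M-step: weighted moments of the reproducible component
        sw = w.sum()
        p = float(np.clip(sw / n, 1e-4, 1.0 - 1e-4))
        if sw > 0:
            mu = float((w * (z1 + z2)).sum() / (2.0 * sw))
            var = float((w * ((z1 - mu) ** 2 + (z2 - mu) ** 2)).sum()
                        / (2.0 * sw))
            var = max(var, 1e-6)
            sigma = float(np.sqrt(var))
            rho = float(np.clip(
                (w * (z1 - mu) * (z2 - mu)).sum() / (var * sw),
                -0.999, 0.999))
        if abs(ll - last_ll) < tol:
            converged = True
            break
        last_ll = ll

    local_idr = 1.0 - w
    global_idr = _cumulative_idr(local_idr)
    fitted = IdrModelParams(mu, sigma, rho, p)
    return local_idr, global_idr, fitted, converged


def _cumulative_idr(local_idr: np.ndarray) -> np.ndarray:
    """Global IDR: running mean of local idr over the ranked pair list,
    with tied local values sharing the value at the end of their tie
    block (so equal evidence maps to equal global IDR)."""
    n = local_idr.size
    order = np.argsort(local_idr, kind="stable")
    sorted_local = local_idr[order]
    cum = np.cumsum(sorted_local) / np.arange(1, n + 1)
    boundaries = np.flatnonzero(np.diff(sorted_local) != 0)
    group_end = np.concatenate([boundaries, [n - 1]])
    sizes = np.diff(np.concatenate([[-1], group_end]))
    cum = cum[np.repeat(group_end, sizes)]
    global_idr = np.empty(n)
    global_idr[order] = cum
    return global_idr


def assign_idr(pairs: pd.DataFrame, init: IdrModelParams | None = None,
               use_local: bool = False, **kwargs) -> tuple[pd.DataFrame,
                                                           IdrModelParams]:
    """Attach ``idr`` (and ``local_idr``/``global_idr``) to a pair table."""
    local, global_, params, converged = estimate_idr(
        pairs["score_rep1"].to_numpy(), pairs["score_rep2"].to_numpy(),
        init=init, **kwargs)
    out = pairs.copy()
    out["local_idr"] = local
    out["global_idr"] = global_
    out["idr"] = local if use_local else global_
    out.attrs["fitted_params"] = params
    out.attrs["converged"] = converged
    return out, params


def reproducible_pauses(pairs: pd.DataFrame,
                        threshold: float = 0.01) -> pd.DataFrame:
    """Pairs with IDR below threshold, merged to a single pause set with
    strength equal to the summed replicate reads."""
    if "idr" not in pairs.columns:
        raise ValueError("pairs must carry an 'idr' column; run assign_idr")
    kept = pairs.loc[pairs["idr"] < threshold].copy()
    kept["reads"] = kept["reads_rep1"] + kept["reads_rep2"]
    cols = PAIR_KEY + ["gene_id", "reads", "idr"]
    cols = [c for c in cols if c in kept.columns]
    return kept[cols].reset_index(drop=True)
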