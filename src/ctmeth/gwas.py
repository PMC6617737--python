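"""Odds-ratio-quantile co-localization of CpG sites with GWAS SNPs.

For a query CpG set (e.g. the top case/control sites), every GWAS SNP within
a 1-kb window of a site is collected and counted per OR quantile (empirical
percentiles of the full GWAS table, so different traits are comparable).
The same is done for k random background CpG sets of equal size; the
empirical P per quantile is the fraction of background sets with a strictly
greater count than the query set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["or_quantile_bins", "snps_near_sites", "coloc_empirical",
           "ColocResult"]


def or_quantile_bins(gwas: pd.DataFrame, n_bins: int = 10):
    """Assign each SNP to an OR quantile bin; ties go to the lower bin.

    Returns (bin_assignment, bin_edges) with ``len(edges) == n_bins + 1``.
    """
    orr = gwas["OR"].to_numpy(dtype=float)
    if orr.size < n_bins:
        raise ValueError("fewer SNPs than bins")
    if np.all(orr == orr[0]):
        raise ValueError("constant OR column")
    edges = np.quantile(orr, np.linspace(0, 1, n_bins + 1))
    # side='left': a value equal to an internal edge stays in the lower bin
    bins = np.searchsorted(edges[1:-1], orr, side="left")
    return bins, edges


def snps_near_sites(sites: pd.DataFrame, gwas: pd.DataFrame,
                    window_bp: int = 1000, centered: bool = True,
                    deduplicate: bool = False) -> pd.DataFrame:
    """GWAS SNPs within a window of any query CpG.

    With ``centered`` (default) the window is ``window_bp`` wide centered on
    the CpG (distance <= window_bp/2); otherwise it is a flank of
    ``window_bp`` on each side. A SNP near two sites appears once per site
    unless ``deduplicate``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp / 2 if centered else float(window_bp)
    hits = []
    for chrom, snps in gwas.groupby("chrom", sort=False):
        spos = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
        if spos.size == 0:
            continue
        spos = np.sort(spos)
        gpos = snps["pos"].to_numpy()
        lo = np.searchsorted(spos, gpos - half, side="left")
        hi = np.searchsorted(spos, gpos + half, side="right")
        n_near = hi - lo
        near = n_near > 0
        if not near.any():
            continue
        sub = snps.loc[near].copy()
        if deduplicate:
            sub["n_sites"] = n_near[near]
            hits.append(sub)
        else:
            reps = n_near[near]
            expanded = sub.loc[sub.index.repeat(reps)].copy()
            site_pos = np.concatenate([spos[a:b] for a, b in
                                       zip(lo[near], hi[near])])
            expanded["site_pos"] = site_pos
            hits.append(expanded)
    if not hits:
        return gwas.iloc[0:0].copy()
    return pd.concat(hits, ignore_index=True)


@dataclass
class ColocResult:
    bin_edges: np.ndarray
    observed_counts: np.ndarray          # per OR quantile
    background_counts: np.ndarray        # (k, n_bins)
    empirical_p: np.ndarray              # per quantile, strict '>' rule
    k: int
    window_bp: int

    def as_frame(self) -> pd.DataFrame:
        nb = len(self.observed_counts)
        return pd.DataFrame({
            "quantile": np.arange(nb),
            "or_lo": self.bin_edges[:-1],
            "or_hi": self.bin_edges[1:],
            "observed": self.observed_counts,
            "background_mean": self.background_counts.mean(axis=0),
            "empirical_p": self.empirical_p,
        })


def _counts_per_bin(sites, gwas_binned, n_bins, window_bp, centered):
    near = snps_near_sites(sites, gwas_binned, window_bp, centered)
    counts = np.zeros(n_bins, dtype=np.int64)
    if len(near):
        got = near.groupby("or_bin").size()
        counts[got.index.to_numpy()] = got.to_numpy()
    return counts


def coloc_empirical(sites: pd.DataFrame, background_pool: pd.DataFrame,
                    gwas: pd.DataFrame, n_bins: int = 10, k: int = 100,
                    window_bp: int = 1000, seed: int = 0,
                    centered: bool = True) -> ColocResult:
    """OR-quantile co-localization with a random-background empirical null.

    ``background_pool`` is the set of eligible non-query CpGs (conventionally
    sites with case/control P > 0.1); the query sites themselves are
    excluded from it. Background sets match the query set size only.
    empirical_p per quantile = #{background sets with count > observed} / k.
    """
    bins, edges = or_quantile_bins(gwas, n_bins)
    gb = gwas.copy()
    gb["or_bin"] = bins

    qkeys = set(zip(sites["chrom"], sites["pos"]))
    pool = background_pool[
        ~pd.Index(zip(background_pool["chrom"], background_pool["pos"]))
        .isin(qkeys)].reset_index(drop=True)
    if len(pool) < len(sites):
        raise ValueError("background pool smaller than the query set")

    observed = _counts_per_bin(sites, gb, n_bins, window_bp, centered)
    rng = np.random.default_rng(seed)
    bg = np.zeros((k, n_bins), dtype=np.int64)
    for i in range(k):
        pick = rng.choice(len(pool), size=len(sites), replace=False)
        bg[i] = _counts_per_bin(pool.iloc[pick], gb, n_bins,
                                window_bp, centered)
    emp = (bg > observed[None, :]).mean(axis=0)
    return ColocResult(edges, observed, bg, emp, k, window_bp)
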