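"""Aggregate significant DMPs into differentially methylated regions (DMRs).

A DMR is a maximal chain of significant DMPs on one chromosome in which
consecutive significant DMPs are at most ``max_gap`` bp apart, containing at
least ``min_dmp`` significant DMPs (default: >= 5 significant DMPs within
50 bp of each other, the "5 DMPs / 50 bp" rule). Non-significant CpGs inside
the span neither break the chain nor count toward ``min_dmp``.

Each region carries an ``area_stat`` — the sum of the per-CpG test statistics
of its member DMPs — and ``mean_diff``, the mean of the member group-mean
fraction differences (signed; group 2 minus group 1).

Region coordinates are 0-based half-open: ``[first_pos - 1, last_pos)``, so
the span of DMPs at 1-based positions 100..140 is 41 bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["call_dmrs", "summarize_dmr"]

REGION_COLUMNS = ["chrom", "start", "end", "n_cpg_significant",
                  "area_stat", "mean_diff"]


def summarize_dmr(chrom: str, members: pd.DataFrame) -> dict:
    """Summary statistics for one region from its significant member DMPs."""
    if len(members) == 0:
        raise ValueError("empty member list")
    pos = members["pos"].to_numpy()
    return {
        "chrom": chrom,
        "start": int(pos.min()) - 1,
        "end": int(pos.max()),
        "n_cpg_significant": int(len(members)),
        "area_stat": float(members["stat"].sum()),
        "mean_diff": float((members["mean_g2"] - members["mean_g1"]).mean()),
    }


def call_dmrs(results: pd.DataFrame, alpha: float = 0.05, max_gap: int = 50,
              min_dmp: int = 5, adjust: str = "p_bonf",
              min_span: int | None = None) -> pd.DataFrame:
    """Chain significant DMPs into DMRs.

    Parameters
    ----------
    results : per-site test results (must be sorted by chrom, pos) with the
        adjusted-P column named by ``adjust`` (default Bonferroni).
    alpha : significance cutoff applied to that column.
    max_gap : maximum bp between consecutive significant DMPs in a chain.
    min_dmp : minimum significant DMPs per emitted region.
    min_span : optionally require the emitted region span to be at least
        this many bp (alternative reading of the "50-bp region" rule).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for chrom, grp in results.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            raise ValueError(f"results not sorted by position on {chrom}")

    regions = []
    sig = results[results[adjust] < alpha]
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if pos.size == 0:
            continue
        # maximal chains: break where the gap between consecutive
        # significant DMPs exceeds max_gap
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, pos.size - 1]
        for s, e in zip(starts, ends):
            if e - s + 1 < min_dmp:
                continue
            region = summarize_dmr(chrom, grp.iloc[s:e + 1])
            if min_span is not None and region["end"] - region["start"] < min_span:
                continue
            regions.append(region)
    return pd.DataFrame(regions, columns=REGION_COLUMNS)
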