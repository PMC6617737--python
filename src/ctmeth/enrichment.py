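"""Matched-null construction and enrichment statistics for region/CpG sets.

The empirical-null scheme follows the standard matched-resampling recipe for
genomic region sets: for each observed region, draw random regions on the
same chromosome with identical length and GC content within a tolerance
(default 1%), build k such null sets (default 100), and compare an overlap
measure between the observed set and each null set. The enrichment ratio is
observed / mean(null); the empirical P is the fraction of null sets at least
as extreme as the observed value (ties count against significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationSet

__all__ = [
    "gc_content",
    "sample_matched_nulls",
    "MatchedNullCollection",
    "EnrichmentResult",
    "enrichment_test",
    "fisher_enrichment",
    "random_cpg_background",
    "annotate_genic",
    "overlap_measure",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# interval utilities (merged sorted arrays + searchsorted)

def _merged(track: AnnotationSet, chrom: str):
    iv = track.intervals
    sub = iv[iv["chrom"] == chrom].sort_values("start")
    starts, ends = [], []
    for s, e in zip(sub["start"], sub["end"]):
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


class _TrackIndex:
    def __init__(self, track: AnnotationSet):
        self._by_chrom = {c: _merged(track, c)
                          for c in track.intervals["chrom"].unique()}

    def bp_overlap(self, chrom, start, end) -> np.ndarray:
        """Per-query bp of overlap with the merged track."""
        start = np.atleast_1d(np.asarray(start))
        end = np.atleast_1d(np.asarray(end))
        if chrom not in self._by_chrom:
            return np.zeros(start.shape, dtype=np.int64)
        ms, me = self._by_chrom[chrom]
        out = np.zeros(start.shape, dtype=np.int64)
        lo = np.searchsorted(me, start, side="right")
        hi = np.searchsorted(ms, end, side="left")
        for i, (s, e, a, b) in enumerate(zip(start, end, lo, hi)):
            if b > a:
                out[i] = np.sum(np.minimum(me[a:b], e) - np.maximum(ms[a:b], s))
        return out


def overlap_measure(items: pd.DataFrame, track: AnnotationSet | _TrackIndex,
                    measure: str) -> float:
    """Overlap of a region set (chrom/start/end) or CpG set (chrom/pos, as
    1 bp queries) with a track.

    measure: ``count_overlapping`` (items with any overlap), ``bp_overlap``
    (total overlapping bp), or ``fraction_overlapping``.
    """
    idx = track if isinstance(track, _TrackIndex) else _TrackIndex(track)
    if {"start", "end"}.issubset(items.columns):
        df = items
    elif "pos" in items.columns:
        df = pd.DataFrame({"chrom": items["chrom"],
                           "start": items["pos"] - 1, "end": items["pos"]})
    else:
        raise ValueError("items must have start/end or pos columns")
    per_item = np.concatenate([
        idx.bp_overlap(c, g["start"].to_numpy(), g["end"].to_numpy())
        for c, g in df.groupby("chrom", sort=False)
    ]) if len(df) else np.array([], dtype=np.int64)
    if measure == "count_overlapping":
        return float((per_item > 0).sum())
    if measure == "bp_overlap":
        return float(per_item.sum())
    if measure == "fraction_overlapping":
        return float((per_item > 0).mean()) if len(df) else 0.0
    raise ValueError(f"unknown measure {measure!r}")


# --------------------------------------------------------------------------
# GC content and matched nulls

def gc_content(genome, chrom: str, start: int, end: int) -> float:
    """(#G + #C) / #unambiguous bases over a 0-based half-open interval.

    Ambiguous (non-ACGT) bases are excluded from numerator and denominator;
    an all-ambiguous interval has GC 0.0.
    """
    if end <= start:
        raise ValueError("zero-length region")
    seq = genome.sequence[chrom][start:end].upper()
    unamb = sum(seq.count(b) for b in "ACGT")
    if unamb == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / unamb


@dataclass
class MatchedNullCollection:
    """k null region sets, each matched 1:1 to the observed regions."""

    observed: pd.DataFrame
    sets: list[pd.DataFrame]
    gc_tol: float
    n_fallback: int = 0

    @property
    def k(self) -> int:
        return len(self.sets)


def sample_matched_nulls(genome, observed: pd.DataFrame, k: int = 100,
                         gc_tol: float = 0.01, seed: int = 0,
                         max_tries: int = 10_000,
                         exclude_observed: bool = True) -> MatchedNullCollection:
    """Draw k sets of random regions matched to ``observed`` by chromosome,
    exact length, and GC content within ``gc_tol``.

    Candidate starts are uniform on the matched chromosome; draws overlapping
    any observed region are rejected. If ``max_tries`` is exhausted for a
    region, the closest-GC candidate seen is used and the fallback logged.
    """
    rng = np.random.default_rng(seed)
    obs = observed.reset_index(drop=True)
    obs_gc = [gc_content(genome, r.chrom, r.start, r.end)
              for r in obs.itertuples()]
    obs_by_chrom = {c: g[["start", "end"]].to_numpy()
                    for c, g in obs.groupby("chrom")}
    n_fallback = 0
    sets = []
    for _ in range(k):
        rows = []
        for r, g0 in zip(obs.itertuples(), obs_gc):
            length = r.end - r.start
            limit = genome.chrom_sizes[r.chrom] - length
            if limit < 0:
                raise ValueError(f"chromosome {r.chrom} shorter than region")
            best, best_d = None, np.inf
            for _try in range(max_tries):
                s = int(rng.integers(0, limit + 1))
                e = s + length
                if exclude_observed and r.chrom in obs_by_chrom:
                    iv = obs_by_chrom[r.chrom]
                    if np.any((s < iv[:, 1]) & (e > iv[:, 0])):
                        continue
                d = abs(gc_content(genome, r.chrom, s, e) - g0)
                if d <= gc_tol:
                    best = (s, e)
                    break
                if d < best_d:
                    best, best_d = (s, e), d
            else:
                n_fallback += 1
                logger.warning("GC matching fell back to closest candidate "
                               "(|dGC|=%.3f) for %s:%d-%d",
                               best_d, r.chrom, r.start, r.end)
            rows.append({"chrom": r.chrom, "start": best[0], "end": best[1]})
        sets.append(pd.DataFrame(rows))
    return MatchedNullCollection(obs, sets, gc_tol, n_fallback)


# --------------------------------------------------------------------------
# enrichment statistics

@dataclass
class EnrichmentResult:
    observed_value: float
    null_values: np.ndarray
    enrichment_ratio: float
    empirical_p: float
    p_is_upper_bound: bool  # True when no null was as extreme: report "< 1/k"

    def __str__(self) -> str:
        ptxt = (f"< {1.0 / len(self.null_values):g}" if self.p_is_upper_bound
                else f"{self.empirical_p:g}")
        return (f"EnrichmentResult(observed={self.observed_value:g}, "
                f"ratio={self.enrichment_ratio:g}, empirical_p={ptxt})")


def enrichment_test(observed: pd.DataFrame, nulls: MatchedNullCollection,
                    track: AnnotationSet, measure: str = "count_overlapping",
                    depletion: bool = False) -> EnrichmentResult:
    """Compare an overlap measure between the observed set and the nulls.

    empirical_p = #{null sets with value >= observed} / k for enrichment
    (<= for depletion); ties count against significance. A zero count is
    reported with ``p_is_upper_bound`` (read "< 1/k").
    """
    if nulls.k < 1:
        raise ValueError("need k >= 1 null sets")
    idx = _TrackIndex(track)
    obs_val = overlap_measure(observed, idx, measure)
    null_vals = np.array([overlap_measure(s, idx, measure)
                          for s in nulls.sets])
    if depletion:
        n_extreme = int((null_vals <= obs_val).sum())
    else:
        n_extreme = int((null_vals >= obs_val).sum())
    null_mean = null_vals.mean()
    ratio = obs_val / null_mean if null_mean > 0 else np.inf
    return EnrichmentResult(
        observed_value=obs_val,
        null_values=null_vals,
        enrichment_ratio=ratio,
        empirical_p=max(n_extreme, 1) / nulls.k if n_extreme == 0
        else n_extreme / nulls.k,
        p_is_upper_bound=n_extreme == 0,
    )


def fisher_enrichment(a: int, b: int, c: int, d: int):
    """Sample odds ratio (a*d)/(b*c) and exact two-sided Fisher P for a
    2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all-zero margin")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return odds, p


def random_cpg_background(results: pd.DataFrame, n: int = 1000,
                          p_floor: float = 0.1, k: int = 100,
                          seed: int = 0) -> list[pd.DataFrame]:
    """k sets of n CpGs sampled (without replacement within a set) from
    sites with case/control P above ``p_floor`` — the large-P background
    used for transcription-factor and co-localization nulls."""
    pool = results[results["p"] > p_floor]
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} sites with P > {p_floor}, need {n}")
    rng = np.random.default_rng(seed)
    return [pool.iloc[rng.choice(len(pool), size=n, replace=False)]
            [["chrom", "pos"]].reset_index(drop=True) for _ in range(k)]


# --------------------------------------------------------------------------
# genic annotation

def annotate_genic(items: pd.DataFrame, gene_models: pd.DataFrame,
                   exons: pd.DataFrame | None = None,
                   promoter_bp: int = 3000,
                   flank_bp: int = 1500) -> pd.DataFrame:
    """Assign a genic category to each site (chrom/pos) or region midpoint.

    Categories, in precedence order: ``promoter`` (within ``promoter_bp`` of
    a TSS), ``exon``, ``intron`` (inside a gene but not an exon),
    ``gene_flank`` (within ``flank_bp`` of a gene start/end), and
    ``distal_intergenic``. The nearest gene id is attached.
    """
    if {"start", "end"}.issubset(items.columns):
        point = ((items["start"] + items["end"]) // 2).to_numpy()
    else:
        point = items["pos"].to_numpy() - 1
    chroms = items["chrom"].to_numpy()

    cats = np.full(len(items), "distal_intergenic", dtype=object)
    nearest = np.full(len(items), "", dtype=object)
    for chrom in np.unique(chroms):
        on = chroms == chrom
        pts = point[on]
        genes = gene_models[gene_models["chrom"] == chrom]
        if len(genes) == 0:
            continue
        tss = genes["tss"].to_numpy()
        gstart = genes["start"].to_numpy()
        gend = genes["end"].to_numpy()
        gids = genes["gene_id"].to_numpy()

        # nearest gene by distance to the gene body
        d = np.maximum.reduce([gstart[None, :] - pts[:, None],
                               pts[:, None] - (gend[None, :] - 1),
                               np.zeros((pts.size, len(genes)), dtype=np.int64)])
        nearest[on] = gids[np.argmin(d, axis=1)]

        in_promoter = (np.abs(pts[:, None] - tss[None, :]) <= promoter_bp).any(axis=1)
        in_gene = ((pts[:, None] >= gstart[None, :])
                   & (pts[:, None] < gend[None, :])).any(axis=1)
        in_flank = d.min(axis=1) <= flank_bp
        in_exon = np.zeros(pts.size, dtype=bool)
        if exons is not None:
            ex = exons[exons["chrom"] == chrom]
            if len(ex):
                in_exon = ((pts[:, None] >= ex["start"].to_numpy()[None, :])
                           & (pts[:, None] < ex["end"].to_numpy()[None, :])).any(axis=1)
        sub = np.full(pts.size, "distal_intergenic", dtype=object)
        sub[in_flank] = "gene_flank"
        sub[in_gene] = "intron"
        sub[in_gene & in_exon] = "exon"
        sub[in_promoter] = "promoter"
        cats[on] = sub
    out = items.copy()
    out["genic_category"] = cats
    out["nearest_gene"] = nearest
    return out
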