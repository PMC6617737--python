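"""Permutation nulls, directionality statistics, cell type-gap reduction,
cross-study concordance binning, and QQ summaries for case/control scans.

The permutation framework shuffles diagnosis labels within cell type
(preserving group sizes and the covariate rows exactly) and re-runs the
chosen per-site test, storing the summaries downstream analyses need: the
top-quantile |statistic|, per-site directions, and the directional-bias
fraction per permutation.

Directionality is tested with a two-sided exact binomial test against 0.5.
Two two-sided rules are available: ``minlike`` (default; sums the
probabilities of all outcomes no more likely than the observed one) and
``doubled`` (twice the smaller tail, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import Design, build_design, site_test_arcsine, site_test_linear
from .io import CountMatrix

__all__ = [
    "permute_diagnosis_labels",
    "PermutationRun",
    "permutation_null_run",
    "binomial_two_sided",
    "directionality_test",
    "cell_type_difference_reduction",
    "concordance_binned",
    "qq_summary",
    "DEFAULT_BIN_EDGES",
]

# external-study P bins on the -log10 scale: (0.1,1], (0.01,0.1], ...
DEFAULT_BIN_EDGES = (0.0, 1.0, 2.0, 3.0, 4.0, np.inf)


# --------------------------------------------------------------------------
# permutations

def permute_diagnosis_labels(samples: pd.DataFrame, seed: int,
                             within: str = "cell_type") -> pd.DataFrame:
    """Shuffle the diagnosis column within each level of ``within``.

    Group sizes are preserved exactly and every other column is untouched.
    """
    if samples["diagnosis"].nunique() < 2:
        raise ValueError("need at least two diagnosis levels to permute")
    rng = np.random.default_rng(seed)
    out = samples.copy()
    diag = out["diagnosis"].to_numpy().copy()
    for _, idx in out.groupby(within).groups.items():
        idx = np.asarray(idx)
        diag[idx] = diag[rng.permutation(idx)]
    out["diagnosis"] = diag
    return out


@dataclass
class PermutationRun:
    """Per-permutation summaries from re-running a site test under shuffled
    diagnosis labels."""

    n_perm: int
    seed: int
    top_abs_stat: np.ndarray          # (n_perm,) top-quantile |stat|
    bias_fraction: np.ndarray         # (n_perm,) fraction of sites hypo in cases
    directions: np.ndarray            # (n_perm, n_tracked) sign of difference
    pvalues: np.ndarray               # (n_perm, n_tracked)
    tracked_sites: pd.DataFrame = field(default_factory=pd.DataFrame)


def permutation_null_run(counts: CountMatrix, samples: pd.DataFrame,
                         covariates: list[str] | None = None,
                         n_perm: int = 100, test: str = "arcsine",
                         seed: int = 0, top_quantile: float = 0.999,
                         tracked_sites: pd.DataFrame | None = None) -> PermutationRun:
    """Re-run the site test ``n_perm`` times with permuted diagnosis labels."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tracked_sites is None:
        tracked_sites = counts.sites
    keys = counts.site_keys()
    track_idx = keys.get_indexer(
        pd.Index(zip(tracked_sites["chrom"], tracked_sites["pos"])))
    if np.any(track_idx < 0):
        raise ValueError("tracked site not present in count matrix")

    top = np.empty(n_perm)
    bias = np.empty(n_perm)
    dirs = np.empty((n_perm, track_idx.size))
    ps = np.empty((n_perm, track_idx.size))
    for i in range(n_perm):
        perm = permute_diagnosis_labels(samples, seed=seed + i)
        design = build_design(perm, "diagnosis", covariates)
        if test == "arcsine":
            res = site_test_arcsine(counts, design)
        elif test == "linear":
            res = site_test_linear(counts.fractions(), counts, design)
        else:
            raise ValueError(f"unknown test {test!r}")
        absstat = np.abs(res["stat"].to_numpy())
        top[i] = np.nanquantile(absstat, top_quantile)
        d = res["direction"].to_numpy()
        nz = d != 0
        bias[i] = (d[nz] < 0).mean() if nz.any() else np.nan
        dirs[i] = d[track_idx]
        ps[i] = res["p"].to_numpy()[track_idx]
    return PermutationRun(n_perm, seed, top, bias, dirs, ps,
                          tracked_sites.reset_index(drop=True))


# --------------------------------------------------------------------------
# exact binomial machinery

def binomial_two_sided(k: int, n: int, p: float = 0.5,
                       method: str = "minlike") -> float:
    """Two-sided exact binomial P of k successes in n trials."""
    if n == 0:
        raise ValueError("n must be > 0")
    if method == "minlike":
        return stats.binomtest(k, n, p).pvalue
    if method == "doubled":
        lower = stats.binom.cdf(k, n, p)
        upper = stats.binom.sf(k - 1, n, p)
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown method {method!r}")


def directionality_test(results: pd.DataFrame, selection=None,
                        method: str = "minlike"):
    """Exact binomial test of hypo- vs hypermethylation in cases.

    ``selection`` is an optional boolean mask or index into ``results``.
    Sites with zero direction are excluded (and counted). Returns
    (n_hypo, n_hyper, fraction_hypo, two_sided_p).
    """
    sub = results if selection is None else results.loc[selection]
    d = sub["direction"].to_numpy()
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("no sites with nonzero direction")
    n_hypo = int((nz < 0).sum())
    n_hyper = int((nz > 0).sum())
    p = binomial_two_sided(n_hypo, nz.size, 0.5, method)
    return n_hypo, n_hyper, n_hypo / nz.size, p


# --------------------------------------------------------------------------
# cell type-gap reduction

def cell_type_difference_reduction(fractions: np.ndarray,
                                   samples: pd.DataFrame,
                                   site_sets: dict[str, np.ndarray],
                                   method: str = "minlike") -> pd.DataFrame:
    """Is the |OLIG2+ - NeuN+| methylation gap larger in controls than cases?

    For each named site set: per site, d_ctrl = |mean(OLIG2,ctrl) -
    mean(NeuN,ctrl)| and d_case likewise; report the fraction of sites with
    d_ctrl > d_case and a two-sided binomial P against 0.5. Ties are
    excluded and counted.
    """
    masks = {}
    for ct in ("NeuN+", "OLIG2+"):
        for dx in ("control", "schizophrenia"):
            m = ((samples["cell_type"] == ct)
                 & (samples["diagnosis"] == dx)).to_numpy()
            if not m.any():
                raise ValueError(f"no samples in group ({ct}, {dx})")
            masks[ct, dx] = m
    with np.errstate(invalid="ignore"):
        gap_ctrl = np.abs(
            np.nanmean(fractions[:, masks["OLIG2+", "control"]], axis=1)
            - np.nanmean(fractions[:, masks["NeuN+", "control"]], axis=1))
        gap_case = np.abs(
            np.nanmean(fractions[:, masks["OLIG2+", "schizophrenia"]], axis=1)
            - np.nanmean(fractions[:, masks["NeuN+", "schizophrenia"]], axis=1))
    rows = []
    for name, idx in site_sets.items():
        gc_, gs_ = gap_ctrl[idx], gap_case[idx]
        ok = np.isfinite(gc_) & np.isfinite(gs_)
        larger = int((gc_[ok] > gs_[ok]).sum())
        smaller = int((gc_[ok] < gs_[ok]).sum())
        ties = int(ok.sum()) - larger - smaller
        n = larger + smaller
        rows.append({
            "set": name, "n": n, "n_ties": ties,
            "n_larger_in_controls": larger,
            "fraction_larger_in_controls": larger / n if n else np.nan,
            "binomial_p": binomial_two_sided(larger, n, 0.5, method)
            if n else np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cross-study concordance

def concordance_binned(results: pd.DataFrame, external: pd.DataFrame,
                       bin_edges=DEFAULT_BIN_EDGES,
                       permutation_run: PermutationRun | None = None,
                       method: str = "minlike") -> pd.DataFrame:
    """Directional concordance with an external study, binned by the
    external P value (bins on the -log10 scale).

    ``external`` needs columns chrom, pos, direction, P. Per bin: the
    fraction of intersected sites whose case/control direction agrees and a
    two-sided binomial P against 0.5. If a permutation run tracking the same
    universe of sites is supplied, the per-bin concordance distribution
    across permutations is attached as a list column.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    merged = results.merge(external, on=["chrom", "pos"],
                           suffixes=("", "_ext"))
    if len(merged) == 0:
        raise ValueError("no common sites with the external study")
    merged = merged[(merged["direction"] != 0)
                    & (merged["direction_ext"] != 0)]
    neglog = -np.log10(merged["P"].to_numpy())
    bin_of = np.digitize(neglog, edges[1:-1], right=True)
    agree = (merged["direction"].to_numpy()
             == merged["direction_ext"].to_numpy())

    perm_bin_frac = None
    if permutation_run is not None:
        pk = pd.Index(zip(permutation_run.tracked_sites["chrom"],
                          permutation_run.tracked_sites["pos"]))
        loc = pk.get_indexer(pd.Index(zip(merged["chrom"], merged["pos"])))
        usable = loc >= 0
        perm_dirs = permutation_run.directions[:, loc[usable]]
        ext_dir = merged["direction_ext"].to_numpy()[usable]
        perm_bin_frac = []
        for b in range(len(edges) - 1):
            inbin = (bin_of == b)[usable]
            if inbin.sum() == 0:
                perm_bin_frac.append(np.full(permutation_run.n_perm, np.nan))
            else:
                perm_bin_frac.append(
                    (perm_dirs[:, inbin] == ext_dir[inbin]).mean(axis=1))

    rows = []
    for b in range(len(edges) - 1):
        inbin = bin_of == b
        n = int(inbin.sum())
        n_agree = int(agree[inbin].sum())
        rows.append({
            "bin_lo_neglog10p": edges[b],
            "bin_hi_neglog10p": edges[b + 1],
            "n": n,
            "n_concordant": n_agree,
            "fraction_concordant": n_agree / n if n else np.nan,
            "binomial_p": binomial_two_sided(n_agree, n, 0.5, method)
            if n else np.nan,
            "empty": n == 0,
            "perm_fractions": (perm_bin_frac[b]
                               if perm_bin_frac is not None else None),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# QQ summary

def qq_summary(p):
    """Sorted observed vs expected -log10 P and the genomic inflation
    factor lambda (median chi-square ratio)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty P list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must be in (0, 1]")
    obs = np.sort(-np.log10(p))
    exp = np.sort(-np.log10((np.arange(1, p.size + 1) - 0.5) / p.size))
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    return exp, obs, lam
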