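"""Per-CpG covariate-adjusted differential methylation testing.

Two site-level tests are provided:

* :func:`site_test_arcsine` — a variance-stabilized weighted regression in
  the style of beta-binomial WGBS methods ("DSS-style"): per-site fractional
  counts are transformed with the arcsine link
  ``Y_i = arcsin(2 (X_i + 0.5) / (N_i + 1) - 1)``, under which binomial
  sampling gives Var(Y_i) ~ 1/N_i approximately independent of the mean.
  Coefficients are then estimated by weighted least squares with weights
  N_i and tested with a Wald statistic against the normal reference.
* :func:`site_test_linear` — ordinary least squares on raw fractional
  methylation values; its coefficient is directly interpretable as a
  difference in methylation fraction.

Sign convention (stated in all output headers): the reference levels are
``NeuN+`` (cell type) and ``control`` (diagnosis); a positive coefficient /
statistic means *higher* methylation in the non-reference level (OLIG2+,
resp. schizophrenia). ``direction = sign(mean_g2 - mean_g1)`` where group 1
is the reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

__all__ = [
    "Design",
    "build_design",
    "filter_polymorphic",
    "filter_coverage",
    "site_test_arcsine",
    "site_test_linear",
    "adjust_pvalues",
    "arcsine_transform",
    "RESULT_COLUMNS",
    "REFERENCE_LEVELS",
]

REFERENCE_LEVELS = {"cell_type": "NeuN+", "diagnosis": "control"}

RESULT_COLUMNS = ["chrom", "pos", "coef", "stat", "p", "q_bh", "p_bonf",
                  "mean_g1", "mean_g2", "direction", "n_used"]

_CHUNK = 8192  # sites per batched linear-algebra block


# --------------------------------------------------------------------------
# design matrices

@dataclass
class Design:
    """A fixed-effects design aligned with the columns of a CountMatrix.

    ``matrix`` holds intercept, the reference-coded target term, and any
    covariate columns (categoricals one-hot minus reference, continuous
    as-is). ``group_ref``/``group_alt`` are boolean masks of the samples in
    the target's reference and non-reference level.
    """

    matrix: np.ndarray
    columns: list[str]
    target: str
    group_ref: np.ndarray
    group_alt: np.ndarray
    skip_log: dict = field(default_factory=dict)

    @property
    def target_index(self) -> int:
        return self.columns.index(self.target)


def build_design(samples: pd.DataFrame, target: str,
                 covariates: list[str] | None = None) -> Design:
    """Build a reference-coded design matrix from a covariate table.

    Categorical covariates are one-hot coded minus their first observed
    level; continuous covariates (the genetic PCs, conversion rate) enter
    as-is. Empty levels are dropped; a rank-deficient result is an error.
    """
    covariates = list(covariates or [])
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    ref = REFERENCE_LEVELS.get(target)
    tvals = samples[target].astype(str)
    levels = [lv for lv in pd.unique(tvals) if lv != ref]
    if ref is None:
        ref = pd.unique(tvals)[0]
        levels = [lv for lv in pd.unique(tvals) if lv != ref]
    if len(levels) != 1:
        raise ValueError(f"target {target!r} must have exactly 2 levels, "
                         f"got {[ref] + levels}")
    alt = levels[0]
    cols.append((tvals == alt).to_numpy(dtype=float))
    target_col = f"{target}[{alt}]"
    names.append(target_col)

    for cov in covariates:
        v = samples[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
            names.append(cov)
        else:
            vals = v.astype(str)
            for lv in pd.unique(vals)[1:]:
                cols.append((vals == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")

    mat = np.column_stack(cols)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Design(mat, names, target_col,
                  group_ref=(tvals == ref).to_numpy(),
                  group_alt=(tvals == alt).to_numpy())


# --------------------------------------------------------------------------
# site filters

def filter_polymorphic(counts: CountMatrix, snp_positions: dict) -> CountMatrix:
    """Drop CpGs whose dyad overlaps a SNP.

    ``snp_positions`` maps chromosome -> iterable of 1-based SNP positions.
    A CpG at position p is removed if a SNP hits p or p+1 (either strand of
    the CG dyad).
    """
    chrom = counts.sites["chrom"].to_numpy()
    pos = counts.sites["pos"].to_numpy()
    drop = np.zeros(len(pos), dtype=bool)
    for c, snps in snp_positions.items():
        snps = np.unique(np.asarray(list(snps), dtype=np.int64))
        if snps.size == 0:
            continue
        on = chrom == c
        hit = (np.isin(pos[on], snps) | np.isin(pos[on] + 1, snps))
        drop[np.flatnonzero(on)[hit]] = True
    return counts.subset_sites(~drop)


def filter_coverage(counts: CountMatrix, min_depth: int, min_fraction: float,
                    groups: dict[str, np.ndarray]) -> CountMatrix:
    """Keep sites covered >= min_depth in >= min_fraction of every group.

    ``groups`` maps group name -> boolean mask over samples (e.g. the
    disease-control groups). The conventional threshold is 20x in at least
    80% of samples per group.
    """
    if not (min_depth >= 1 and 0 < min_fraction <= 1):
        raise ValueError("min_depth >= 1 and 0 < min_fraction <= 1 required")
    keep = np.ones(counts.n_sites, dtype=bool)
    for name, mask in groups.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} has no samples")
        frac_ok = (counts.N[:, mask] >= min_depth).mean(axis=1)
        keep &= frac_ok >= min_fraction
    return counts.subset_sites(keep)


# --------------------------------------------------------------------------
# site tests

def arcsine_transform(X: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Y = arcsin(2 (X+0.5)/(N+1) - 1); the 0.5/1 pseudocounts keep the
    argument strictly inside (-1, 1)."""
    return np.arcsin(2.0 * (X + 0.5) / (N + 1.0) - 1.0)


def _group_means(counts: CountMatrix, design: Design):
    frac = counts.fractions()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN groups
        g1 = np.nanmean(frac[:, design.group_ref], axis=1)
        g2 = np.nanmean(frac[:, design.group_alt], axis=1)
    return g1, g2


def _batched_wls(Y, W, D):
    """Weighted LS of each row of Y on D with per-row weights W.

    Returns (beta, Ainv, ok): coefficient matrix, (D'WD)^-1 per site (the
    known-variance covariance when Var(y_i) = 1/w_i), and a mask of sites
    whose weighted normal equations were invertible.
    """
    m, p = Y.shape[0], D.shape[1]
    A = np.einsum("ip,si,iq->spq", D, W, D, optimize=True)
    b = np.einsum("ip,si->sp", D, W * Y, optimize=True)
    ok = np.abs(np.linalg.det(A)) > 1e-10
    beta = np.full((m, p), np.nan)
    Ainv = np.full((m, p, p), np.nan)
    if ok.any():
        Ainv[ok] = np.linalg.inv(A[ok])
        beta[ok] = np.einsum("spq,sq->sp", Ainv[ok], b[ok])
    return beta, Ainv, ok


def _finalize(counts, design, coef, stat, p, n_used, skipped) -> pd.DataFrame:
    g1, g2 = _group_means(counts, design)
    q_bh = np.full_like(p, np.nan)
    p_bonf = np.full_like(p, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q_bh[tested] = adjust_pvalues(p[tested], "bh")
        p_bonf[tested] = adjust_pvalues(p[tested], "bonferroni")
    out = pd.DataFrame({
        "chrom": counts.sites["chrom"],
        "pos": counts.sites["pos"],
        "coef": coef, "stat": stat, "p": p,
        "q_bh": q_bh, "p_bonf": p_bonf,
        "mean_g1": g1, "mean_g2": g2,
        "direction": np.sign(g2 - g1),
        "n_used": n_used,
    })
    out.attrs["skipped"] = skipped
    out.attrs["target"] = design.target
    out.attrs["sign_convention"] = (
        "positive coef/stat = higher methylation in the non-reference level")
    return out


def site_test_arcsine(counts: CountMatrix, design: Design) -> pd.DataFrame:
    """DSS-style arcsine variance-stabilized weighted regression per CpG.

    Weights are the read depths N_i (missing cells weight 0); the Wald
    statistic coef/SE is referred to the standard normal. Sites with < 2
    covered samples in either target level, or a rank-deficient per-site
    design after missingness, are skipped and counted in
    ``result.attrs['skipped']``.
    """
    D = design.matrix
    j = design.target_index
    m = counts.n_sites
    coef = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    p = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    skipped = {"too_few_per_level": 0, "rank_deficient": 0}

    covered = counts.N > 0
    enough = ((covered[:, design.group_ref].sum(axis=1) >= 2)
              & (covered[:, design.group_alt].sum(axis=1) >= 2))
    skipped["too_few_per_level"] = int((~enough).sum())
    Yall = arcsine_transform(counts.X, counts.N)

    idx = np.flatnonzero(enough)
    for lo in range(0, idx.size, _CHUNK):
        sel = idx[lo:lo + _CHUNK]
        W = counts.N[sel].astype(float)
        Y = np.where(W > 0, Yall[sel], 0.0)
        beta, Ainv, ok = _batched_wls(Y, W, D)
        skipped["rank_deficient"] += int((~ok).sum())
        se = np.sqrt(Ainv[:, j, j])
        z = beta[:, j] / se
        coef[sel] = beta[:, j]
        stat[sel] = z
        p[sel] = np.where(ok, np.clip(2.0 * stats.norm.sf(np.abs(z)),
                                      np.nextafter(0, 1), 1.0), np.nan)
        n_used[sel] = (W > 0).sum(axis=1)
    return _finalize(counts, design, coef, stat, p, n_used, skipped)


def site_test_linear(fractions: np.ndarray, counts: CountMatrix,
                     design: Design) -> pd.DataFrame:
    """Per-CpG OLS of fractional methylation on the design.

    ``fractions`` is the (sites x samples) fraction matrix with NaN where
    there is no observation (see :meth:`CountMatrix.fractions`). The target
    coefficient is in fraction units; P values use the t reference with
    n_used - p degrees of freedom. Sites with fewer observations than design
    columns or zero residual variance are skipped (counted, not P=0).
    """
    D = design.matrix
    j = design.target_index
    m = fractions.shape[0]
    pcols = D.shape[1]
    coef = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    p = np.full(m, np.nan)
    n_used = (~np.isnan(fractions)).sum(axis=1)
    skipped = {"too_few_obs": 0, "rank_deficient": 0, "zero_residual_variance": 0}

    covered = ~np.isnan(fractions)
    enough = ((covered[:, design.group_ref].sum(axis=1) >= 2)
              & (covered[:, design.group_alt].sum(axis=1) >= 2)
              & (n_used > pcols))
    skipped["too_few_obs"] = int((~enough).sum())

    idx = np.flatnonzero(enough)
    for lo in range(0, idx.size, _CHUNK):
        sel = idx[lo:lo + _CHUNK]
        W = covered[sel].astype(float)
        Y = np.nan_to_num(fractions[sel])
        beta, Ainv, ok = _batched_wls(Y, W, D)
        skipped["rank_deficient"] += int((~ok).sum())
        fit = np.einsum("sp,ip->si", np.nan_to_num(beta), D)
        rss = (W * (Y - fit) ** 2).sum(axis=1)
        df = W.sum(axis=1) - pcols
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma2 = rss / df
        # residuals from an exact fit are pure float noise (~1e-16 on the
        # fraction scale); genuine residual variance is far above this
        nonzero = sigma2 > 1e-20
        skipped["zero_residual_variance"] += int((ok & ~nonzero).sum())
        use = ok & nonzero
        se = np.sqrt(sigma2 * Ainv[:, j, j])
        t = beta[:, j] / se
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        coef[sel] = np.where(use, beta[:, j], np.nan)
        stat[sel] = np.where(use, t, np.nan)
        p[sel] = np.where(use, np.clip(pv, np.nextafter(0, 1), 1.0), np.nan)
    return _finalize(counts, design, coef, stat, p, n_used, skipped)


# --------------------------------------------------------------------------
# multiple testing

def adjust_pvalues(p, method: str) -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni min(m*p, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN P value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must be in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown method {method!r}")
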