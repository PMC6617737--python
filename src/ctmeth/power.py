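"""EWAS power simulations for small-cohort case/control methylation scans.

Simulation 1 — per-CpG power. Each simulated CpG draws a parametric control
mean from a truncated normal(0.7, 0.05) on [0.1, 0.9] (mirroring the skewed
genome-wide distribution of fractional methylation), a parametric SD from
uniform(1e-7, 0.2), and a case-control effect from uniform(0, 0.20). Control
individuals (default n=25) are drawn from truncnorm(mean, SD) on [0, 1] and
cases (default n=28) from truncnorm(mean + effect, SD) on [0, 1]; fractional
methylation is regressed on the diagnosis indicator and the two-sided P
recorded. Binning the drawn effects against P thresholds gives the power
heatmap.

Simulation 2 — top-k false discovery rate under a polygenic architecture.
``n_causal`` (default 5000) CpGs receive effects drawn from a
Beta(parameter1, parameter2) distribution; their P values come from the
simulation-1 cohort model. The remaining ``n_total - n_causal`` (default
10,000,000 total) null CpGs receive uniform(0, 1] P values. All sites are
ranked ascending and FDR = 1 - (#causal in top k)/k, default k = 1000. A
grid search over (parameter1, parameter2) in [0.1, 1.5] x [20, 51] locates
the effect-size architectures consistent with a target top-k FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CohortSimConfig",
    "truncated_normal",
    "simulate_cpg_scan",
    "PowerGrid",
    "power_heatmap",
    "TopKFdrResult",
    "simulate_topk_fdr",
    "fdr_grid_search",
]


@dataclass
class CohortSimConfig:
    """Generative parameters for the cohort power model (fractions)."""

    n_sims: int = 100_000
    n_controls: int = 25
    n_cases: int = 28
    mean_loc: float = 0.7
    mean_scale: float = 0.05
    mean_bounds: tuple[float, float] = (0.1, 0.9)
    sd_range: tuple[float, float] = (1e-7, 0.2)
    effect_range: tuple[float, float] = (0.0, 0.20)
    individual_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_cases < 2:
            raise ValueError("group sizes must be >= 2")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


def truncated_normal(loc, scale, low, high, size, rng) -> np.ndarray:
    """Exact truncated-normal sampling by inverse CDF on [low, high].

    ``loc``/``scale`` broadcast against ``size``; reproducible under the
    supplied generator.
    """
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    a = special.ndtr((low - loc) / scale)
    b = special.ndtr((high - loc) / scale)
    u = rng.uniform(size=size)
    # guard against CDF underflow when loc is far outside [low, high] with
    # tiny scale: the mass collapses onto the nearest bound
    q = np.clip(a + u * (b - a), 1e-300, 1.0 - 1e-16)
    x = np.clip(loc + scale * special.ndtri(q), low, high)
    return np.where(np.isfinite(x), x, np.clip(loc, low, high))


def simulate_cpg_scan(config: CohortSimConfig, seed: int = 0,
                      effects: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate per-CpG case/control scans; returns columns effect, p.

    The per-CpG regression of fraction on the diagnosis indicator is
    computed in its equivalent pooled two-sample t form (identical
    coefficient, statistic, and P), vectorized across CpGs.
    """
    rng = np.random.default_rng(seed)
    m = config.n_sims if effects is None else len(np.asarray(effects))
    lo, hi = config.mean_bounds
    ctrl_mean = truncated_normal(config.mean_loc, config.mean_scale,
                                 lo, hi, m, rng)
    sd = rng.uniform(*config.sd_range, size=m)
    if effects is None:
        effects = rng.uniform(*config.effect_range, size=m)
    else:
        effects = np.asarray(effects, dtype=float)
    ilo, ihi = config.individual_bounds
    n1, n2 = config.n_controls, config.n_cases
    ctrl = truncated_normal(ctrl_mean[:, None], sd[:, None], ilo, ihi,
                            (m, n1), rng)
    case = truncated_normal((ctrl_mean + effects)[:, None], sd[:, None],
                            ilo, ihi, (m, n2), rng)

    m1, m2 = ctrl.mean(axis=1), case.mean(axis=1)
    v1 = ctrl.var(axis=1, ddof=1)
    v2 = case.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    # degenerate draws (SD ~ 0 and effect 0 -> 0/0) are unambiguous nulls
    p = np.where(np.isfinite(t), p, 1.0)
    return pd.DataFrame({"effect": effects, "p": np.clip(p, 1e-300, 1.0),
                         "coef": m2 - m1, "stat": t})


@dataclass
class PowerGrid:
    effect_bin_edges: np.ndarray
    p_thresholds: np.ndarray
    power: np.ndarray          # (n_bins, n_thresholds)
    n_per_bin: np.ndarray
    flagged: np.ndarray        # bins with < 100 sims

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.n_per_bin)):
            for jt, thr in enumerate(self.p_thresholds):
                rows.append({
                    "effect_lo": self.effect_bin_edges[i],
                    "effect_hi": self.effect_bin_edges[i + 1],
                    "p_threshold": thr,
                    "power": self.power[i, jt],
                    "n": self.n_per_bin[i],
                    "flagged": bool(self.flagged[i]),
                })
        return pd.DataFrame(rows)


def power_heatmap(scan: pd.DataFrame, effect_bins, p_thresholds) -> PowerGrid:
    """Fraction of simulated CpGs per effect bin reaching each P threshold."""
    edges = np.asarray(effect_bins, dtype=float)
    thrs = np.asarray(p_thresholds, dtype=float)
    eff = scan["effect"].to_numpy()
    p = scan["p"].to_numpy()
    nb = len(edges) - 1
    power = np.full((nb, len(thrs)), np.nan)
    n_per_bin = np.zeros(nb, dtype=int)
    for i in range(nb):
        inbin = (eff >= edges[i]) & (eff < edges[i + 1])
        n_per_bin[i] = inbin.sum()
        if n_per_bin[i]:
            power[i] = [(p[inbin] < thr).mean() for thr in thrs]
    return PowerGrid(edges, thrs, power, n_per_bin, n_per_bin < 100)


@dataclass
class TopKFdrResult:
    parameter1: float
    parameter2: float
    fdr: float
    fdr_reps: np.ndarray
    tp_effects: np.ndarray = field(default_factory=lambda: np.array([]))
    tp_pvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def simulate_topk_fdr(parameter1: float, parameter2: float,
                      n_causal: int = 5000, n_total: int = 10_000_000,
                      k: int = 1000, cohort: CohortSimConfig | None = None,
                      reps: int = 1, seed: int = 0) -> TopKFdrResult:
    """Top-k FDR of a genome-wide scan with Beta-distributed causal effects.

    Per replicate: draw ``n_causal`` effects from Beta(parameter1,
    parameter2), obtain their P values through the cohort generative model,
    draw ``n_total - n_causal`` null P values uniform on (0, 1], rank all
    ascending (stable ties) and compute FDR = 1 - (#causal in top k)/k.
    The true-positive effect sizes and P values inside the top k of the last
    replicate are retained for downstream histograms.
    """
    if not (parameter1 > 0 and parameter2 > 0):
        raise ValueError("Beta parameters must be positive")
    if n_causal > n_total:
        raise ValueError("n_causal must be <= n_total")
    if k > n_total:
        raise ValueError("k must be <= n_total")
    if cohort is None:
        cohort = CohortSimConfig(n_sims=n_causal)
    rng = np.random.default_rng(seed)
    fdrs = np.empty(reps)
    tp_eff = tp_p = np.array([])
    for r in range(reps):
        effects = rng.beta(parameter1, parameter2, size=n_causal)
        scan = simulate_cpg_scan(cohort, seed=int(rng.integers(2**31)),
                                 effects=effects)
        causal_p = scan["p"].to_numpy()
        null_p = rng.uniform(size=n_total - n_causal)
        allp = np.concatenate([causal_p, null_p])
        top = np.argpartition(allp, k - 1)[:k]
        causal_in_top = top[top < n_causal]
        fdrs[r] = 1.0 - causal_in_top.size / k
        tp_eff = effects[causal_in_top]
        tp_p = causal_p[causal_in_top]
    return TopKFdrResult(parameter1, parameter2, float(fdrs.mean()), fdrs,
                         tp_eff, tp_p)


def fdr_grid_search(parameter1_values, parameter2_values,
                    target_fdr: float = 0.5, tolerance: float = 0.05,
                    n_causal: int = 5000, n_total: int = 10_000_000,
                    k: int = 1000, cohort: CohortSimConfig | None = None,
                    reps: int = 1, seed: int = 0):
    """Evaluate the top-k FDR over a Beta-parameter grid.

    Returns (grid, band): ``grid`` is a DataFrame with one row per cell
    (parameter1, parameter2, fdr, fdr_sd); ``band`` is the list of
    :class:`TopKFdrResult` for cells with |FDR - target| <= tolerance,
    carrying the true-positive effect/P distributions inside the top k.
    """
    results = []
    rng = np.random.default_rng(seed)
    for p1 in parameter1_values:
        for p2 in parameter2_values:
            results.append(simulate_topk_fdr(
                p1, p2, n_causal=n_causal, n_total=n_total, k=k,
                cohort=cohort, reps=reps, seed=int(rng.integers(2**31))))
    grid = pd.DataFrame({
        "parameter1": [r.parameter1 for r in results],
        "parameter2": [r.parameter2 for r in results],
        "fdr": [r.fdr for r in results],
        "fdr_sd": [r.fdr_reps.std(ddof=1) if len(r.fdr_reps) > 1 else np.nan
                   for r in results],
    })
    band = [r for r in results if abs(r.fdr - target_fdr) <= tolerance]
    return grid, band
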