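"""Synthetic genomes, cohorts, methylomes, GWAS and external EWAS tables.

The generator emulates the statistical structure of a sorted-nuclei WGBS
case/control study of two brain cell types:

* two cell types (NeuN+ neurons, OLIG2+ oligodendrocytes) x two diagnoses
  (control, schizophrenia), with cohort sizes defaulting to 25/28 (NeuN+
  control/case) and 20/22 (OLIG2+);
* large cell type methylation differences — planted cell type DMPs with a
  mean absolute difference of 0.326, 64% of them hypermethylated in NeuN+;
* small disease effects (~6% mean absolute difference) with cell
  type-opposite directionality: 93% hypomethylated in schizophrenia at NeuN+
  szDMPs, 75.9% hypermethylated at OLIG2+ szDMPs;
* nuisance covariates (age class, sex, hemisphere, PMI class, conversion
  rate, brain bank, 10 genetic PCs), with zero methylation effect by
  default so planted signal is isolated;
* read depth ~ negative binomial (mean 25 by default) and methylated reads
  binomial given depth and the per-individual fraction;
* GWAS SNPs whose odds ratios are inflated near planted disease sites.

Every planted effect is recorded in a :class:`TruthTable`; all generators
are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix
from .power import truncated_normal

__all__ = [
    "SyntheticGenome",
    "CohortDesign",
    "EffectConfig",
    "GwasSimConfig",
    "TruthTable",
    "generate_genome",
    "generate_cohort",
    "generate_methylomes",
    "generate_gwas_summary",
    "generate_external_ewas",
]

CELL_TYPES = ("NeuN+", "OLIG2+")
DIAGNOSES = ("control", "schizophrenia")


# --------------------------------------------------------------------------
# genome

@dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    sequence: dict[str, str]
    cpg_positions: dict[str, np.ndarray]      # 1-based position of the C
    gene_models: pd.DataFrame                 # chrom,start,end,strand,tss,gene_id
    exons: pd.DataFrame                       # chrom,start,end,gene_id
    chromatin_tracks: dict[str, pd.DataFrame] # name -> chrom,start,end

    def __post_init__(self) -> None:
        for chrom, pos in self.cpg_positions.items():
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"cpg positions not strictly increasing on {chrom}")
            if pos.size and pos[-1] > self.chrom_sizes[chrom]:
                raise ValueError(f"cpg position beyond {chrom} length")
        for chrom, seq in self.sequence.items():
            if len(seq) != self.chrom_sizes[chrom]:
                raise ValueError(f"sequence length mismatch on {chrom}")

    def all_sites(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"chrom": c, "pos": p})
                  for c, p in sorted(self.cpg_positions.items())]
        return pd.concat(frames, ignore_index=True)


def _remove_cg(seq: np.ndarray) -> np.ndarray:
    """Replace the G of every CG dinucleotide with A (repeat to fixpoint)."""
    while True:
        hits = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        if hits.size == 0:
            return seq
        seq[hits + 1] = b"A"


def generate_genome(n_chrom: int = 1, chrom_len: int = 1_000_000,
                    cpg_density: float = 0.01, seed: int = 0,
                    cluster_rate: float = 1 / 3000,
                    genes_per_bp: float = 1 / 20_000,
                    enhancer_fraction: float = 0.02) -> SyntheticGenome:
    """Generate a random genome with CpGs planted at a controlled density.

    The background sequence is i.i.d. ACGT with accidental CG dinucleotides
    removed; CG pairs are then written at ~``cpg_density`` per bp, plus
    occasional dense clusters (5-8 CpGs spaced 6-10 bp, at ``cluster_rate``
    per bp) so that DMR-scale CpG clusters exist. CpG positions are finally
    re-derived by scanning the sequence for "CG". Gene models and chromatin
    tracks are non-overlapping within each track.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10000")
    min_gene = 2000
    if chrom_len < min_gene + 200:
        raise ValueError("chrom_len too small to place any gene model")
    rng = np.random.default_rng(seed)
    chrom_sizes, sequence, cpg_positions = {}, {}, {}
    genes, exons, enhancers = [], [], []
    gene_counter = 0
    for ci in range(1, n_chrom + 1):
        chrom = f"chr{ci}"
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len)
        seq = _remove_cg(seq)

        # scattered CpGs, then clusters; planted Cs must be >= 2 bp apart
        singles = np.flatnonzero(rng.random(chrom_len - 1) < cpg_density)
        anchors = np.flatnonzero(rng.random(chrom_len) < cluster_rate)
        clustered = []
        for a in anchors:
            n_c = int(rng.integers(5, 9))
            gaps = rng.integers(6, 11, size=n_c - 1)
            clustered.append(a + np.r_[0, np.cumsum(gaps)])
        planted = np.unique(np.concatenate([singles] + clustered)) \
            if clustered else np.unique(singles)
        planted = planted[planted < chrom_len - 1]
        if planted.size:
            keep = np.r_[True, np.diff(planted) >= 2]
            planted = planted[keep]
            seq[planted] = b"C"
            seq[planted + 1] = b"G"

        cg = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        chrom_sizes[chrom] = chrom_len
        sequence[chrom] = seq.tobytes().decode("ascii")
        cpg_positions[chrom] = cg + 1  # 1-based position of the C

        # gene models: sequential placement with random gaps
        n_genes = max(1, int(round(chrom_len * genes_per_bp)))
        cursor = int(rng.integers(100, 2000))
        for _ in range(n_genes):
            length = int(rng.integers(min_gene, 8001))
            if cursor + length > chrom_len - 100:
                break
            start, end = cursor, cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            gid = f"gene{gene_counter}"
            genes.append({"chrom": chrom, "start": start, "end": end,
                          "strand": strand,
                          "tss": start if strand == "+" else end - 1,
                          "gene_id": gid})
            n_ex = int(rng.integers(2, 5))
            ex_starts = np.sort(rng.integers(start, end - 300, size=n_ex))
            for es in ex_starts:
                exons.append({"chrom": chrom, "start": int(es),
                              "end": int(es) + 300, "gene_id": gid})
            cursor = end + int(rng.integers(1500, 6000))
        if not any(g["chrom"] == chrom for g in genes):
            raise ValueError("chrom_len too small to place any gene model")

        # enhancer-like track covering ~enhancer_fraction of the chromosome
        covered, cursor = 0, int(rng.integers(0, 3000))
        target = chrom_len * enhancer_fraction
        while covered < target and cursor < chrom_len - 2000:
            length = int(rng.integers(500, 2001))
            enhancers.append({"chrom": chrom, "start": cursor,
                              "end": cursor + length})
            covered += length
            cursor += length + int(rng.integers(2000, 20_000))

    return SyntheticGenome(
        chrom_sizes, sequence, cpg_positions,
        pd.DataFrame(genes), pd.DataFrame(exons),
        {"brain_enhancer": pd.DataFrame(enhancers)},
    )


# --------------------------------------------------------------------------
# cohort

@dataclass
class CohortDesign:
    """Cohort layout: samples per (cell type, diagnosis) group, covariate
    level sets/probabilities, and the read-depth distribution."""

    group_sizes: dict = field(default_factory=lambda: {
        ("NeuN+", "control"): 25, ("NeuN+", "schizophrenia"): 28,
        ("OLIG2+", "control"): 20, ("OLIG2+", "schizophrenia"): 22,
    })
    covariate_levels: dict = field(default_factory=lambda: {
        "age_class": (["young", "mid", "old"], [0.3, 0.4, 0.3]),
        "sex": (["M", "F"], [0.6, 0.4]),
        "hemisphere": (["L", "R"], [0.5, 0.5]),
        "pmi_class": (["short", "long"], [0.5, 0.5]),
        "brain_bank": (["bankA", "bankB", "bankC"], [0.4, 0.35, 0.25]),
    })
    coverage_mean: float = 25.0
    coverage_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {key} must have >= 2 samples")
        if self.coverage_mean <= 0:
            raise ValueError("coverage mean must be > 0")


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """One covariate row per sample, with exact group sizes by design."""
    rng = np.random.default_rng(design.seed)
    rows = []
    i = 0
    for (ct, dx), n in design.group_sizes.items():
        for _ in range(n):
            i += 1
            row = {"sample_id": f"s{i:03d}", "cell_type": ct, "diagnosis": dx}
            for col, (levels, probs) in design.covariate_levels.items():
                row[col] = rng.choice(levels, p=probs)
            row["conversion_rate"] = float(rng.uniform(0.985, 0.999))
            for j in range(1, 11):
                row[f"pc{j}"] = float(rng.normal())
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["design"] = design
    return out


# --------------------------------------------------------------------------
# methylomes

@dataclass
class EffectConfig:
    """Planted-effect structure for :func:`generate_methylomes`.

    Absolute cell type differences are drawn from a normal centered on
    ``mean_abs_delta`` truncated symmetrically at +-``delta_halfwidth`` (so
    the planted mean equals ``mean_abs_delta`` exactly); disease effects
    likewise around ``mean_abs_beta``. Signs follow the stated directional
    fractions. Covariate nuisance effects default to zero so the planted
    signal is isolated.
    """

    frac_celltype_dmp: float = 0.10
    mean_abs_delta: float = 0.326
    delta_halfwidth: float = 0.25
    delta_sd: float = 0.10
    neun_hyper_frac: float = 0.64
    n_szdmp_per_celltype: int = 50
    szdmp_in_celltype_dmp_frac: float = 0.5
    mean_abs_beta: float = 0.06
    beta_halfwidth: float = 0.04
    beta_sd: float = 0.03
    neun_hypo_frac: float = 0.93
    olig2_hyper_frac: float = 0.759
    n_planted_dmrs: int = 20
    dmr_n_cpg: int = 5
    dmr_span: int = 50
    dmr_abs_delta: float | None = None  # None: draw from the DMP distribution
    individual_sd: float = 0.05
    covariate_effects: dict = field(default_factory=dict)  # col -> sd

    def __post_init__(self) -> None:
        for name, val in [("mean_abs_delta", self.mean_abs_delta),
                          ("mean_abs_beta", self.mean_abs_beta)]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_abs_delta + self.delta_halfwidth > 1:
            raise ValueError("cell type effect magnitude can exceed 1")
        for frac in (self.frac_celltype_dmp, self.neun_hyper_frac,
                     self.neun_hypo_frac, self.olig2_hyper_frac,
                     self.szdmp_in_celltype_dmp_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class TruthTable:
    """Planted effects, realized exactly as applied to the group means."""

    sites: pd.DataFrame       # chrom,pos,is_celltype_dmp,celltype_delta,
                              # is_szdmp,sz_delta,cell_type_of_effect
    planted_dmrs: pd.DataFrame  # chrom,start,end,n_cpg,delta

    def __post_init__(self) -> None:
        if np.any(np.abs(self.sites["celltype_delta"]) > 1):
            raise ValueError("|celltype_delta| > 1")
        if np.any(np.abs(self.sites["sz_delta"]) > 1):
            raise ValueError("|sz_delta| > 1")
        bad = (~self.sites["is_szdmp"]) & (self.sites["sz_delta"] != 0)
        if bad.any():
            raise ValueError("sz effect at a non-szDMP site")


def _signed_magnitudes(n, mean, sd, halfwidth, positive_frac, rng):
    mags = truncated_normal(mean, sd, mean - halfwidth, mean + halfwidth,
                            n, rng)
    signs = np.where(rng.random(n) < positive_frac, 1.0, -1.0)
    return mags * signs


def _find_dmr_candidates(sites: pd.DataFrame, n_cpg: int, span: int):
    """Indices (into sites) of disjoint runs of n_cpg CpGs within span bp."""
    runs = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx0 = grp.index.to_numpy()
        i = 0
        while i + n_cpg - 1 < pos.size:
            if pos[i + n_cpg - 1] - pos[i] <= span - 1:
                runs.append(idx0[i:i + n_cpg])
                i += n_cpg  # disjoint runs
            else:
                i += 1
    return runs


def generate_methylomes(genome: SyntheticGenome, samples: pd.DataFrame,
                        effects: EffectConfig | None = None,
                        seed: int = 0) -> tuple[CountMatrix, TruthTable]:
    """Simulate per-sample CpG counts with planted effects.

    Per CpG: a baseline fraction from truncated normal(0.7, 0.05) on
    [0.1, 0.9]; group means are the baseline split symmetrically by the
    planted cell type delta (the pair shifted, never clipped, so the
    realized difference equals the planted delta) plus the disease beta in
    the affected cell type (clipped into [0.005, 0.995] with the realized
    beta recorded); per-individual fractions are truncated normal around
    the group mean on [0, 1]; read depth is negative binomial and
    methylated reads binomial.
    """
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    sites = genome.all_sites()
    m = len(sites)
    n = len(samples)

    mu = truncated_normal(0.7, 0.05, 0.1, 0.9, m, rng)

    # --- cell type DMPs: planted DMR members first, then scattered sites
    delta = np.zeros(m)
    is_ct = np.zeros(m, dtype=bool)
    dmr_rows = []
    if effects.n_planted_dmrs > 0:
        candidates = _find_dmr_candidates(sites, effects.dmr_n_cpg,
                                          effects.dmr_span)
        rng.shuffle(candidates)
        for run in candidates[:effects.n_planted_dmrs]:
            if effects.dmr_abs_delta is None:
                d = float(_signed_magnitudes(
                    1, effects.mean_abs_delta, effects.delta_sd,
                    effects.delta_halfwidth, 1 - effects.neun_hyper_frac,
                    rng)[0])
            else:
                sign = 1.0 if rng.random() >= effects.neun_hyper_frac else -1.0
                d = sign * effects.dmr_abs_delta
            delta[run] = d
            is_ct[run] = True
            pos = sites.loc[run, "pos"]
            dmr_rows.append({"chrom": sites.loc[run[0], "chrom"],
                             "start": int(pos.min()) - 1,
                             "end": int(pos.max()),
                             "n_cpg": len(run), "delta": d})
    n_scatter = int(round(effects.frac_celltype_dmp * m))
    free = np.flatnonzero(~is_ct)
    if n_scatter > 0 and free.size:
        pick = rng.choice(free, size=min(n_scatter, free.size), replace=False)
        # delta is OLIG2 - NeuN: NeuN-hypermethylated DMPs have delta < 0
        delta[pick] = _signed_magnitudes(
            pick.size, effects.mean_abs_delta, effects.delta_sd,
            effects.delta_halfwidth, 1 - effects.neun_hyper_frac, rng)
        is_ct[pick] = True

    # --- szDMPs per cell type, preferentially inside cell type DMPs
    beta = np.zeros(m)
    is_sz = np.zeros(m, dtype=bool)
    sz_ct = np.full(m, "", dtype=object)
    for ct, pos_frac in (("NeuN+", 1 - effects.neun_hypo_frac),
                         ("OLIG2+", effects.olig2_hyper_frac)):
        k = effects.n_szdmp_per_celltype
        if k == 0:
            continue
        k_in = int(round(k * effects.szdmp_in_celltype_dmp_frac))
        pools = [np.flatnonzero(is_ct & ~is_sz),
                 np.flatnonzero(~is_ct & ~is_sz)]
        chosen = []
        for pool, want in zip(pools, (k_in, k - k_in)):
            take = min(want, pool.size)
            if take:
                chosen.append(rng.choice(pool, size=take, replace=False))
        idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
        beta[idx] = _signed_magnitudes(idx.size, effects.mean_abs_beta,
                                       effects.beta_sd,
                                       effects.beta_halfwidth, pos_frac, rng)
        is_sz[idx] = True
        sz_ct[idx] = ct

    # --- group means: shift the pair so the realized delta is exact.
    # Group means are kept inside [0.1, 0.9] so the per-individual
    # truncated-normal draw on [0, 1] stays essentially unbiased and the
    # realized group difference equals the planted delta.
    half = np.abs(delta) / 2
    pad = 0.1
    center = np.clip(mu, pad + half, 1 - pad - half)
    group_mean = {}
    for ct in CELL_TYPES:
        base = center - half * np.sign(delta) if ct == "NeuN+" \
            else center + half * np.sign(delta)
        group_mean[ct, "control"] = base
        case = base.copy()
        affected = is_sz & (sz_ct == ct)
        case[affected] = np.clip(base[affected] + beta[affected], 0.02, 0.98)
        group_mean[ct, "schizophrenia"] = case
    realized_beta = np.zeros(m)
    for ct in CELL_TYPES:
        affected = is_sz & (sz_ct == ct)
        realized_beta[affected] = (group_mean[ct, "schizophrenia"][affected]
                                   - group_mean[ct, "control"][affected])

    # --- per-sample fractions with optional covariate nuisance
    sample_mean = np.empty((m, n))
    for j, row in enumerate(samples.itertuples()):
        sample_mean[:, j] = group_mean[row.cell_type, row.diagnosis]
    for col, sd in effects.covariate_effects.items():
        if sd == 0:
            continue
        v = samples[col]
        if pd.api.types.is_numeric_dtype(v):
            x = (v - v.mean()).to_numpy(dtype=float)
        else:
            codes = pd.Categorical(v).codes.astype(float)
            x = codes - codes.mean()
        site_coef = rng.normal(0.0, sd, size=m)
        sample_mean += np.outer(site_coef, x)
    sample_mean = np.clip(sample_mean, 0.001, 0.999)
    frac = truncated_normal(sample_mean, effects.individual_sd, 0.0, 1.0,
                            (m, n), rng)

    # --- counts
    design_src = samples.attrs.get("design")
    cov_mean = getattr(design_src, "coverage_mean", 25.0)
    cov_disp = getattr(design_src, "coverage_dispersion", 5.0)
    p_nb = cov_disp / (cov_disp + cov_mean)
    N = rng.negative_binomial(cov_disp, p_nb, size=(m, n))
    X = rng.binomial(N, frac)

    counts = CountMatrix(sites, list(samples["sample_id"]), N, X)
    truth = TruthTable(
        sites.assign(is_celltype_dmp=is_ct, celltype_delta=delta,
                     is_szdmp=is_sz, sz_delta=realized_beta,
                     cell_type_of_effect=sz_ct),
        pd.DataFrame(dmr_rows, columns=["chrom", "start", "end",
                                        "n_cpg", "delta"]),
    )
    return counts, truth


# --------------------------------------------------------------------------
# GWAS summary statistics

@dataclass
class GwasSimConfig:
    snp_density: float = 1 / 500      # SNPs per bp
    log_or_sd: float = 0.15
    excess_multiplier: float = 1.0    # OR multiplier near planted szDMPs
    near_bp: int = 1000

    def __post_init__(self) -> None:
        if self.excess_multiplier <= 0:
            raise ValueError("excess_multiplier must be > 0")


def generate_gwas_summary(genome: SyntheticGenome, truth: TruthTable,
                          enr: GwasSimConfig | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Random GWAS SNPs with lognormal ORs, inflated near planted szDMPs."""
    enr = enr or GwasSimConfig()
    rng = np.random.default_rng(seed)
    sz = truth.sites[truth.sites["is_szdmp"]]
    rows = []
    snp_i = 0
    for chrom, size in sorted(genome.chrom_sizes.items()):
        n_snp = rng.binomial(size, enr.snp_density)
        pos = np.sort(rng.choice(size, size=n_snp, replace=False)) + 1
        orr = np.exp(rng.normal(0.0, enr.log_or_sd, size=n_snp))
        szpos = np.sort(sz.loc[sz["chrom"] == chrom, "pos"].to_numpy())
        if szpos.size:
            lo = np.searchsorted(szpos, pos - enr.near_bp, side="left")
            hi = np.searchsorted(szpos, pos + enr.near_bp, side="right")
            near = hi > lo
            orr[near] *= enr.excess_multiplier
        p = rng.uniform(np.nextafter(0, 1), 1.0, size=n_snp)
        for j in range(n_snp):
            snp_i += 1
            rows.append({"snp": f"rs{snp_i:06d}", "chrom": chrom,
                         "pos": int(pos[j]), "OR": float(orr[j]),
                         "P": float(p[j])})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# external EWAS

def generate_external_ewas(truth: TruthTable | pd.DataFrame,
                           concordance: float, n_sites: int,
                           ramp: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """External-study table whose direction agrees with a reference at a
    controlled rate.

    The reference is either a TruthTable (szDMP signs; other sites get a
    random reference direction) or a DataFrame with chrom, pos, direction.
    Per site the agreement probability is ``concordance + ramp * q`` (capped
    at [0, 1]), where q in [0, 1] grows as the assigned external P shrinks —
    a monotone concordance ramp across P bins.
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(truth, TruthTable):
        ref = truth.sites[["chrom", "pos"]].copy()
        d = np.where(truth.sites["is_szdmp"],
                     np.sign(truth.sites["sz_delta"]),
                     np.where(rng.random(len(ref)) < 0.5, 1.0, -1.0))
        ref["direction"] = d
    else:
        ref = truth[["chrom", "pos", "direction"]].copy()
    ref = ref[ref["direction"] != 0]
    if n_sites > len(ref):
        raise ValueError("n_sites exceeds available reference sites")
    pick = rng.choice(len(ref), size=n_sites, replace=False)
    out = ref.iloc[pick].reset_index(drop=True).copy()
    neglog = rng.uniform(0.0, 5.0, size=n_sites)
    out["P"] = 10.0 ** (-neglog)
    q = neglog / 5.0
    p_agree = np.clip(concordance + ramp * q, 0.0, 1.0)
    agree = rng.random(n_sites) < p_agree
    out["direction"] = np.where(agree, out["direction"], -out["direction"])
    return out
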