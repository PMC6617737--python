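import numpy as np
import pandas as pd
import pytest

from ctmeth import diffmeth, simulate
from ctmeth.io import CountMatrix


@pytest.fixture(scope="session")
def genome():
    return simulate.generate_genome(n_chrom=1, chrom_len=500_000, seed=11)


@pytest.fixture(scope="session")
def cohort():
    return simulate.generate_cohort(simulate.CohortDesign(seed=11))


@pytest.fixture(scope="session")
def methylomes(genome, cohort):
    counts, truth = simulate.generate_methylomes(
        genome, cohort, simulate.EffectConfig(), seed=12)
    return counts, truth


@pytest.fixture(scope="session")
def null_methylomes(genome, cohort):
    """No planted effects anywhere."""
    eff = simulate.EffectConfig(frac_celltype_dmp=0.0,
                                n_szdmp_per_celltype=0, n_planted_dmrs=0)
    counts, truth = simulate.generate_methylomes(genome, cohort, eff, seed=13)
    return counts, truth


@pytest.fixture(scope="session")
def celltype_results(methylomes, cohort):
    counts, _ = methylomes
    design = diffmeth.build_design(cohort, "cell_type", ["sex", "age_class"])
    return diffmeth.site_test_arcsine(counts, design)


def make_counts(N, X, positions=None, chrom="chr1", sample_ids=None):
    """Small hand-built CountMatrix for unit tests."""
    N = np.atleast_2d(np.asarray(N))
    X = np.atleast_2d(np.asarray(X))
    m, n = N.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    return CountMatrix(sites, sample_ids, N, X)


def two_group_samples(n1, n2, target="cell_type"):
    levels = {"cell_type": ("NeuN+", "OLIG2+"),
              "diagnosis": ("control", "schizophrenia")}[target]
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n1 + n2)],
        target: [levels[0]] * n1 + [levels[1]] * n2,
    })
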