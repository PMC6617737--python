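"""Readers and writers for the tabular and interval formats the pipeline touches.

Conventions
-----------
* Per-sample CpG count tables are TSV with header columns ``chr, pos, N, X``
  (total and methylated read counts), positions 1-based and strand-collapsed:
  one record per CpG dyad, anchored at the C of the plus strand.
* Covariate tables are TSV with one row per sample.
* Interval tracks are BED3/BED6, 0-based half-open.
* GWAS summary statistics are TSV with columns ``snp, chr, pos, OR, P``.

All readers accept plain or gzip-compressed files (pandas handles compression
by file extension). Conversion between 1-based CpG positions and 0-based
half-open intervals is centralized in :func:`cpg_to_interval` and
:func:`interval_to_cpg`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "AnnotationSet",
    "cpg_to_interval",
    "interval_to_cpg",
    "read_count_tables",
    "write_count_table",
    "read_covariates",
    "write_covariates",
    "read_intervals",
    "write_intervals",
    "read_gwas",
    "write_gwas",
    "REQUIRED_COVARIATE_COLUMNS",
]


# --------------------------------------------------------------------------
# coordinate conventions

def cpg_to_interval(pos: int | np.ndarray, dyad: bool = True):
    """1-based CpG position -> 0-based half-open (start, end).

    With ``dyad=True`` the interval covers both strands' cytosines (the CG
    dinucleotide, 2 bp); otherwise just the plus-strand C (1 bp).
    """
    start = np.asarray(pos) - 1
    return start, start + (2 if dyad else 1)


def interval_to_cpg(start: int | np.ndarray):
    """0-based interval start -> 1-based position of the first base."""
    return np.asarray(start) + 1


# --------------------------------------------------------------------------
# containers

@dataclass
class CountMatrix:
    """Per-CpG, per-sample read counts from WGBS.

    Attributes
    ----------
    sites : DataFrame with columns ``chrom`` and ``pos`` (1-based), sorted by
        (chrom, pos).
    samples : list of unique sample ids, aligned with the columns of N and X.
    N, X : (n_sites, n_samples) integer arrays of total and methylated read
        counts. A cell with ``N == 0`` means *no observation*, never
        methylation zero.
    """

    sites: pd.DataFrame
    samples: list[str]
    N: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N)
        self.X = np.asarray(self.X)
        if self.N.shape != self.X.shape:
            raise ValueError("N and X must have the same shape")
        if self.N.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count shape does not match sites x samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if np.any(self.X > self.N):
            raise ValueError("X > N at some cell")
        if np.any(self.N < 0) or np.any(self.X < 0):
            raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def fractions(self) -> np.ndarray:
        """X/N with NaN where there is no observation (N == 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.X / self.N
        return np.where(self.N > 0, f, np.nan)

    def subset_sites(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.N[mask],
            self.X[mask],
        )

    def site_keys(self) -> pd.Index:
        return pd.Index(zip(self.sites["chrom"], self.sites["pos"]))


@dataclass
class AnnotationSet:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals)
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"intervals missing column {col!r}")
        if len(df) and np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
            raise ValueError("interval with start >= end")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


# --------------------------------------------------------------------------
# count tables

def _sort_sites(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_count_tables(paths, sample_ids=None) -> CountMatrix:
    """Read per-sample count TSVs into a single :class:`CountMatrix`.

    The site list is the union across samples; a site absent from a sample is
    stored with N = X = 0 (missing observation). Input that is not sorted by
    (chrom, pos) is sorted with a warning.
    """
    paths = list(paths)
    if sample_ids is None:
        sample_ids = [str(p) for p in paths]
    frames = []
    for path, sid in zip(paths, sample_ids):
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        missing = {"chr", "pos", "N", "X"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        bad = np.flatnonzero(df["X"].to_numpy() > df["N"].to_numpy())
        if bad.size:
            # +2: 1-based line numbers and the header line
            raise ValueError(f"{path}: X > N at line {bad[0] + 2}")
        if not df[["chr", "pos"]].equals(_sort_sites(
                df.rename(columns={"chr": "chrom"}))[["chrom", "pos"]]
                .rename(columns={"chrom": "chr"})):
            warnings.warn(f"{path}: unsorted input, sorting")
            df = df.sort_values(["chr", "pos"], kind="mergesort")
        df = df.rename(columns={"chr": "chrom"}).set_index(["chrom", "pos"])
        frames.append(df[["N", "X"]].rename(columns=lambda c: f"{c}|{sid}"))
    merged = pd.concat(frames, axis=1, join="outer").fillna(0).astype(np.int64)
    merged = merged.sort_index()
    sites = merged.index.to_frame(index=False, name=["chrom", "pos"])
    N = merged[[f"N|{s}" for s in sample_ids]].to_numpy()
    X = merged[[f"X|{s}" for s in sample_ids]].to_numpy()
    return CountMatrix(sites, list(sample_ids), N, X)


def write_count_table(cm: CountMatrix, path, sample: str) -> None:
    """Write one sample's counts as a DSS-convention TSV (sites with N>0)."""
    j = cm.samples.index(sample)
    keep = cm.N[:, j] > 0
    out = pd.DataFrame({
        "chr": cm.sites["chrom"][keep],
        "pos": cm.sites["pos"][keep],
        "N": cm.N[keep, j],
        "X": cm.X[keep, j],
    })
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# covariates

REQUIRED_COVARIATE_COLUMNS = (
    ["sample_id", "cell_type", "diagnosis", "age_class", "sex", "hemisphere",
     "pmi_class", "conversion_rate", "brain_bank"]
    + [f"pc{i}" for i in range(1, 11)]
)


def _validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id")
    cr = df["conversion_rate"].to_numpy(dtype=float)
    if np.any((cr < 0) | (cr > 1)):
        raise ValueError("conversion_rate outside [0, 1]")
    return df.reset_index(drop=True)


def read_covariates(path) -> pd.DataFrame:
    """Read and validate a sample covariate table (TSV)."""
    return _validate_covariates(pd.read_csv(path, sep="\t"))


def write_covariates(samples: pd.DataFrame, path) -> None:
    _validate_covariates(samples).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# BED intervals

def read_intervals(path, name: str) -> AnnotationSet:
    """Read a BED3+ file (0-based half-open) into an :class:`AnnotationSet`."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return AnnotationSet(name, pd.DataFrame(columns=["chrom", "start", "end"]))
    cols = ["chrom", "start", "end", "label", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return AnnotationSet(name, df[cols])


def write_intervals(ann: AnnotationSet, path) -> None:
    ann.intervals.to_csv(path, sep="\t", index=False, header=False)


# --------------------------------------------------------------------------
# GWAS summary statistics

def read_gwas(path) -> pd.DataFrame:
    """Read a GWAS summary table (TSV: snp, chr, pos, OR, P).

    Rows with missing OR are dropped with a warning; OR <= 0 or P outside
    (0, 1] is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = {"snp", "chr", "pos", "OR", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns {sorted(missing)}")
    n_before = len(df)
    df = df.dropna(subset=["OR"]).reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with missing OR")
    orr = df["OR"].to_numpy(dtype=float)
    if np.any(~np.isfinite(orr)) or np.any(orr <= 0):
        raise ValueError("OR must be finite and positive")
    p = df["P"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P must be in (0, 1]")
    return df.rename(columns={"chr": "chrom"})


def write_gwas(gwas: pd.DataFrame, path) -> None:
    out = gwas.rename(columns={"chrom": "chr"})
    out.to_csv(path, sep="\t", index=False)
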