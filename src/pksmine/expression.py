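"""RPKM expression categorization and two-condition differential testing.

The transcriptome enters as a raw count matrix (genes x samples) with
per-gene exonic lengths and a sample sheet mapping each sample to its
condition (active growth at 24 h vs stationary phase at 48 h).  The
machinery implemented here:

* RPKM = count x 10^9 / (length_bp x library reads), averaged across
  replicates per condition.
* An expression call on the log2 scale: a gene counts as expressed at a
  time point iff log2(RPKM) >= 1, i.e. RPKM >= 2 (boundary inclusive);
  reported expression below the threshold is floored to 0.
* The three-way category: Cat1 silent at both time points, Cat2
  expressed at exactly one (i.e. differentially expressed in the
  categorical sense), Cat3 expressed at both.
* TMM (trimmed mean of M-values) between-sample normalization factors,
  computed exactly as edgeR defines them (reference sample by 75th
  percentile, 30% two-sided trim on M, 5% on A, precision-weighted mean,
  factors rescaled to geometric mean 1).
* A per-gene differential test between the two conditions: Welch's
  unequal-variance t-test on TMM-normalized log2-CPM with a 0.5-read
  pseudo-count, significance at p < 0.05 and a "strong" flag at
  |log2FC| >= 1 (twofold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionRecord",
    "read_counts",
    "rpkm",
    "rpkm_matrix",
    "expressed_call",
    "categorize",
    "tmm_factors",
    "log2_cpm",
    "differential",
    "expression_table",
    "expression_records",
    "LOG2_RPKM_THRESHOLD",
    "P_CUTOFF",
    "STRONG_LOG2FC",
]

LOG2_RPKM_THRESHOLD = 1.0  # expressed iff log2(RPKM) >= 1, i.e. RPKM >= 2
P_CUTOFF = 0.05
STRONG_LOG2FC = 1.0  # twofold
PSEUDO_COUNT = 0.5  # reads added before CPM, keeps log2 finite at zero counts


@dataclass
class CountMatrix:
    """Raw read counts with gene lengths, conditions and library sizes.

    ``counts``: DataFrame genes x samples (non-negative integers);
    ``lengths``: per-gene exonic length in bp; ``conditions``: per-sample
    condition label; ``library_sizes`` defaults to the column sums.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    conditions: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()[:5]
            raise ValueError(f"missing gene lengths, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            raise ValueError("every sample needs a condition label")
        if self.conditions.nunique() < 1:
            raise ValueError("at least one condition required")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def read_counts(counts_tsv, samples_tsv) -> CountMatrix:
    """Load the counts TSV (gene_id, length_bp, samples...) + sample sheet.

    The sample sheet needs ``sample`` and ``condition`` columns; an
    optional ``library_size`` column overrides the column sums (used
    when the counts table covers only part of the sequenced library).
    """
    table = pd.read_csv(counts_tsv, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in table.columns:
            raise ValueError(f"counts table missing column {col!r}")
    table = table.set_index("gene_id")
    lengths = table.pop("length_bp")
    sheet = pd.read_csv(samples_tsv, sep="\t")
    if not {"sample", "condition"} <= set(sheet.columns):
        raise ValueError("sample sheet needs columns: sample, condition")
    sheet = sheet.set_index("sample")
    library_sizes = sheet["library_size"] if "library_size" in sheet.columns else None
    return CountMatrix(
        counts=table[list(sheet.index)],
        lengths=lengths,
        conditions=sheet["condition"],
        library_sizes=library_sizes,
    )


def rpkm(count, length_bp, library_size):
    """Reads per kilobase of exon per million library reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    return np.asarray(count, dtype=float) * 1e9 / (length_bp * library_size)


def rpkm_matrix(cm: CountMatrix) -> pd.DataFrame:
    values = rpkm(
        cm.counts.to_numpy(dtype=float),
        cm.lengths.to_numpy(dtype=float)[:, None],
        cm.library_sizes.to_numpy(dtype=float)[None, :],
    )
    return pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns)


def expressed_call(log2rpkm: float) -> tuple[bool, float]:
    """Threshold one log2(RPKM) value.

    Returns ``(expressed, reported)``: expressed iff log2RPKM >= 1
    (inclusive); the reported value is floored to 0 below the threshold,
    matching the convention that sub-threshold expression is biologically
    irrelevant and set to zero.  ``-inf`` (an RPKM of 0) is handled.
    """
    expressed = bool(log2rpkm >= LOG2_RPKM_THRESHOLD)
    return expressed, float(log2rpkm) if expressed else 0.0


def categorize(expressed_24h: bool, expressed_48h: bool) -> str:
    """Cat1 silent at both; Cat2 expressed at exactly one; Cat3 at both."""
    n = int(expressed_24h) + int(expressed_48h)
    return ("Cat1", "Cat2", "Cat3")[n]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M: inverse is the weight
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[keep], a[keep], v[keep]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not trimmed.any():
        return 1.0
    f = np.sum(m[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts, library_sizes=None) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those percentiles; M-values are trimmed 30%
    two-sided and A-values 5%, the surviving M are combined by
    precision-weighted mean, and the factors are rescaled to geometric
    mean 1.  Genes at zero in either member of a pair drop out of that
    pair's trimmed mean.
    """
    counts = np.asarray(
        counts.to_numpy() if hasattr(counts, "to_numpy") else counts, dtype=float
    )
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    if library_sizes is None:
        lib = counts.sum(axis=0)
    else:
        lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("a sample with an all-zero (or negative) library")
    f75 = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    if np.median(f75) < 1e-20:
        raise ValueError("counts too sparse for TMM (75th percentiles all zero)")
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref])
            for j in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log2_cpm(counts, library_sizes, factors=None, pseudo: float = PSEUDO_COUNT):
    """log2 counts per million on effective (TMM-scaled) library sizes."""
    counts = np.asarray(
        counts.to_numpy() if hasattr(counts, "to_numpy") else counts, dtype=float
    )
    lib = np.asarray(library_sizes, dtype=float)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    return np.log2((counts + pseudo) / lib[None, :] * 1e6)


# ---------------------------------------------------------------------------
# Differential test
# ---------------------------------------------------------------------------


def differential(
    log2cpm_a: np.ndarray, log2cpm_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene (log2fc, p, significant, strong) for condition b vs a.

    log2FC is the difference of replicate-mean log2-CPM; the p-value is
    Welch's unequal-variance two-sample t-test across replicates.  With
    fewer than two replicates in either group the p-value is NaN and
    significance false.  Genes whose replicate values are exactly equal
    in both groups get p = 1; zero-variance groups with unequal means
    get p = 0 (the test degenerates to certainty).
    """
    a = np.atleast_2d(np.asarray(log2cpm_a, dtype=float))
    b = np.atleast_2d(np.asarray(log2cpm_b, dtype=float))
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    n_genes = a.shape[0]
    if a.shape[1] < 2 or b.shape[1] < 2:
        p = np.full(n_genes, np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
        zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
        p = np.where(zero_var & (log2fc == 0), 1.0, p)
        p = np.where(zero_var & (log2fc != 0), 0.0, p)
    significant = np.where(np.isnan(p), False, p < P_CUTOFF)
    strong = np.abs(log2fc) >= STRONG_LOG2FC
    return log2fc, p, significant.astype(bool), strong


# ---------------------------------------------------------------------------
# Per-gene expression records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionRecord:
    """Everything the downstream filters need to know about one gene."""

    gene_id: str
    rpkm_24h: float
    rpkm_48h: float
    log2rpkm_24h: float  # reported values, floored to 0 below threshold
    log2rpkm_48h: float
    expressed_24h: bool
    expressed_48h: bool
    category: str
    log2fc: float
    p_value: float
    significant: bool
    strong: bool


def expression_table(
    cm: CountMatrix,
    condition_a: str = "24h",
    condition_b: str = "48h",
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-gene expression table for a two-condition experiment.

    RPKM is averaged across replicates per condition before the log2
    threshold is applied; the differential columns come from the Welch
    test on TMM-normalized log2-CPM (factors computed here if absent).
    """
    for cond in (condition_a, condition_b):
        if cond not in set(cm.conditions):
            raise ValueError(f"condition {cond!r} absent from sample sheet")
    if factors is None:
        factors = tmm_factors(cm.counts, cm.library_sizes.to_numpy())
    rp = rpkm_matrix(cm)
    samples_a = cm.samples_for(condition_a)
    samples_b = cm.samples_for(condition_b)
    mean_a = rp[samples_a].mean(axis=1).to_numpy()
    mean_b = rp[samples_b].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore"):
        log_a = np.log2(mean_a)
        log_b = np.log2(mean_b)
    expressed_a = log_a >= LOG2_RPKM_THRESHOLD
    expressed_b = log_b >= LOG2_RPKM_THRESHOLD
    reported_a = np.where(expressed_a, log_a, 0.0)
    reported_b = np.where(expressed_b, log_b, 0.0)
    lcpm = log2_cpm(cm.counts, cm.library_sizes.to_numpy(), factors)
    cols = list(cm.counts.columns)
    idx_a = [cols.index(s) for s in samples_a]
    idx_b = [cols.index(s) for s in samples_b]
    log2fc, p, significant, strong = differential(lcpm[:, idx_a], lcpm[:, idx_b])
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            f"rpkm_{condition_a}": mean_a,
            f"rpkm_{condition_b}": mean_b,
            f"log2rpkm_{condition_a}": reported_a,
            f"log2rpkm_{condition_b}": reported_b,
            f"expressed_{condition_a}": expressed_a,
            f"expressed_{condition_b}": expressed_b,
            "category": [
                categorize(ea, eb) for ea, eb in zip(expressed_a, expressed_b)
            ],
            "log2fc": log2fc,
            "p_value": p,
            "significant": significant,
            "strong": strong,
        }
    ).set_index("gene_id", drop=False)


def expression_records(
    table: pd.DataFrame, condition_a: str = "24h", condition_b: str = "48h"
) -> dict[str, ExpressionRecord]:
    """Convert an expression table into per-gene records keyed by gene id."""
    records = {}
    for row in table.itertuples(index=False):
        rec = ExpressionRecord(
            gene_id=row.gene_id,
            rpkm_24h=getattr(row, f"rpkm_{condition_a}"),
            rpkm_48h=getattr(row, f"rpkm_{condition_b}"),
            log2rpkm_24h=getattr(row, f"log2rpkm_{condition_a}"),
            log2rpkm_48h=getattr(row, f"log2rpkm_{condition_b}"),
            expressed_24h=bool(getattr(row, f"expressed_{condition_a}")),
            expressed_48h=bool(getattr(row, f"expressed_{condition_b}")),
            category=row.category,
            log2fc=row.log2fc,
            p_value=row.p_value,
            significant=bool(row.significant),
            strong=bool(row.strong),
        )
        records[rec.gene_id] = rec
    return records
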