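"""Quality control that never consults mitochondrial content.

Cells are flagged per patient when any of three metrics — log1p total counts,
log1p genes expressed, or the fraction of counts in the top 50 genes — lies
more than ``n_mads`` raw median absolute deviations from the patient median,
and by absolute cutoffs on totals and gene counts. The pctMT threshold filter
exists only for strategy comparison. All flags are computed on the input
table in one pass (no iterative re-filtering), so filters commute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellTable, NormalizedMatrix

__all__ = [
    "QCReport",
    "mad_outlier_flags",
    "absolute_flags",
    "top_k_fraction",
    "transcriptome_variance",
    "pctmt_threshold_filter",
    "run_qc",
]

MAD_METRICS = ("log1p_total_counts", "log1p_n_genes", "top50_fraction")


@dataclass
class QCReport:
    """Per-cell QC flags plus the thresholds that produced them.

    A cell is removed iff any enabled flag is set; ``keep`` is the complement
    of the OR over flag columns.
    """

    flags: pd.DataFrame  # boolean columns per flag, indexed by cell id
    thresholds: dict = field(default_factory=dict)

    @property
    def keep(self) -> pd.Series:
        return ~self.flags.any(axis=1)

    def per_patient_summary(self, patient_ids: pd.Series) -> pd.DataFrame:
        df = self.flags.copy()
        df["removed"] = ~self.keep
        df["patient_id"] = patient_ids.values
        return df.groupby("patient_id").sum()


def top_k_fraction(t: CellTable, k: int = 50) -> np.ndarray:
    """Fraction of each cell's counts held by its k most-expressed genes."""
    totals = t.total_counts().astype(float)
    out = np.ones(t.n_cells)
    csr = t.counts
    for i in range(t.n_cells):
        row = csr.data[csr.indptr[i] : csr.indptr[i + 1]]
        if totals[i] <= 0:
            out[i] = 0.0
        elif len(row) <= k:
            out[i] = 1.0
        else:
            top = np.partition(row, len(row) - k)[-k:]
            out[i] = top.sum() / totals[i]
    return out


def mad_outlier_flags(t: CellTable, n_mads: float = 5.0) -> pd.Series:
    """Per-patient MAD outlier flags over the three QC metrics.

    MAD is the raw (unscaled) median absolute deviation, two-sided; a cell is
    flagged if it is an outlier on any metric. A patient with a single cell
    passes trivially, with a warning.
    """
    metrics = pd.DataFrame(
        {
            "log1p_total_counts": np.log1p(t.total_counts().astype(float)),
            "log1p_n_genes": np.log1p(t.genes_per_cell().astype(float)),
            "top50_fraction": top_k_fraction(t, 50),
        },
        index=t.cell_ids,
    )
    flagged = pd.Series(False, index=t.cell_ids)
    for pid, sub in metrics.groupby(t.cell_meta["patient_id"].values):
        if len(sub) < 2:
            warnings.warn(f"patient {pid} has a single cell; MAD filter skipped")
            continue
        for m in MAD_METRICS:
            v = sub[m].to_numpy()
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            flagged.loc[sub.index[np.abs(v - med) > n_mads * mad]] = True
    return flagged


def absolute_flags(
    t: CellTable,
    min_counts: int = 1500,
    max_counts: int = 50000,
    min_genes: int = 500,
) -> pd.Series:
    """Flag cells with fewer than ``min_counts`` or more than ``max_counts``
    total counts, or fewer than ``min_genes`` genes expressed (strict)."""
    totals = t.total_counts()
    ngenes = t.genes_per_cell()
    bad = (totals < min_counts) | (totals > max_counts) | (ngenes < min_genes)
    return pd.Series(bad, index=t.cell_ids)


def transcriptome_variance(n: NormalizedMatrix) -> np.ndarray:
    """Population variance (ddof 0) of each cell's normalized expression."""
    return n.values.var(axis=1, ddof=0)


def pctmt_threshold_filter(t: CellTable, threshold: float = 15.0) -> CellTable:
    """Drop cells with pctMT strictly above ``threshold`` percent.

    Used only when comparing filtering strategies; requires a ``pctMT``
    column in ``cell_meta`` (computed by :func:`highmt.mito.compute_pctmt`).
    """
    if "pctMT" not in t.cell_meta.columns:
        raise ValueError("cell_meta lacks a pctMT column; compute it first")
    return t.subset_cells((t.cell_meta["pctMT"] <= threshold).to_numpy())


def run_qc(
    t: CellTable,
    n_mads: float = 5.0,
    min_counts: int = 1500,
    max_counts: int = 50000,
    min_genes: int = 500,
    use_doublet_flag: bool = True,
) -> tuple[CellTable, QCReport]:
    """Apply the pctMT-free QC and return the filtered table plus report."""
    flags = pd.DataFrame(index=t.cell_ids)
    flags["mad_outlier"] = mad_outlier_flags(t, n_mads=n_mads)
    absf = absolute_flags(t, min_counts, max_counts, min_genes)
    totals = t.total_counts()
    ngenes = t.genes_per_cell()
    flags["low_counts"] = pd.Series(totals < min_counts, index=t.cell_ids)
    flags["high_counts"] = pd.Series(totals > max_counts, index=t.cell_ids)
    flags["low_genes"] = pd.Series(ngenes < min_genes, index=t.cell_ids)
    assert (flags[["low_counts", "high_counts", "low_genes"]].any(axis=1) == absf).all()
    if use_doublet_flag and "doublet_flag" in t.cell_meta.columns:
        flags["doublet"] = t.cell_meta["doublet_flag"].fillna(False).astype(bool)
    else:
        flags["doublet"] = False
    report = QCReport(
        flags=flags,
        thresholds={
            "n_mads": n_mads,
            "min_counts": min_counts,
            "max_counts": max_counts,
            "min_genes": min_genes,
        },
    )
    return t.subset_cells(report.keep.to_numpy()), report


def gene_expression_by_group(
    n: NormalizedMatrix, gene: str, groups: pd.Series
) -> pd.DataFrame:
    """Summarize one gene's normalized expression across QC groups.

    Generic report used for MALAT1-style sanity checks: per group, the count,
    mean and median of the gene's log1p-CP10K expression.
    """
    if gene not in n.gene_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    j = n.gene_ids.get_loc(gene)
    df = pd.DataFrame({"expr": n.values[:, j], "group": groups.values})
    return df.groupby("group")["expr"].agg(["count", "mean", "median"])
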