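"""Metacell aggregation: small disjoint groups of homogeneous cells.

Within each (patient, cell_type) stratum, cells are embedded by PCA of their
log1p-CP10K expression (top 30 components) and partitioned by seeded k-means
with k = ceil(n / target_size), so metacells average ~25 cells. Counts are
summed per cluster — exact conservation of per-gene totals. A metacell is
HighMT when more than 30% of its members are HighMT, and malignant when more
than 50% are malignant (both strict).

This is a size-targeted surrogate for graph-partition metacell algorithms;
the downstream statistics depend only on the contract: disjoint, homogeneous,
roughly ``target_size`` cells each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import CellTable, NormalizedMatrix, normalize_cp10k_log1p

__all__ = ["MetacellTable", "build_metacells", "label_metacells"]


@dataclass
class MetacellTable:
    counts: sp.csr_matrix  # metacell x gene
    gene_ids: pd.Index
    metacell_ids: pd.Index
    membership: dict[str, list[str]]  # metacell -> member cell ids
    meta: pd.DataFrame  # per-metacell annotations

    @property
    def n_metacells(self) -> int:
        return self.counts.shape[0]

    def normalized(self) -> NormalizedMatrix:
        """log1p-CP10K of the aggregated counts (metacells as observations)."""
        totals = np.asarray(self.counts.sum(axis=1)).ravel().astype(float)
        if (totals <= 0).any():
            raise ValueError("metacell with zero total counts")
        vals = np.log1p(self.counts.multiply(1e4 / totals[:, None]).toarray())
        return NormalizedMatrix(
            values=vals, gene_ids=self.gene_ids, cell_ids=self.metacell_ids
        )


def _balanced_assign(emb: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Assign cells to k-means centers under balanced capacities.

    Capacities differ by at most one cell; cells are processed by decreasing
    margin between their best and second-best center (confident cells first),
    each taking the nearest center with remaining capacity. Keeps metacell
    sizes within floor/ceil of n/k while respecting cluster structure;
    deterministic for fixed embedding and centers.
    """
    n, k = emb.shape[0], centers.shape[0]
    d = np.linalg.norm(emb[:, None, :] - centers[None, :, :], axis=2)
    caps = np.full(k, n // k)
    caps[: n % k] += 1
    if k == 1:
        return np.zeros(n, dtype=int)
    sorted_d = np.sort(d, axis=1)
    margin = sorted_d[:, 1] - sorted_d[:, 0]
    order = np.lexsort((np.arange(n), -margin))
    assign = np.empty(n, dtype=int)
    counts = np.zeros(k, dtype=int)
    for i in order:
        for c in np.argsort(d[i], kind="stable"):
            if counts[c] < caps[c]:
                assign[i] = c
                counts[c] += 1
                break
    return assign


def build_metacells(
    t: CellTable,
    target_size: int = 25,
    n_components: int = 30,
    seed: int = 0,
    stratify_by_patient: bool = True,
) -> MetacellTable:
    """Partition cells into metacells within (patient, cell_type) strata.

    Strata smaller than ``target_size`` form a single metacell. Set
    ``stratify_by_patient=False`` to pool patients within a cell type.
    """
    keys = ["patient_id", "cell_type"] if stratify_by_patient else ["cell_type"]
    if "cell_type" not in t.cell_meta.columns:
        raise ValueError("cell_meta lacks a cell_type column")
    groups = t.cell_meta.groupby(keys, sort=True).groups

    mc_counts, mc_ids, membership, meta_rows = [], [], {}, []
    mc_counter = 0
    for key, cell_index in groups.items():
        if len(cell_index) == 0:
            continue
        sub = t.subset_cells(list(cell_index))
        n = sub.n_cells
        if n <= target_size:
            labels = np.zeros(n, dtype=int)
            k = 1
        else:
            norm = normalize_cp10k_log1p(sub)
            k = int(np.ceil(n / target_size))
            ncomp = min(n_components, n - 1, sub.n_genes)
            emb = PCA(n_components=ncomp, random_state=seed).fit_transform(
                norm.values
            )
            km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(emb)
            labels = _balanced_assign(emb, km.cluster_centers_)
        key_t = key if isinstance(key, tuple) else (key,)
        for lab in range(k):
            members = sub.cell_ids[labels == lab]
            if len(members) == 0:
                continue
            mc_id = f"MC{mc_counter:05d}"
            mc_counter += 1
            mask = sub.cell_ids.isin(members)
            mc_counts.append(np.asarray(sub.counts[mask].sum(axis=0)).ravel())
            mc_ids.append(mc_id)
            membership[mc_id] = list(members)
            row = dict(zip(keys, key_t))
            row.update({"metacell_id": mc_id, "n_cells": int(len(members))})
            meta_rows.append(row)

    counts = sp.csr_matrix(np.vstack(mc_counts)) if mc_counts else sp.csr_matrix(
        (0, t.n_genes)
    )
    meta = pd.DataFrame(meta_rows).set_index("metacell_id") if meta_rows else (
        pd.DataFrame(index=pd.Index([], name="metacell_id"))
    )
    return MetacellTable(
        counts=counts,
        gene_ids=t.gene_ids,
        metacell_ids=pd.Index(mc_ids, name="metacell_id"),
        membership=membership,
        meta=meta,
    )


def label_metacells(
    m: MetacellTable,
    t: CellTable,
    mt_status: pd.Series,
    highmt_frac: float = 0.30,
    malignant_frac: float = 0.50,
) -> MetacellTable:
    """Add HighMT / malignant labels from member-cell composition (strict >)."""
    comp = t.cell_meta["compartment"]
    fr_high, fr_mal = [], []
    for mc in m.metacell_ids:
        members = m.membership[mc]
        st = mt_status.loc[members]
        fr_high.append(float((st == "HighMT").mean()))
        fr_mal.append(float((comp.loc[members] == "malignant").mean()))
    m.meta["frac_highmt"] = fr_high
    m.meta["frac_malignant"] = fr_mal
    m.meta["highmt_label"] = np.where(
        np.array(fr_high) > highmt_frac, "HighMT", "LowMT"
    )
    m.meta["malignant_label"] = np.array(fr_mal) > malignant_frac
    return m
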