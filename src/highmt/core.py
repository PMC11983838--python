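"""Core data model and I/O.

Holds the cell-by-gene count table with per-cell metadata, named gene sets,
and the CP10K/log1p normalization every downstream stage consumes. Counts are
kept sparse (CSR); metadata lives in a pandas DataFrame aligned to the cell
axis. Gene identifiers are matched case-sensitively, exactly as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellTable",
    "GeneSet",
    "GeneSetCollection",
    "NormalizedMatrix",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "normalize_cp10k_log1p",
    "mt_gene_mask",
]

COMPARTMENTS = ("malignant", "TME")


@dataclass
class GeneSet:
    """A named, duplicate-free set of gene identifiers.

    ``category`` is free-form (e.g. a xenobiotic phase or drug-target class).
    """

    name: str
    genes: frozenset[str]
    category: str | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, gene_ids) -> list[str]:
        """Members present in ``gene_ids``, in the order of ``gene_ids``."""
        members = self.genes
        return [g for g in gene_ids if g in members]


class GeneSetCollection:
    """Ordered collection of :class:`GeneSet`, keyed by name."""

    def __init__(self, sets: list[GeneSet] | None = None):
        self._sets: dict[str, GeneSet] = {}
        for s in sets or []:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self._sets:
            raise ValueError(f"duplicate gene set name {s.name!r}")
        self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)


@dataclass
class CellTable:
    """Sparse cell x gene raw counts plus per-cell metadata.

    ``cell_meta`` must carry ``patient_id`` and ``compartment`` (one of
    ``malignant`` / ``TME``); an optional boolean ``doublet_flag`` and a
    ``cell_type`` column are recognized by downstream stages. Derived per-cell
    scalars (total_counts, n_genes, pctMT, scores, ...) are appended to
    ``cell_meta`` by the stages that compute them.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.cell_ids.has_duplicates:
            raise ValueError("duplicate cell ids")
        if self.gene_ids.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if not self.cell_meta.index.equals(self.cell_ids):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        for col in ("patient_id", "compartment"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
            if self.cell_meta[col].isna().any():
                bad = self.cell_meta.index[self.cell_meta[col].isna()]
                raise ValueError(f"cells without {col}: {list(bad[:5])}")
        bad = set(self.cell_meta["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment values: {sorted(bad)}")

    # -- shape ------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    # -- per-cell scalars --------------------------------------------------
    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        c = self.counts.copy()
        c.eliminate_zeros()
        return np.diff(c.indptr)

    # -- subsetting --------------------------------------------------------
    def subset_cells(self, mask) -> "CellTable":
        """New table restricted to cells where ``mask`` is True (or an id list)."""
        if isinstance(mask, (list, pd.Index)):
            mask = self.cell_ids.isin(mask)
        mask = np.asarray(mask, dtype=bool)
        return CellTable(
            counts=self.counts[mask],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[mask],
            cell_meta=self.cell_meta.loc[mask].copy(),
        )

    def to_anndata(self):
        """Thin AnnData converter for interop with the scanpy ecosystem."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )


@dataclass
class NormalizedMatrix:
    """log1p(CP10K) expression: value(i,j) = log(1 + 1e4 * c_ij / T_i)."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    provenance: CellTable | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def normalize_cp10k_log1p(t: CellTable) -> NormalizedMatrix:
    """Counts-per-10k followed by natural log1p, per cell.

    Every cell must have a positive total count; zero-total cells are a QC
    failure and are reported by id.
    """
    totals = t.total_counts().astype(float)
    if (totals <= 0).any():
        bad = list(t.cell_ids[totals <= 0][:10])
        raise ValueError(f"cells with zero total counts (run QC first): {bad}")
    scaled = t.counts.multiply(1e4 / totals[:, None]).toarray()
    return NormalizedMatrix(
        values=np.log1p(scaled),
        gene_ids=t.gene_ids,
        cell_ids=t.cell_ids,
        provenance=t,
    )


def mt_gene_mask(
    gene_ids, mt_genes: GeneSet | None = None, prefix: str = "MT-"
) -> np.ndarray:
    """Boolean mask of mitochondrial genes.

    An explicit gene list wins over the prefix convention; both are matched
    case-sensitively.
    """
    gene_ids = pd.Index(gene_ids)
    if mt_genes is not None:
        return gene_ids.isin(mt_genes.genes)
    return np.array([g.startswith(prefix) for g in gene_ids], dtype=bool)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_meta(meta_path, cell_ids: pd.Index) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype={0: str})
    first = meta.columns[0]
    if first not in ("cell_id", "barcode"):
        raise ValueError(
            f"metadata first column must be 'cell_id' or 'barcode', got {first!r}"
        )
    meta = meta.set_index(first)
    if meta.index.has_duplicates:
        raise ValueError("duplicate cell ids in metadata")
    missing = cell_ids.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing cells: {list(missing[:10])}")
    if "compartment" not in meta.columns:
        raise ValueError("metadata missing required 'compartment' column")
    extra = meta.index.difference(cell_ids)
    if len(extra):
        warnings.warn(
            f"dropping {len(extra)} metadata rows for unknown cells", stacklevel=3
        )
    meta = meta.loc[cell_ids]
    meta.index.name = "cell_id"
    return meta


def read_counts(path: str | Path, meta_path: str | Path) -> CellTable:
    """Read a count matrix (10x-style MatrixMarket directory, or dense TSV).

    A directory is expected to contain ``matrix.mtx`` (genes x cells, 1-based
    indices per the MatrixMarket standard), ``barcodes.tsv`` and
    ``features.tsv``. A dense TSV has cells in rows (first column = cell id)
    and genes in columns. ``meta_path`` is a TSV whose first column
    (``cell_id``/``barcode``) covers every cell; unreferenced rows are dropped
    with a warning.
    """
    path = Path(path)
    if path.is_dir():
        mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx").T)
        barcodes = pd.Index(
            pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        )
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        gene_ids = pd.Index(features[0].astype(str))
        if mat.shape != (len(barcodes), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(barcodes)} barcodes x {len(gene_ids)} features"
            )
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        mat = sp.csr_matrix(dense.to_numpy())
        barcodes = pd.Index(dense.index.astype(str))
        gene_ids = pd.Index(dense.columns.astype(str))
    meta = _read_meta(meta_path, barcodes)
    return CellTable(counts=mat, gene_ids=gene_ids, cell_ids=barcodes, cell_meta=meta)


def write_counts(t: CellTable, outdir: str | Path) -> None:
    """Write a CellTable as matrix.mtx + barcodes.tsv + features.tsv + meta.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), sp.coo_matrix(t.counts.T), field="integer"
    )
    pd.Series(t.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(t.gene_ids).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    t.cell_meta.to_csv(outdir / "meta.tsv", sep="\t", index_label="cell_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated; the description field is
    stored as the set's category when non-empty.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected >= 3"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno} has no genes")
            coll.add(GeneSet(name=name, genes=frozenset(genes), category=desc or None))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.category or "na", *sorted(s.genes)]) + "\n")
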