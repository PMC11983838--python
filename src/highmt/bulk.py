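"""Bulk vs bulkified concordance of mitochondrial gene expression.

Single-cell counts are aggregated into one per-patient expression vector
("bulkified") and regressed on the paired bulk measurement with a polynomial
whose degree (1-6) is chosen at the elbow of the R-squared curve. The model
is trained excluding MT genes; the statistic is the mean residual of the MT
genes (observed bulkified minus predicted). Its null distribution comes from
resampling same-size gene sets from the most-expressed genes, refitting, and
recording their mean residuals; the one-sided p-value uses the +1
finite-sample correction, so it is always at least 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import CellTable, GeneSet, mt_gene_mask

__all__ = [
    "BulkPair",
    "ResidualTestResult",
    "bulkify",
    "make_bulk_pair",
    "select_degree",
    "mt_residual_statistic",
    "empirical_gene_sampling_test",
    "adjust_pvalues",
]


@dataclass
class BulkPair:
    """Aligned per-gene bulk and bulkified vectors for one patient."""

    patient_id: str
    bulk: pd.Series
    bulkified: pd.Series
    mode: str  # sum_log1p | mean_tpm

    def __post_init__(self) -> None:
        shared = self.bulk.index.intersection(self.bulkified.index)
        if len(shared) == 0:
            raise ValueError("bulk and bulkified share no genes")
        self.bulk = self.bulk.loc[shared].astype(float)
        self.bulkified = self.bulkified.loc[shared].astype(float)
        if self.bulk.isna().any() or self.bulkified.isna().any():
            raise ValueError("missing values after gene intersection")

    @property
    def genes(self) -> pd.Index:
        return self.bulk.index


@dataclass
class ResidualTestResult:
    patient_id: str
    degree_selected: int
    r2_curve: dict[int, float]
    mt_mean_residual: float
    null_means: np.ndarray
    null_ci95: tuple[float, float]
    p_raw: float
    p_adj: float = np.nan
    correction: str | None = None


def bulkify(t: CellTable, patient: str, mode: str = "sum_log1p") -> pd.Series:
    """Aggregate one patient's cells into a per-gene expression vector.

    ``sum_log1p``: log(1 + summed raw counts) per gene — the droplet (UMI)
    convention. ``mean_tpm``: mean across cells of per-cell TPM (counts scaled
    to 1e6 per cell) — the plate/Smart-seq convention, where gene-length
    correction is assumed upstream.
    """
    mask = (t.cell_meta["patient_id"] == patient).to_numpy()
    if not mask.any():
        raise KeyError(f"unknown patient {patient!r}")
    sub = t.counts[mask]
    if mode == "sum_log1p":
        vec = np.log1p(np.asarray(sub.sum(axis=0)).ravel().astype(float))
    elif mode == "mean_tpm":
        totals = np.asarray(sub.sum(axis=1)).ravel().astype(float)
        if (totals <= 0).any():
            raise ValueError("cell with zero total counts")
        tpm = sub.multiply(1e6 / totals[:, None])
        vec = np.asarray(tpm.mean(axis=0)).ravel()
    else:
        raise ValueError(f"unknown bulkification mode {mode!r}")
    return pd.Series(vec, index=t.gene_ids, name=f"bulkified:{patient}")


def make_bulk_pair(
    t: CellTable, bulk: pd.Series, patient: str, mode: str = "sum_log1p"
) -> BulkPair:
    return BulkPair(
        patient_id=patient,
        bulk=bulk,
        bulkified=bulkify(t, patient, mode=mode),
        mode=mode,
    )


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int) -> np.polynomial.Polynomial:
    return np.polynomial.Polynomial.fit(x, y, deg=degree)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero-variance response; R-squared undefined")
    return 1.0 - ss_res / ss_tot


def select_degree(
    bulk: np.ndarray | pd.Series,
    bulkified: np.ndarray | pd.Series,
    degrees: range = range(1, 7),
    epsilon: float = 0.01,
) -> tuple[int, dict[int, float]]:
    """Pick the polynomial degree at the elbow of the R-squared curve.

    Fits bulkified ~ poly(bulk) for each degree and returns the smallest
    degree whose successor improves R-squared by less than ``epsilon``; if
    every step improves by at least ``epsilon``, the largest degree wins.
    """
    x = np.asarray(bulk, dtype=float)
    y = np.asarray(bulkified, dtype=float)
    degrees = list(degrees)
    if len(x) < degrees[-1] + 2:
        raise ValueError(f"need at least {degrees[-1] + 2} genes")
    r2_curve = {d: _r2(y, _fit_poly(x, y, d)(x)) for d in degrees}
    for d in degrees[:-1]:
        if r2_curve[d + 1] - r2_curve[d] < epsilon:
            return d, r2_curve
    return degrees[-1], r2_curve


def mt_residual_statistic(
    pair: BulkPair, mt_genes: GeneSet | None, degree: int
) -> float:
    """Mean residual of MT genes under a model trained without them."""
    mt = mt_gene_mask(pair.genes, mt_genes)
    if not mt.any():
        raise ValueError("no MT gene in the shared gene index")
    x = pair.bulk.to_numpy()
    y = pair.bulkified.to_numpy()
    model = _fit_poly(x[~mt], y[~mt], degree)
    return float(np.mean(y[mt] - model(x[mt])))


def empirical_gene_sampling_test(
    pair: BulkPair,
    mt_genes: GeneSet | None,
    degree: int,
    B: int = 500,
    pool_size: int = 500,
    seed: int | None = 0,
) -> ResidualTestResult:
    """One-sided empirical test of the MT mean residual.

    B times, |MT| genes are drawn (without replacement) from the
    ``pool_size`` most-expressed genes (by bulkified mean), the model is
    refit excluding them, and their mean residual is recorded. p_raw =
    (1 + #{null >= observed}) / (B + 1); the 95% band is the empirical
    2.5/97.5 percentile interval of the null means.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    mt = mt_gene_mask(pair.genes, mt_genes)
    n_mt = int(mt.sum())
    if n_mt == 0:
        raise ValueError("no MT gene in the shared gene index")
    pool_size = min(pool_size, len(pair.genes))
    if n_mt > pool_size:
        raise ValueError(f"|MT|={n_mt} exceeds pool_size={pool_size}")
    rng = np.random.default_rng(seed)
    x = pair.bulk.to_numpy()
    y = pair.bulkified.to_numpy()

    observed = mt_residual_statistic(pair, mt_genes, degree)
    # top pool by bulkified expression; ties broken by gene order (stable)
    pool = np.argsort(-y, kind="stable")[:pool_size]
    null_means = np.empty(B)
    for b in range(B):
        pick = rng.choice(pool, size=n_mt, replace=False)
        excl = np.zeros(len(y), dtype=bool)
        excl[pick] = True
        model = _fit_poly(x[~excl], y[~excl], degree)
        null_means[b] = np.mean(y[excl] - model(x[excl]))
    p_raw = (1.0 + float((null_means >= observed).sum())) / (B + 1.0)
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return ResidualTestResult(
        patient_id=pair.patient_id,
        degree_selected=degree,
        r2_curve={},
        mt_mean_residual=observed,
        null_means=null_means,
        null_ci95=(float(lo), float(hi)),
        p_raw=p_raw,
    )


def adjust_pvalues(p: np.ndarray | list[float], method: str = "bonferroni") -> np.ndarray:
    """Multiplicity correction: 'bonferroni' or 'bh' (Benjamini-Hochberg)."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction {method!r}")


def run_residual_tests(
    t: CellTable,
    bulks: pd.DataFrame,
    mt_genes: GeneSet | None = None,
    mode: str = "sum_log1p",
    B: int = 500,
    pool_size: int = 500,
    epsilon: float = 0.01,
    correction: str = "bonferroni",
    seed: int | None = 0,
) -> list[ResidualTestResult]:
    """Run the full residual test for every patient with a bulk column.

    ``bulks`` columns are named ``bulk:<patient_id>``; the per-patient seed is
    derived from ``seed`` so results do not depend on patient order.
    """
    results = []
    patients = [c.split(":", 1)[1] for c in bulks.columns if c.startswith("bulk:")]
    for i, pid in enumerate(patients):
        pair = make_bulk_pair(t, bulks[f"bulk:{pid}"], pid, mode=mode)
        degree, r2_curve = select_degree(
            pair.bulk, pair.bulkified, epsilon=epsilon
        )
        res = empirical_gene_sampling_test(
            pair,
            mt_genes,
            degree,
            B=B,
            pool_size=pool_size,
            seed=None if seed is None else seed + 1000 * i,
        )
        res.r2_curve = r2_curve
        results.append(res)
    if results:
        adj = adjust_pvalues([r.p_raw for r in results], method=correction)
        for r, a in zip(results, adj):
            r.p_adj = float(a)
            r.correction = correction
    return results
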