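"""Synthetic cohort, bulk-pair, cell-line and spatial generators.

Every input the pipeline consumes can be generated here with plantable
ground-truth effects: a malignant-vs-TME shift in mitochondrial RNA fraction,
a dissociation-stress program optionally coupled to HighMT status, per-patient
mitochondrial excess in paired bulk/bulkified data, per-drug pctMT-IC50
correlations, and spatial fields with regionally varying malignant pctMT.

The mitochondrial fraction is modeled at the probability level: each cell
draws a true MT fraction and its counts are multinomial over gene weights in
which the MT genes jointly receive that fraction. The observed pctMT is then
a noisy estimate of the truth, matching the estimator the pipeline computes.
Cell totals are log-normal, and a configurable fraction of "junk" cells (very
low totals concentrated on few genes) gives the QC stage something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellTable, GeneSet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_bulk_pair",
    "simulate_cell_lines",
    "simulate_spatial",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    pctMT targets are Beta-distributed per compartment; ``pctmt_params`` maps
    compartment -> (mean, concentration). The dissociation-stress program is a
    block of non-MT genes whose weights are multiplied by ``exp(stress_effect)``
    in HighMT cells when ``stress_coupled`` is on. ``mt_excess`` multiplies a
    patient's single-cell MT counts relative to its paired bulk sample.
    """

    n_patients: int = 8
    cells_per_patient: int = 300
    n_genes: int = 1200
    n_mt_genes: int = 13  # the 13 MT-encoded protein-coding genes
    malignant_fraction: float = 0.5
    # compartment -> (mean MT fraction, Beta concentration)
    pctmt_params: dict = field(
        default_factory=lambda: {"malignant": (0.25, 12.0), "TME": (0.05, 30.0)}
    )
    n_stress_genes: int = 30
    stress_effect: float = 0.0  # log-scale weight shift in HighMT cells
    stress_coupled: bool = True
    planted_pathway_effects: dict = field(default_factory=dict)
    pathway_size: int = 20
    total_counts_mean_log: float = np.log(5000.0)
    total_counts_sd_log: float = 0.35
    junk_fraction: float = 0.0
    junk_total: int = 300
    junk_top_genes: int = 10
    bulk_noise_sd: float = 0.05
    bulk_transform: tuple = (0.0, 1.0, 0.0)  # bulk = c0 + c1*z + c2*z^2
    mt_excess: dict = field(default_factory=dict)  # patient -> factor
    # drug -> true pctMT/logIC50 correlation
    drug_params: dict = field(default_factory=dict)
    n_cancer_types: int = 4
    lines_per_type: int = 50
    drug_categories: tuple = ("metabolism", "kinase", "genome_integrity", "other")
    # spatial
    field_px: tuple = (4000, 4000)
    n_spatial_cells: int = 4000
    spatial_regions: dict = field(
        default_factory=lambda: {"hot": ((0, 0, 2000, 2000), 0.25)}
    )
    spatial_base_pctmt: float = 0.05
    spatial_malignant_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.malignant_fraction <= 1:
            raise ValueError("malignant_fraction must be in [0,1]")
        if self.n_mt_genes >= self.n_genes:
            raise ValueError("n_mt_genes must be < n_genes")
        for comp, (m, _) in self.pctmt_params.items():
            if not 0 <= m <= 1:
                raise ValueError(f"pctMT mean for {comp} outside [0,1]")
        if not 0 <= self.junk_fraction < 1:
            raise ValueError("junk_fraction must be in [0,1)")
        for d, r in self.drug_params.items():
            if abs(r) > 1:
                raise ValueError(f"|true correlation| > 1 for drug {d}")


@dataclass
class GroundTruth:
    """Planted truths aligned to generated tables by id."""

    cell_mt_fraction: pd.Series
    cell_is_junk: pd.Series
    stress_genes: list
    pathway_genes: dict
    mt_genes: list
    drug_true_r: dict
    patient_mt_excess: dict


def _gene_names(cfg: SynthConfig) -> list[str]:
    mt = [f"MT-G{i}" for i in range(cfg.n_mt_genes)]
    rest = [f"GENE{i}" for i in range(cfg.n_genes - cfg.n_mt_genes)]
    return mt + rest


def mt_gene_set(cfg: SynthConfig) -> GeneSet:
    return GeneSet("MT", frozenset(f"MT-G{i}" for i in range(cfg.n_mt_genes)))


def _beta_ab(mean: float, conc: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return mean * conc, (1 - mean) * conc


def simulate_cohort(cfg: SynthConfig) -> tuple[CellTable, GroundTruth]:
    """Draw a multi-patient cohort with malignant and TME compartments.

    Deterministic given ``cfg.seed``. Per cell: compartment, a true MT
    fraction (Beta), a log-normal total count, then multinomial counts over
    gene weights where the MT genes jointly carry the MT fraction. Stress and
    pathway programs shift gene weights multiplicatively in HighMT cells
    (true fraction > 0.15) when planted.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg)
    n_mt = cfg.n_mt_genes
    n_rest = cfg.n_genes - n_mt

    # fixed relative abundances within the MT block and the rest
    w_mt = rng.gamma(5.0, 1.0, size=n_mt)
    w_mt /= w_mt.sum()
    w_rest_base = rng.gamma(0.8, 1.0, size=n_rest) + 1e-3
    w_rest_base /= w_rest_base.sum()

    rest_names = genes[n_mt:]
    stress_genes = rest_names[: cfg.n_stress_genes]
    stress_idx = np.arange(cfg.n_stress_genes)
    pathway_genes: dict[str, list[str]] = {}
    pathway_idx: dict[str, np.ndarray] = {}
    offset = cfg.n_stress_genes
    for name in cfg.planted_pathway_effects:
        idx = np.arange(offset, offset + cfg.pathway_size)
        if idx[-1] >= n_rest:
            raise ValueError("not enough genes for planted pathways")
        pathway_idx[name] = idx
        pathway_genes[name] = [rest_names[i] for i in idx]
        offset += cfg.pathway_size

    rows, cols, vals = [], [], []
    cell_ids, patients, comps, truth_frac, is_junk = [], [], [], [], []
    row = 0
    for p in range(cfg.n_patients):
        pid = f"P{p:02d}"
        for c in range(cfg.cells_per_patient):
            cid = f"{pid}_C{c:04d}"
            mal = rng.random() < cfg.malignant_fraction
            comp = "malignant" if mal else "TME"
            mean_mt, conc_mt = cfg.pctmt_params[comp]
            if mean_mt in (0.0, 1.0):  # degenerate: exact fraction
                f_mt = float(mean_mt)
            else:
                a, b = _beta_ab(mean_mt, conc_mt)
                f_mt = rng.beta(a, b)
            junk = rng.random() < cfg.junk_fraction
            if junk:
                total = max(
                    int(rng.poisson(cfg.junk_total)), cfg.junk_top_genes
                )
                w_rest = np.zeros(n_rest)
                top = rng.choice(n_rest, size=cfg.junk_top_genes, replace=False)
                w_rest[top] = rng.gamma(5.0, 1.0, size=cfg.junk_top_genes)
                w_rest /= w_rest.sum()
            else:
                total = int(
                    np.round(
                        rng.lognormal(cfg.total_counts_mean_log, cfg.total_counts_sd_log)
                    )
                )
                total = max(total, 100)
                w_rest = w_rest_base.copy()
                highmt = f_mt > 0.15
                if highmt and cfg.stress_coupled and cfg.stress_effect != 0.0:
                    w_rest[stress_idx] *= np.exp(cfg.stress_effect)
                if (not cfg.stress_coupled) and cfg.stress_effect != 0.0:
                    # uncoupled: stress hits a random half of cells instead
                    if rng.random() < 0.5:
                        w_rest[stress_idx] *= np.exp(cfg.stress_effect)
                if highmt:
                    for name, eff in cfg.planted_pathway_effects.items():
                        w_rest[pathway_idx[name]] *= np.exp(eff)
                w_rest = w_rest / w_rest.sum()
            w = np.concatenate([f_mt * w_mt, (1.0 - f_mt) * w_rest])
            counts = rng.multinomial(total, w)
            nz = np.nonzero(counts)[0]
            rows.extend([row] * len(nz))
            cols.extend(nz.tolist())
            vals.extend(counts[nz].tolist())
            cell_ids.append(cid)
            patients.append(pid)
            comps.append(comp)
            truth_frac.append(f_mt)
            is_junk.append(junk)
            row += 1

    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(row, cfg.n_genes), dtype=np.int64
    )
    meta = pd.DataFrame(
        {
            "patient_id": patients,
            "compartment": comps,
            "cell_type": [
                "tumor" if c == "malignant" else "stromal" for c in comps
            ],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    table = CellTable(
        counts=counts,
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
    )
    truth = GroundTruth(
        cell_mt_fraction=pd.Series(truth_frac, index=table.cell_ids),
        cell_is_junk=pd.Series(is_junk, index=table.cell_ids),
        stress_genes=list(stress_genes),
        pathway_genes=pathway_genes,
        mt_genes=genes[:n_mt],
        drug_true_r=dict(cfg.drug_params),
        patient_mt_excess=dict(cfg.mt_excess),
    )
    return table, truth


def simulate_bulk_pair(cfg: SynthConfig, t: CellTable) -> pd.DataFrame:
    """Per-patient paired bulk vectors matched to a cohort's pseudobulk.

    The bulk sample is a monotone polynomial transform of the patient's
    log1p-pseudobulk plus Gaussian noise. When ``cfg.mt_excess[patient] > 1``
    the single-cell MT counts are treated as inflated relative to bulk: the
    bulk side is computed from pseudobulk with MT counts divided by that
    factor, so the bulkified MT genes exceed the bulk-based model prediction.

    Returns a DataFrame indexed by gene with one ``bulk:<patient>`` column per
    patient.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    c0, c1, c2 = cfg.bulk_transform
    if c1 <= 0:
        raise ValueError("bulk transform must be increasing (c1 > 0)")
    mt_mask = np.array([g.startswith("MT-") for g in t.gene_ids])
    out = {}
    for pid, idx in t.cell_meta.groupby("patient_id").groups.items():
        mask = t.cell_ids.isin(idx)
        pseudo = np.asarray(t.counts[mask].sum(axis=0)).ravel().astype(float)
        excess = float(cfg.mt_excess.get(pid, 1.0))
        bulk_side = pseudo.copy()
        if excess != 1.0:
            bulk_side[mt_mask] /= excess
        z = np.log1p(bulk_side)
        bulk = c0 + c1 * z + c2 * z**2
        if cfg.bulk_noise_sd > 0:
            bulk = bulk + rng.normal(0.0, cfg.bulk_noise_sd, size=bulk.size)
        out[f"bulk:{pid}"] = bulk
    if not out:
        raise ValueError("cohort has no patients")
    return pd.DataFrame(out, index=t.gene_ids)


def simulate_cell_lines(cfg: SynthConfig) -> pd.DataFrame:
    """Cell-line drug-response table with planted pctMT-IC50 correlations.

    Each cell line draws one pctMT value per cancer type; each drug's IC50
    (reported on the natural-log scale, as drug panels usually are) is
    generated so that its within-type Pearson correlation with pctMT has the
    configured true value. Columns: cell_line, cancer_type, pctmt, drug,
    ic50, category.
    """
    if not cfg.drug_params:
        raise ValueError("cfg.drug_params is empty")
    rng = np.random.default_rng(cfg.seed + 2)
    cats = list(cfg.drug_categories)
    records = []
    for ti in range(cfg.n_cancer_types):
        ctype = f"type{ti}"
        n = cfg.lines_per_type
        z = rng.standard_normal(n)  # standardized latent pctMT
        pctmt = np.clip(15.0 + 4.0 * z, 0.0, 100.0)
        for di, (drug, r) in enumerate(cfg.drug_params.items()):
            eps = rng.standard_normal(n)
            ic50 = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * eps
            cat = cats[di % len(cats)]
            for li in range(n):
                records.append(
                    (f"{ctype}_L{li:03d}", ctype, pctmt[li], drug, ic50[li], cat)
                )
    return pd.DataFrame(
        records,
        columns=["cell_line", "cancer_type", "pctmt", "drug", "ic50", "category"],
    )


def simulate_spatial(cfg: SynthConfig) -> pd.DataFrame:
    """Spatial cell table over a pixel field with regional pctMT structure.

    Cells are placed uniformly; malignant cells inside a configured region
    draw their MT fraction around that region's mean, elsewhere around the
    base mean. Columns: cell_id, x, y, pctmt, total_counts, malignant_flag.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    W, H = cfg.field_px
    n = cfg.n_spatial_cells
    x = rng.uniform(0, W, size=n)
    y = rng.uniform(0, H, size=n)
    malignant = rng.random(n) < cfg.spatial_malignant_fraction
    mean = np.full(n, cfg.spatial_base_pctmt)
    for (x0, y0, x1, y1), m in cfg.spatial_regions.values():
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        mean[inside & malignant] = m
    conc = 40.0
    a = np.clip(mean, 1e-4, 1 - 1e-4) * conc
    b = conc - a
    frac = rng.beta(a, b)
    totals = np.maximum(
        np.round(
            rng.lognormal(cfg.total_counts_mean_log, cfg.total_counts_sd_log, size=n)
        ),
        50,
    ).astype(int)
    return pd.DataFrame(
        {
            "cell_id": [f"S{i:05d}" for i in range(n)],
            "x": x,
            "y": y,
            "pctmt": 100.0 * frac,
            "total_counts": totals,
            "malignant_flag": malignant,
        }
    )
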