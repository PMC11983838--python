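# highmt

Viable malignant cells with high mitochondrial RNA content (**HighMT** cells)
are routinely discarded by single-cell RNA-seq quality control, because a high
fraction of mitochondrially encoded transcripts (**pctMT**) is the standard
proxy for dying or broken cells. In tumors this assumption is unsafe:
malignant cells often carry genuinely elevated mitochondrial activity, so a
fixed pctMT cutoff (typically 10–20%) silently removes a biologically
distinctive — and possibly drug-resistant — subpopulation.

`highmt` is a Python library for analyzing this population without throwing
it away. It is aimed at computational biologists working with cancer
scRNA-seq, paired bulk RNA-seq, cell-line drug panels, or spatial
transcriptomics.

## What it computes

- **pctMT-free quality control** — per patient, cells beyond 5 raw median
  absolute deviations (MADs) of log1p total counts, log1p genes expressed, or
  the top-50-gene count fraction are removed, plus absolute cutoffs
  (counts < 1500 or > 50 000, genes < 500). Mitochondrial content is never
  consulted; the classic > 15%-pctMT filter is available only for strategy
  comparison.
- **HighMT classification and patient annotation** — a cell is HighMT iff
  pctMT > 15. Per patient the 2×2 contingency of HighMT/LowMT × malignant/TME
  gives the odds ratio

  `OR = (n(HighMT,mal)/n(LowMT,mal)) / (n(HighMT,TME)/n(LowMT,TME))`

  and a patient is a *case* when OR > 2 and ≥ 15% of its malignant cells are
  HighMT (patients with < 30 cells in a compartment or < 20 HighMT cells are
  excluded).
- **Signature scoring** — Tirosh-style bin-controlled scoring (25 expression
  bins, 50 control genes per signature gene, seeded), point-biserial
  correlation of scores with HighMT status, meta-signature intersection, and
  label-by-max-score assignment.
- **Metacells** — ~25-cell disjoint homogeneous groups per (patient,
  cell type) stratum via PCA + balanced k-means, with exact count
  conservation; HighMT (> 30% HighMT members) and malignant (> 50% malignant
  members) labels.
- **Bulk vs bulkified testing** — per-patient pseudobulk (summed counts,
  log1p, or mean TPM) regressed on paired bulk with a polynomial of
  elbow-selected degree (1–6, R² improvement < 0.01), trained without MT
  genes; the mean MT-gene residual is tested against an empirical null built
  by resampling equal-size gene sets from the 500 most-expressed genes
  (500 draws, one-sided p with the +1 correction, Bonferroni or BH across
  patients).
- **Pathway dysregulation** — per-pathway difference of median scores between
  HighMT and LowMT malignant metacells, Ward/Euclidean clustering of pathway
  vectors, and the xenobiotic phase I/II/III (CYP, UGT/GST, ABC) comparison.
- **Drug association** — per (drug, cancer type) Pearson r between cell-line
  pctMT and IC50 with Student-t p-values, top/bottom-15 ranking by median r,
  Fisher-exact target-category enrichment, and a within-type permutation
  calibration of the median-r tails.
- **Spatial patches** — median malignant pctMT per origin-anchored
  1000×1000 px patch (patches with < 10 malignant cells excluded) and a
  Spearman depth-confounding check.
- **Synthetic data** — generators for every input above with plantable ground
  truth (compartment pctMT shift, HighMT-coupled stress program, per-patient
  MT excess, per-drug correlations, spatial hot regions), so the whole
  pipeline is testable offline.

## Worked example

Annotate patients of a synthetic cohort (malignant cells draw their MT
fraction around 25%, TME cells around 5%):

```python
from highmt import SynthConfig, simulate_cohort
from highmt.mito import (annotate_case_control, classify_highmt,
                         compute_pctmt, patient_contingency,
                         summaries_to_frame)
from highmt.synthetic import mt_gene_set

cfg = SynthConfig(n_patients=6, cells_per_patient=250, seed=0)
table, _ = simulate_cohort(cfg)
pct = compute_pctmt(table, mt_gene_set(cfg))
status = classify_highmt(pct, threshold=15.0)
summaries = annotate_case_control(patient_contingency(table, status))
print(summaries_to_frame(summaries).round(3))
```

prints (excerpt):

```
            n_highmt_mal  n_lowmt_mal  n_highmt_tme  n_lowmt_tme  odds_ratio  highmt_malignant_fraction status
patient_id
P00                   92           32             2          124     178.250                      0.742   case
P01                  112           20             6          112     104.533                      0.848   case
P02                   93           29             1          127     407.276                      0.762   case
```

Every patient is a case: the HighMT fraction of the malignant compartment
(0.74–0.85) far exceeds the TME's, so the odds ratios are two orders of
magnitude above the case threshold of 2. Scoring a stress program planted
only in HighMT cells (`examples/03_signature_scoring.py`) yields

```
mean score HighMT/LowMT: 0.407 / -0.223
point-biserial r       : 0.872  (p = 9.07e-122)
```

i.e. the bin-controlled score cleanly separates the two groups. The
`examples/` directory holds one short script per capability (QC, case/control,
scoring, bulk comparison, drugs, spatial, metacells + pathways); each prints
its result with a note on what the numbers mean. A thin CLI mirrors the
stages: `highmt run --seed 0 --outdir out` executes the full synthetic
pipeline and writes TSV results plus a reproducibility manifest.

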