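# Methods

This note documents the statistical procedures implemented in `highmt`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Data model and normalization

Counts are held sparse (CSR) with per-cell metadata (`patient_id`,
`compartment` ∈ {malignant, TME}, `cell_type`, optional `doublet_flag`).
Normalization is counts-per-10k followed by natural log1p:
`x_ij = log(1 + 10^4 c_ij / T_i)`. Mitochondrial genes are designated either
by an explicit gene set or by the case-sensitive prefix `MT-`; an explicit
set wins. Cohorts differ in whether MT tRNA/rRNA genes are counted into
pctMT; this stays a user choice (the gene set), not something the package
resolves.

## Quality control

Three per-patient metrics — log1p total counts, log1p genes expressed,
fraction of counts in the 50 most-expressed genes — are screened two-sided at
5 raw (unscaled) MADs. The unscaled MAD, rather than the 1.4826-scaled
normal-consistent version, keeps "5 MADs" reproducible and matches
single-cell best-practice tooling. All flags (MAD, absolute cutoffs
1500/50 000/500, doublet) are computed on the input table in one pass and
OR-ed; there is no iterative re-filtering, so flag computation commutes and
a QC report fully determines the removal set. Whether the three MAD screens
should be applied jointly or sequentially is ambiguous in general; one-pass
OR-ing is this package's documented choice. Doublet detection is an input
column, not computed. QC never reads MT-gene identity — a property the test
suite enforces by relabeling genes.

## HighMT classification and patient annotation

pctMT is reported on the 0–100 scale; HighMT is strict (`pctMT > 15`). The
patient odds ratio uses the cross-product form; when any cell of the 2×2
table is zero, 0.5 is added to all four entries (Haldane–Anscombe) and the
result is flagged so users can exclude corrected values. Case status
requires OR strictly above 2 *and* a HighMT malignant fraction of at least
15% (the fraction criterion is ≥, the OR criterion is >, following the
respective wordings "more than" and "at least"). Exclusion precedes case
calling: fewer than 30 cells in either compartment, or fewer than 20 HighMT
cells in total. Note that an OR of 2 and a "twice-higher HighMT proportion"
diverge for extreme fractions; the odds-ratio definition is the one
implemented.

## Signature scoring

Scores follow the bin-controlled scheme standard in single-cell analysis:
genes are ranked by mean expression over the scored observations (cells or
metacells — the observations being scored, not an external reference) and
cut into `n_bins = 25` equal-size rank bins; each signature gene draws
`ctrl_size = 50` control genes from the non-signature genes of its bin, with
replacement, seeded; the score is the mean signature expression minus the
mean over the unique control set. Two edge rules: (i) a bin whose genes are
all in the signature widens its control pool to the nearest bins that still
hold non-signature genes; (ii) a signature covering every gene takes the
full index as control, making its score identically zero — a conservation
property the tests assert exactly. Scoring parameters are not universal
constants; all three (bins, control size, seed) are recorded wherever scores
are written. When several studies are scored, binning is per study.

Planted-effect recovery is attenuated for *uniform* shifts (a shifted gene
drags its control bin upward with it); the quantity the pipeline relies on —
the score difference between cell groups, where controls cancel — recovers a
planted program shift unbiasedly, and that is what the tests check.

## Metacells

Within each (patient, cell type) stratum, cells are embedded by PCA (top 30
components of log1p-CP10K) and partitioned by seeded k-means with
`k = ceil(n / 25)`, followed by a balanced capacity assignment: cells are
assigned, most-confident first, to their nearest center with remaining
capacity, capacities differing by at most one cell. This keeps metacell
sizes within floor/ceil of n/k (median near the 25-cell target) while
respecting cluster structure; counts are summed per metacell, conserving
per-gene totals exactly. The graph-partition algorithm of dedicated metacell
packages is deliberately not re-implemented: downstream statistics depend
only on the contract (disjoint, homogeneous, ~25 cells). Stratification is
per patient by default to avoid cross-patient chimeric metacells;
`stratify_by_patient=False` pools patients within a cell type. Labels are
strict: HighMT iff > 30% HighMT members, malignant iff > 50% malignant
members.

## Bulk vs bulkified

Bulkification is `log1p(Σ_cells counts)` per gene for UMI data and the mean
of per-cell TPM for plate data. The bulk–bulkified relationship is modeled
by least-squares polynomials of degree 1–6; the selected degree is the
smallest whose successor improves R² by less than 0.01 (else degree 6).
R² is non-decreasing in degree (nested models), asserted at run time. The
MT statistic is the mean residual of MT genes under a model trained without
them. The empirical null resamples, per iteration, as many genes as there
are MT genes — matching the statistic's dimensionality — from the 500
most-expressed genes (ranked by mean bulkified expression; the ranking side
is configurable), refits, and records their mean residual. The one-sided
p-value uses the +1 finite-sample correction, `p = (1 + #{null ≥ obs})/(B+1)`,
so `p ≥ 1/(B+1)` and validity holds for any B. Both Bonferroni (default) and
Benjamini–Hochberg corrections are offered across patients.

## Pathways and xenobiotic metabolism

Pathway dysregulation is `median(score | HighMT) − median(score | LowMT)`
over malignant metacells (antisymmetric under label swap; undefined with an
empty group). Pathway-by-study vectors are clustered with Ward linkage on
Euclidean distances; rows with missing entries are dropped by default.
Report ordering is by median delta across studies, descending. The
xenobiotic comparison scores phase I (CYP), II (UGT/GST) and III (ABC) gene
sets and applies a two-sided Mann–Whitney U per phase and study.

## Drug association

Per (drug, cancer type) with ≥ 3 lines and non-degenerate variables:
Pearson r, `t = r sqrt((n−2)/(1−r²))`, two-sided p on n−2 df. Per-drug
medians over types rank the top/bottom 15 (ties broken lexicographically and
flagged). Category enrichment uses the two-sided Fisher exact test on
{selected, unselected} × {in category, not}. The permutation scheme shuffles
pctMT across cell lines *within* each cancer type — preserving type
composition and each line's value across its drugs — and compares the
observed 5th/95th percentiles of the per-drug median-r distribution to their
permutation nulls with +1-corrected empirical p-values. IC50 is used on the
scale provided (a log transform is available via `log_ic50=True`).

## Spatial patches

The grid is anchored at the origin with half-open cells
`[k·p, (k+1)·p) × [l·p, (l+1)·p)`, `p = 1000 px` by default. Each patch
reports the median pctMT over its malignant cells; fewer than 10 malignant
cells ⇒ excluded. The depth-confounding check is a Spearman correlation
(robust to the skewed pctMT distribution; Pearson available) of pctMT with
total counts, separately per compartment. The units of the rows (segmented
cells or spots) are whatever the input table represents.

## Synthetic generators

`simulate_cohort` models the MT fraction at the probability level: each cell
draws a true fraction from a per-compartment Beta (defaults: malignant mean
0.25, TME mean 0.05) and its multinomial gene weights allocate exactly that
fraction to the 13 MT genes, so observed pctMT is a noisy estimate of the
truth — matching the estimator the pipeline computes. Totals are log-normal
(median 5000, σ_log 0.35); a configurable junk fraction plants low-total,
top-heavy cells for QC to remove. A stress program (30 genes) and planted
pathways (20 genes each) shift gene weights multiplicatively in HighMT cells.
`simulate_bulk_pair` builds the bulk side from pseudobulk with MT counts
divided by the planted excess factor, then applies a monotone polynomial
transform plus Gaussian noise. `simulate_cell_lines` plants exact per-drug
correlations between a line's latent pctMT and its IC50 (reported on the log
scale, as panels usually distribute it). `simulate_spatial` draws uniform
coordinates with region-dependent Beta pctMT means.

Not emulated: gene–gene covariance, batch effects, ambient RNA, realistic
cell-type hierarchies, dropout beyond multinomial sampling. Passing tests
therefore demonstrate the statistical machinery — calibration, planted-effect
recovery, conservation, determinism — not robustness to those real-data
phenomena.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down versions of each analysis,
chosen to exercise the asymptotics that matter: calibration loops use 200
replicates with B = 99 resampling draws and ~300-gene panels; power checks
use 100 replicates; pathway recovery uses 40 replicates of 2-patient
cohorts. Library defaults stay at the full values (B = 500, pool = 500,
patch 1000 px, target size 25, 25 bins / 50 controls). Ties in ranking and
label assignment break lexicographically and are flagged; empirical p-values
never return 0; degenerate inputs (zero-total cells, constant responses,
all-zero tables, single-cell patients) raise or warn as documented in each
function.
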