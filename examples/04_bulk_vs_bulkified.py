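"""Test mitochondrial gene excess in single-cell data against paired bulk.

Per patient, single-cell counts are bulkified (summed then log1p), a
polynomial of elbow-selected degree (1-6) maps bulk to bulkified excluding
MT genes, and the statistic is the mean MT-gene residual. Its null comes
from resampling same-size gene sets from the 500 most-expressed genes;
p-values are Bonferroni-corrected across patients.
"""

from highmt import SynthConfig, run_residual_tests, simulate_bulk_pair, \
    simulate_cohort
from highmt.synthetic import mt_gene_set

cfg = SynthConfig(n_patients=3, cells_per_patient=150, n_genes=500, seed=0,
                  bulk_noise_sd=0.05, mt_excess={"P00": 3.0})
table, _ = simulate_cohort(cfg)
bulks = simulate_bulk_pair(cfg, table)

results = run_residual_tests(table, bulks, mt_gene_set(cfg),
                             B=500, pool_size=300, seed=0)
for r in results:
    lo, hi = r.null_ci95
    print(f"{r.patient_id}: degree={r.degree_selected} "
          f"mt_residual={r.mt_mean_residual:+.3f} "
          f"null95=[{lo:+.3f},{hi:+.3f}] p_adj={r.p_adj:.4f}")
# Patient P00 carries a 3x planted MT excess: its mean residual sits far
# above the resampling null (p_adj < 0.05); the other patients do not.
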