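import numpy as np
import pandas as pd
import pytest

from highmt import (
    absolute_flags,
    mad_outlier_flags,
    normalize_cp10k_log1p,
    pctmt_threshold_filter,
    run_qc,
    top_k_fraction,
    transcriptome_variance,
)
from highmt.synthetic import SynthConfig, simulate_cohort

from conftest import make_table


def brute_force_mad_flags(metrics: pd.DataFrame, patients, n_mads=5.0):
    """Independent per-patient implementation: plain loops, raw MAD."""
    flagged = pd.Series(False, index=metrics.index)
    for pid in sorted(set(patients)):
        idx = [i for i, p in zip(metrics.index, patients) if p == pid]
        if len(idx) < 2:
            continue
        for col in metrics.columns:
            v = metrics.loc[idx, col].to_numpy()
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            for i, val in zip(idx, v):
                if abs(val - med) > n_mads * mad:
                    flagged.loc[i] = True
    return flagged


class TestMADFlags:
    def test_hand_example_single_metric(self):
        # totals [10,12,11,10,50]; other two metrics constant across cells
        # (single expressed gene -> top-50 fraction 1, n_genes 1):
        # median 11, MAD 1, |50-11| = 39 > 5 -> only the last cell flagged
        counts = np.array([[10], [12], [11], [10], [50]])
        t = make_table(counts)
        flags = mad_outlier_flags(t, n_mads=5)
        assert flags.tolist() == [False, False, False, False, True]

    def test_all_equal_metric_flags_none(self):
        t = make_table(np.full((4, 1), 9))
        assert not mad_outlier_flags(t).any()

    def test_mad_zero_flags_any_deviation(self):
        # four identical cells and one different: MAD 0, deviant flagged
        counts = np.array([[9], [9], [9], [9], [10]])
        flags = mad_outlier_flags(make_table(counts), n_mads=5)
        assert flags.tolist() == [False] * 4 + [True]

    def test_patients_processed_independently(self, rng):
        counts = rng.integers(1, 50, size=(30, 20))
        patients = ["P0"] * 15 + ["P1"] * 15
        t = make_table(counts, patients=patients)
        metrics = pd.DataFrame(
            {
                "log1p_total_counts": np.log1p(t.total_counts().astype(float)),
                "log1p_n_genes": np.log1p(t.genes_per_cell().astype(float)),
                "top50_fraction": top_k_fraction(t, 50),
            },
            index=t.cell_ids,
        )
        expected = brute_force_mad_flags(metrics, patients, n_mads=1.5)
        got = mad_outlier_flags(t, n_mads=1.5)
        assert (expected == got).all()

    def test_single_cell_patient_passes_with_warning(self):
        t = make_table([[5], [6], [7]], patients=["P0", "P0", "P1"])
        with pytest.warns(UserWarning, match="P1"):
            flags = mad_outlier_flags(t)
        assert not flags["c2"]


class TestAbsoluteFlags:
    @pytest.mark.parametrize(
        "total,n_genes,expect",
        [
            (1400, 600, True),   # fewer than 1500 counts
            (1500, 500, False),  # boundary values are kept
            (60000, 600, True),  # more than 50000 counts
            (2000, 499, True),   # fewer than 500 genes
        ],
    )
    def test_boundaries(self, total, n_genes, expect):
        row = np.zeros(700, dtype=int)
        row[:n_genes] = 1
        row[0] += total - n_genes
        flags = absolute_flags(make_table(row[None, :]))
        assert bool(flags.iloc[0]) is expect


class TestTopKFraction:
    def test_few_genes_gives_one(self):
        t = make_table([[1, 2, 3]])
        assert top_k_fraction(t, 50)[0] == 1.0

    def test_sixty_genes_hand_value(self):
        # 60 expressed genes; top 50 hold 90 of 100 counts
        row = np.zeros(60, dtype=int)
        row[:50] = 1
        row[0] += 40  # top-50 genes: 41 + 49*1 = 90; rest: 10 genes x 1
        row[50:] = 1
        t = make_table(row[None, :])
        np.testing.assert_allclose(top_k_fraction(t, 50)[0], 0.9)

    def test_uniform_hundred_genes(self):
        t = make_table(np.ones((1, 100), dtype=int))
        np.testing.assert_allclose(top_k_fraction(t, 50)[0], 0.5)


class TestTranscriptomeVariance:
    def test_constant_cell_is_zero(self):
        t = make_table([[5, 5, 5, 5]])
        n = normalize_cp10k_log1p(t)
        n.values[0] = 1.0  # constant vector
        assert transcriptome_variance(n)[0] == 0.0

    def test_hand_value(self):
        n = normalize_cp10k_log1p(make_table([[1, 1]]))
        n.values = np.array([[0.0, 2.0]])
        np.testing.assert_allclose(transcriptome_variance(n)[0], 1.0)

    def test_matches_two_pass_oracle(self, rng):
        t = make_table(rng.integers(1, 30, size=(6, 40)))
        n = normalize_cp10k_log1p(t)
        got = transcriptome_variance(n)
        for i in range(6):
            v = n.values[i]
            mean = sum(v) / len(v)
            var = sum((x - mean) ** 2 for x in v) / len(v)
            np.testing.assert_allclose(got[i], var, rtol=1e-12)


class TestThresholdFilter:
    def test_strictly_above_threshold_dropped(self):
        t = make_table(np.ones((3, 2), dtype=int))
        t.cell_meta["pctMT"] = [10.0, 15.0, 16.0]
        kept = pctmt_threshold_filter(t, threshold=15.0)
        assert list(kept.cell_ids) == ["c0", "c1"]

    def test_threshold_100_is_identity(self):
        t = make_table(np.ones((3, 2), dtype=int))
        t.cell_meta["pctMT"] = [0.0, 50.0, 100.0]
        assert pctmt_threshold_filter(t, 100.0).n_cells == 3

    def test_threshold_0_keeps_only_zero(self):
        t = make_table(np.ones((3, 2), dtype=int))
        t.cell_meta["pctMT"] = [0.0, 0.1, 5.0]
        assert list(pctmt_threshold_filter(t, 0.0).cell_ids) == ["c0"]


class TestQCPipeline:
    def test_qc_blind_to_mt_gene_identity(self, small_cohort):
        t, _ = small_cohort
        _, report = run_qc(t, min_counts=500, min_genes=100)
        # relabel genes so a different block looks mitochondrial
        renamed = [f"MT-{g}" if not g.startswith("MT-") else f"X{g}"
                   for g in t.gene_ids]
        t2 = make_table(
            t.counts.toarray(),
            patients=list(t.cell_meta["patient_id"]),
            compartments=list(t.cell_meta["compartment"]),
            gene_ids=renamed,
        )
        _, report2 = run_qc(t2, min_counts=500, min_genes=100)
        assert (report.flags.to_numpy() == report2.flags.to_numpy()).all()

    def test_flags_computed_in_one_pass_commute(self, small_cohort):
        # MAD and absolute flags are defined on the input table, so the OR of
        # separately computed flags equals the report's removal set
        t, _ = small_cohort
        _, report = run_qc(t, min_counts=500, min_genes=100)
        manual = mad_outlier_flags(t) | absolute_flags(t, 500, 50000, 100)
        assert (report.keep == ~manual).all()

    def test_planted_junk_removed(self):
        cfg = SynthConfig(n_patients=2, cells_per_patient=200, seed=8,
                          junk_fraction=0.1)
        t, truth = simulate_cohort(cfg)
        filtered, report = run_qc(t)
        junk_ids = set(truth.cell_is_junk.index[truth.cell_is_junk])
        removed = set(t.cell_ids) - set(filtered.cell_ids)
        assert len(junk_ids & removed) / len(junk_ids) >= 0.9

    def test_doublet_column_respected(self):
        t = make_table(np.full((4, 600), 3), doublet_flag=[False, True, False, True])
        filtered, report = run_qc(t, min_counts=1, min_genes=1)
        assert filtered.n_cells == 2
        assert report.flags["doublet"].sum() == 2
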