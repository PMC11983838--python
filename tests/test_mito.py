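import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from highmt import (
    annotate_case_control,
    classify_highmt,
    clinical_association,
    compute_pctmt,
    patient_contingency,
    patient_odds_ratio,
)
from highmt.core import GeneSet
from highmt.mito import PatientMTSummary

from conftest import make_table

MT2 = GeneSet("mt", frozenset({"g0", "g1"}))


class TestPctMT:
    def test_quarter_of_counts(self):
        # 5 MT counts of a 20-count cell -> 25%
        t = make_table([[3, 2, 10, 5]])
        assert compute_pctmt(t, MT2).iloc[0] == 25.0

    def test_zero_and_full(self):
        t = make_table([[0, 0, 4, 6], [5, 5, 0, 0]])
        pct = compute_pctmt(t, MT2)
        assert pct.tolist() == [0.0, 100.0]

    def test_complement_identity(self, rng):
        t = make_table(rng.integers(1, 20, size=(10, 8)))
        mt = GeneSet("mt", frozenset({"g0", "g3"}))
        non_mt = GeneSet("rest", frozenset({f"g{j}" for j in (1, 2, 4, 5, 6, 7)}))
        total = compute_pctmt(t, mt) + compute_pctmt(t, non_mt)
        np.testing.assert_allclose(total, 100.0, rtol=1e-12)

    def test_no_mt_gene_detected_errors(self):
        t = make_table([[1, 2]])
        with pytest.raises(ValueError, match="no mitochondrial gene"):
            compute_pctmt(t, GeneSet("mt", frozenset({"absent"})))


class TestClassify:
    @pytest.mark.parametrize("pct,expect", [(15.0, "LowMT"), (15.01, "HighMT"),
                                            (0.0, "LowMT"), (100.0, "HighMT")])
    def test_strict_threshold(self, pct, expect):
        s = classify_highmt(pd.Series([pct]))
        assert s.iloc[0] == expect


class TestOddsRatio:
    def test_hand_value(self):
        odds, corr = patient_odds_ratio(30, 70, 10, 90)
        np.testing.assert_allclose(odds, 27 / 7)
        assert not corr

    def test_symmetric_table_is_one(self):
        odds, _ = patient_odds_ratio(10, 90, 10, 90)
        assert odds == 1.0

    def test_zero_cell_gets_continuity_correction(self):
        odds, corr = patient_odds_ratio(5, 95, 0, 100)
        np.testing.assert_allclose(odds, (5.5 / 95.5) / (0.5 / 100.5))
        assert corr

    def test_all_zero_table_errors(self):
        with pytest.raises(ValueError):
            patient_odds_ratio(0, 0, 0, 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_reciprocal_table_inverts_odds(self, counts):
        # swapping the compartments inverts the odds ratio exactly
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        odds, _ = patient_odds_ratio(a, b, c, d)
        flipped, _ = patient_odds_ratio(c, d, a, b)
        np.testing.assert_allclose(odds * flipped, 1.0, rtol=1e-12)

    def test_matches_cross_product_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            odds, corr = patient_odds_ratio(a, b, c, d)
            assert not corr
            np.testing.assert_allclose(odds, (a * d) / (b * c), rtol=1e-12)


def summary(pid="P0", hm=40, lm=60, ht=10, lt=90):
    s = PatientMTSummary(pid, hm, lm, ht, lt)
    s.odds_ratio, s.or_corrected = patient_odds_ratio(hm, lm, ht, lt)
    s.highmt_malignant_fraction = hm / (hm + lm)
    return s


class TestCaseControl:
    def test_case_requires_both_criteria(self):
        # OR=(40/60)/(10/90)=6 > 2 and fraction 0.4 >= 0.15 -> case
        s = annotate_case_control([summary()])[0]
        assert s.status == "case"

    def test_low_fraction_is_control(self):
        # OR=(14/90)/(8/200)~3.9 and 22 HighMT cells, but fraction 0.13 < 0.15
        s = annotate_case_control([summary(hm=14, lm=90, ht=8, lt=200)])[0]
        assert s.odds_ratio > 2 and s.status == "control"

    def test_small_malignant_compartment_excluded(self):
        s = annotate_case_control([summary(hm=10, lm=15, ht=30, lt=70)])[0]
        assert s.status == "excluded"
        assert s.exclusion_reason == "malignant<30"

    def test_few_highmt_cells_excluded(self):
        s = annotate_case_control([summary(hm=15, lm=100, ht=4, lt=100)])[0]
        assert s.status == "excluded"
        assert s.exclusion_reason == "HighMT<20"

    def test_invariant_to_cell_order(self, rng):
        counts = rng.integers(0, 60, size=(120, 4)) + 1
        patients = [f"P{i%3}" for i in range(120)]
        comps = ["malignant" if i % 2 else "TME" for i in range(120)]
        t = make_table(counts, patients=patients, compartments=comps,
                       gene_ids=["MT-A", "g1", "g2", "g3"])
        status = classify_highmt(compute_pctmt(t))
        base = patient_contingency(t, status)
        perm = rng.permutation(t.n_cells)
        t2 = make_table(counts[perm],
                        patients=[patients[i] for i in perm],
                        compartments=[comps[i] for i in perm],
                        gene_ids=["MT-A", "g1", "g2", "g3"])
        status2 = classify_highmt(compute_pctmt(t2))
        got = patient_contingency(t2, status2)
        assert [s.counts for s in base] == [s.counts for s in got]

    def test_case_rate_monotone_in_planted_shift(self):
        from highmt.synthetic import SynthConfig, mt_gene_set, simulate_cohort

        rates = []
        for shift in (0.05, 0.15, 0.30):
            cfg = SynthConfig(
                n_patients=6, cells_per_patient=150, n_genes=300, seed=21,
                pctmt_params={"malignant": (shift, 12.0), "TME": (0.05, 30.0)},
            )
            t, _ = simulate_cohort(cfg)
            status = classify_highmt(compute_pctmt(t, mt_gene_set(cfg)))
            summaries = annotate_case_control(patient_contingency(t, status))
            rates.append(np.mean([s.status == "case" for s in summaries]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[0] < rates[2]


class TestClinicalAssociation:
    def _summaries(self, fracs):
        out = []
        for i, f in enumerate(fracs):
            s = PatientMTSummary(f"P{i}", 0, 0, 0, 0)
            s.highmt_malignant_fraction = f
            out.append(s)
        return out

    def test_separated_groups_give_extreme_u(self):
        s = self._summaries([0.1, 0.2, 0.5, 0.6])
        clinical = pd.Series(["A", "A", "B", "B"],
                             index=["P0", "P1", "P2", "P3"])
        res = clinical_association(s, clinical)
        assert res.loc[0, "U"] == 0.0  # all group-A ranks below group B

    def test_identical_groups_not_significant(self):
        s = self._summaries([0.1, 0.2, 0.1, 0.2])
        clinical = pd.Series(["A", "A", "B", "B"],
                             index=["P0", "P1", "P2", "P3"])
        res = clinical_association(s, clinical)
        assert res.loc[0, "p"] > 0.9

    def test_small_group_skipped_with_warning(self):
        s = self._summaries([0.1, 0.2, 0.3])
        clinical = pd.Series(["A", "A", "B"], index=["P0", "P1", "P2"])
        with pytest.warns(UserWarning, match="'B'"):
            res = clinical_association(s, clinical)
        assert res.empty
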