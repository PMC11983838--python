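import numpy as np
import pandas as pd
import pytest

from highmt import (
    category_enrichment,
    per_type_correlations,
    permutation_calibration,
    rank_by_median,
)


def panel(rows):
    return pd.DataFrame(rows, columns=["cell_line", "cancer_type", "pctmt",
                                       "drug", "ic50"])


def simple_panel(pct, ic50, drug="d1", ctype="t1"):
    return panel([(f"L{i}", ctype, p, drug, c) for i, (p, c) in
                  enumerate(zip(pct, ic50))])


class TestPerTypeCorrelations:
    def test_perfect_positive(self):
        res = per_type_correlations(simple_panel([1, 2, 3], [2, 4, 6]))
        assert res.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert res.loc[0, "p"] == pytest.approx(0.0)

    def test_perfect_negative(self):
        res = per_type_correlations(simple_panel([1, 2, 3], [6, 4, 2]))
        assert res.loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_t_statistic_hand_value(self, rng):
        # r=0.99, n=10 -> t = 0.99*sqrt(8/(1-0.9801)) ~ 19.85
        r, n = 0.99, 10
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert t == pytest.approx(19.85, abs=0.01)
        # and the implementation reproduces its own r via the t formula
        x = rng.normal(size=30)
        y = 0.8 * x + rng.normal(size=30) * 0.5
        res = per_type_correlations(simple_panel(x, y))
        got_r, got_t = res.loc[0, "pearson_r"], res.loc[0, "t_stat"]
        assert got_t == pytest.approx(
            got_r * np.sqrt(28 / (1 - got_r**2)), rel=1e-12
        )

    def test_matches_covariance_oracle(self, rng):
        for _ in range(30):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            res = per_type_correlations(simple_panel(x, y))
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            np.testing.assert_allclose(res.loc[0, "pearson_r"], num / den,
                                       atol=1e-12)

    def test_small_and_degenerate_pairs_excluded(self):
        t = pd.concat([simple_panel([1, 2], [1, 2], drug="small"),
                       simple_panel([3, 3, 3], [1, 2, 3], drug="flat")])
        res = per_type_correlations(t).set_index("drug")
        assert res.loc["small", "excluded"] == "n<3"
        assert res.loc["flat", "excluded"] == "constant variable"


class TestRankByMedian:
    def _corr_frame(self, med_by_drug):
        rows = []
        for drug, rs in med_by_drug.items():
            for i, r in enumerate(rs):
                rows.append({"drug": drug, "cancer_type": f"t{i}", "n": 10,
                             "pearson_r": r, "excluded": pd.NA})
        return pd.DataFrame(rows)

    def test_median_hand_value(self):
        med, _, _, _ = rank_by_median(self._corr_frame({"d": [0.2, 0.5, 0.8]}))
        assert med["d"] == pytest.approx(0.5)

    def test_top_15_of_20(self):
        frame = self._corr_frame({f"d{i:02d}": [i / 20] for i in range(20)})
        med, top, bottom, tie = rank_by_median(frame, k=15)
        assert len(top) == 15 and len(bottom) == 15
        assert "d19" in top and "d19" not in bottom
        assert "d00" in bottom and "d00" not in top
        assert set(top[:5]) & set(bottom) == set()

    def test_tie_at_cutoff_flagged_lexicographic(self):
        vals = {f"d{i}": [1.0 - 0.1 * i] for i in range(4)}
        vals["dz"] = vals["d3"]  # tie at the k=4 cutoff with d3
        med, top, _, tie = rank_by_median(self._corr_frame(vals), k=4)
        assert tie
        assert top[-1] == "d3"  # lexicographic winner at the tied cutoff


class TestCategoryEnrichment:
    def test_hand_contingency(self):
        drugs = [f"d{i}" for i in range(100)]
        cats = ["met"] * 5 + ["other"] * 10 + ["met"] * 10 + ["other"] * 75
        universe = pd.DataFrame({"drug": drugs, "category": cats})
        selected = drugs[:15]  # 5 met + 10 other
        res = category_enrichment(selected, universe)
        assert res.loc["met", ["a", "b", "c", "d"]].tolist() == [5, 10, 10, 75]
        assert res.loc["met", "odds_ratio"] == pytest.approx(3.75)

    def test_all_selected_gives_unit_odds(self):
        universe = pd.DataFrame({"drug": ["a", "b"], "category": ["x", "y"]})
        res = category_enrichment(["a", "b"], universe)
        # with no unselected drugs the odds ratio degenerates; both zero
        # cells sit in the unselected margin
        assert (res["c"] == 0).all() and (res["d"] == 0).all()

    def test_absent_category_reported_missing(self):
        universe = pd.DataFrame({"drug": ["a", "b"],
                                 "category": [np.nan, "x"]})
        res = category_enrichment(["a"], universe)
        assert "other" in res.index  # missing category coerced


class TestPermutationCalibration:
    def _null_panel(self, seed, n_lines=20, n_drugs=5, n_types=2):
        rng = np.random.default_rng(seed)
        rows = []
        for t in range(n_types):
            pct = rng.normal(10, 3, size=n_lines)
            for d in range(n_drugs):
                ic = rng.normal(size=n_lines)
                for i in range(n_lines):
                    rows.append((f"t{t}L{i}", f"t{t}", pct[i], f"d{d}", ic[i]))
        return panel(rows)

    def test_b_equal_one_edge(self):
        res = permutation_calibration(self._null_panel(0), B=1, seed=1)
        assert res["p_upper"] in (0.5, 1.0)
        assert res["p_lower"] in (0.5, 1.0)

    def test_null_panel_not_significant(self):
        res = permutation_calibration(self._null_panel(3), B=99, seed=2)
        assert res["p_upper"] > 0.05
        assert res["p_lower"] > 0.05

    def test_planted_tail_detected(self):
        rng = np.random.default_rng(7)
        rows = []
        for t in range(2):
            z = rng.normal(size=40)
            pct = 10 + 3 * z
            for d in range(10):
                r = 0.8 if d == 0 else 0.0
                ic = r * z + np.sqrt(1 - r * r) * rng.normal(size=40)
                for i in range(40):
                    rows.append((f"t{t}L{i}", f"t{t}", pct[i], f"d{d}", ic[i]))
        res = permutation_calibration(panel(rows), B=99, seed=0)
        assert res["p_upper"] < 0.05

    def test_too_few_lines_everywhere_errors(self):
        t = simple_panel([1, 2], [3, 4])
        with pytest.raises(ValueError, match="permute"):
            permutation_calibration(t, B=5)

    def test_median_r_sign_symmetric_under_exchangeability(self):
        # flipping IC50 signs mirrors the per-drug median-r distribution
        tbl = self._null_panel(11)
        med1, _, _, _ = rank_by_median(per_type_correlations(tbl))
        flipped = tbl.assign(ic50=-tbl["ic50"])
        med2, _, _, _ = rank_by_median(per_type_correlations(flipped))
        np.testing.assert_allclose(med1.to_numpy(), -med2.to_numpy(), atol=1e-12)
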