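"""pctMT vs drug-sensitivity association in cell-line panels.

For every (drug, cancer type) with at least three cell lines, the Pearson
correlation between pctMT and IC50 is computed with a Student-t p-value
(t = r * sqrt((n-2)/(1-r^2)), n-2 df). Drugs are ranked by their median
correlation across cancer types; the top/bottom 15 are tested for drug-target
category enrichment with a two-sided Fisher exact test. A permutation scheme
that shuffles pctMT within each cancer type calibrates how far the observed
tails of the median-correlation distribution sit from chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "DrugAssocResult",
    "per_type_correlations",
    "rank_by_median",
    "category_enrichment",
    "permutation_calibration",
    "analyze_drug_response",
]

REQUIRED_COLUMNS = ("cell_line", "cancer_type", "pctmt", "drug", "ic50")


@dataclass
class DrugAssocResult:
    correlations: pd.DataFrame  # per (drug, cancer_type)
    median_r: pd.Series  # per drug
    top: list[str]
    bottom: list[str]
    tie_at_cutoff: bool
    enrichment: pd.DataFrame | None = None
    permutation: dict | None = None


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"drug-response table missing columns: {missing}")


def per_type_correlations(
    table: pd.DataFrame, min_n: int = 3, log_ic50: bool = False
) -> pd.DataFrame:
    """Pearson r, t and p per (drug, cancer_type); small/degenerate pairs
    are reported with an ``excluded`` reason instead of a correlation."""
    _validate(table)
    rows = []
    for (drug, ctype), sub in table.groupby(["drug", "cancer_type"], sort=True):
        x = sub["pctmt"].to_numpy(dtype=float)
        y = sub["ic50"].to_numpy(dtype=float)
        if log_ic50:
            y = np.log(y)
        n = len(sub)
        rec = {"drug": drug, "cancer_type": ctype, "n": n}
        if n < min_n:
            rec["excluded"] = f"n<{min_n}"
        elif np.ptp(x) == 0 or np.ptp(y) == 0:
            rec["excluded"] = "constant variable"
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(min(r, 1.0), -1.0)
            if abs(r) == 1.0:
                t, p = np.inf * np.sign(r), 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
            rec.update({"pearson_r": r, "t_stat": float(t), "p": float(p)})
        rows.append(rec)
    df = pd.DataFrame(rows)
    if "excluded" not in df.columns:
        df["excluded"] = pd.NA
    return df


def rank_by_median(
    correlations: pd.DataFrame, k: int = 15
) -> tuple[pd.Series, list[str], list[str], bool]:
    """Per-drug median r over cancer types; top/bottom-k drug lists.

    Ties at a cutoff are broken lexicographically by drug name and flagged.
    Returns (median_r, top_k, bottom_k, tie_at_cutoff).
    """
    valid = correlations[correlations["excluded"].isna()]
    if valid.empty:
        raise ValueError("no valid (drug, cancer_type) correlations")
    med = valid.groupby("drug")["pearson_r"].median()
    # deterministic: sort by (-median, name) for top, (median, name) for bottom
    top_order = med.sort_values(ascending=False, kind="stable")
    top_sorted = sorted(med.index, key=lambda d: (-med[d], d))
    bot_sorted = sorted(med.index, key=lambda d: (med[d], d))
    k = min(k, len(med))
    top = top_sorted[:k]
    bottom = bot_sorted[:k]
    tie = False
    if len(med) > k:
        tie = (
            med[top_sorted[k - 1]] == med[top_sorted[k]]
            or med[bot_sorted[k - 1]] == med[bot_sorted[k]]
        )
    del top_order
    return med, top, bottom, bool(tie)


def category_enrichment(
    selected: list[str], all_drugs: pd.DataFrame
) -> pd.DataFrame:
    """Fisher exact enrichment of drug-target categories in a selection.

    ``all_drugs`` needs columns drug, category (one row per drug; missing
    categories become "other"). For each category the 2x2 table is
    {selected&cat, selected&!cat, unselected&cat, unselected&!cat}. A category
    absent from the universe is reported with missing OR/p.
    """
    drugs = all_drugs.drop_duplicates("drug").set_index("drug")
    cat = drugs.get("category")
    if cat is None:
        raise ValueError("all_drugs lacks a category column")
    cat = cat.fillna("other")
    unknown = set(selected) - set(cat.index)
    if unknown:
        raise ValueError(f"selected drugs missing from universe: {sorted(unknown)}")
    sel = cat.index.isin(selected)
    rows = []
    for c in sorted(cat.unique()):
        in_cat = (cat == c).to_numpy()
        a = int((sel & in_cat).sum())
        b = int((sel & ~in_cat).sum())
        c_ = int((~sel & in_cat).sum())
        d = int((~sel & ~in_cat).sum())
        if (a + c_) == 0:
            rows.append(
                {"category": c, "a": a, "b": b, "c": c_, "d": d,
                 "odds_ratio": np.nan, "p": np.nan}
            )
            continue
        odds, p = scipy.stats.fisher_exact([[a, b], [c_, d]], alternative="two-sided")
        rows.append(
            {"category": c, "a": a, "b": b, "c": c_, "d": d,
             "odds_ratio": float(odds), "p": float(p)}
        )
    return pd.DataFrame(rows).set_index("category")


def permutation_calibration(
    table: pd.DataFrame,
    B: int = 1000,
    tail_quantiles: tuple[float, float] = (0.05, 0.95),
    seed: int | None = 0,
    log_ic50: bool = False,
) -> dict:
    """Permutation null for the tails of the per-drug median-r distribution.

    pctMT is shuffled across cell lines within each cancer type (one shared
    permutation per type per iteration, preserving each line's value across
    its drugs), the per-drug median correlation is recomputed, and the
    observed lower/upper tail quantiles are compared to their null
    distributions. Empirical p-values carry the +1 correction.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    _validate(table)
    sizes = table.groupby("cancer_type")["cell_line"].nunique()
    if (sizes < 3).all():
        raise ValueError("every cancer type has <3 cell lines; nothing to permute")
    rng = np.random.default_rng(seed)

    obs_corr = per_type_correlations(table, log_ic50=log_ic50)
    obs_med, _, _, _ = rank_by_median(obs_corr)
    qlo, qhi = tail_quantiles
    obs_lo = float(np.quantile(obs_med, qlo))
    obs_hi = float(np.quantile(obs_med, qhi))

    # per cancer type: the unique lines and each row's line position
    line_maps = {}
    for ctype, sub in table.groupby("cancer_type"):
        lines = sub["cell_line"].unique()
        pct = sub.drop_duplicates("cell_line").set_index("cell_line")["pctmt"]
        line_maps[ctype] = (lines, pct.loc[lines].to_numpy())

    null_lo = np.empty(B)
    null_hi = np.empty(B)
    perm_table = table.copy()
    for b in range(B):
        for ctype, (lines, vals) in line_maps.items():
            perm = rng.permutation(vals)
            mapping = dict(zip(lines, perm))
            sel = perm_table["cancer_type"] == ctype
            perm_table.loc[sel, "pctmt"] = (
                perm_table.loc[sel, "cell_line"].map(mapping).to_numpy()
            )
        corr = per_type_correlations(perm_table, log_ic50=log_ic50)
        med, _, _, _ = rank_by_median(corr)
        null_lo[b] = np.quantile(med, qlo)
        null_hi[b] = np.quantile(med, qhi)
    p_upper = (1.0 + float((null_hi >= obs_hi).sum())) / (B + 1.0)
    p_lower = (1.0 + float((null_lo <= obs_lo).sum())) / (B + 1.0)
    return {
        "B": B,
        "tail_quantiles": tail_quantiles,
        "observed": {"lower": obs_lo, "upper": obs_hi},
        "null_mean": {"lower": float(null_lo.mean()), "upper": float(null_hi.mean())},
        "null_sd": {"lower": float(null_lo.std()), "upper": float(null_hi.std())},
        "p_lower": p_lower,
        "p_upper": p_upper,
    }


def analyze_drug_response(
    table: pd.DataFrame,
    k: int = 15,
    B: int | None = None,
    seed: int | None = 0,
    log_ic50: bool = False,
) -> DrugAssocResult:
    """End-to-end drug association: correlations, ranking, enrichment,
    and (when ``B`` is set) the permutation calibration."""
    corr = per_type_correlations(table, log_ic50=log_ic50)
    med, top, bottom, tie = rank_by_median(corr, k=k)
    enrichment = None
    if "category" in table.columns:
        universe = table[["drug", "category"]]
        enrichment = pd.concat(
            {
                "top": category_enrichment(top, universe),
                "bottom": category_enrichment(bottom, universe),
            },
            names=["selection", "category"],
        )
    perm = None
    if B:
        perm = permutation_calibration(table, B=B, seed=seed, log_ic50=log_ic50)
    return DrugAssocResult(
        correlations=corr,
        median_r=med,
        top=top,
        bottom=bottom,
        tie_at_cutoff=tie,
        enrichment=enrichment,
        permutation=perm,
    )
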