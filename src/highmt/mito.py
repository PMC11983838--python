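"""pctMT, HighMT classification and patient-level case/control annotation.

pctMT is the percentage of a cell's counts mapping to mitochondrially encoded
genes (0-100 scale). Cells above 15% are HighMT. Per patient, a 2x2 table of
HighMT/LowMT by malignant/TME yields an odds ratio

    OR = (n(HighMT,mal)/n(LowMT,mal)) / (n(HighMT,TME)/n(LowMT,TME))

and a patient is a *case* when OR > 2 and at least 15% of its malignant cells
are HighMT; patients with fewer than 30 cells in either compartment or fewer
than 20 HighMT cells overall are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import CellTable, GeneSet, mt_gene_mask

__all__ = [
    "PatientMTSummary",
    "compute_pctmt",
    "classify_highmt",
    "patient_odds_ratio",
    "patient_contingency",
    "annotate_case_control",
    "clinical_association",
]


@dataclass
class PatientMTSummary:
    patient_id: str
    n_highmt_mal: int
    n_lowmt_mal: int
    n_highmt_tme: int
    n_lowmt_tme: int
    odds_ratio: float = np.nan
    or_corrected: bool = False
    highmt_malignant_fraction: float = np.nan
    status: str = "unassigned"  # case | control | excluded
    exclusion_reason: str | None = None

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.n_highmt_mal,
            self.n_lowmt_mal,
            self.n_highmt_tme,
            self.n_lowmt_tme,
        )


def compute_pctmt(
    t: CellTable, mt_genes: GeneSet | None = None, prefix: str = "MT-"
) -> pd.Series:
    """Percent of counts in detected mitochondrial genes, per cell (0-100)."""
    mask = mt_gene_mask(t.gene_ids, mt_genes, prefix=prefix)
    if not mask.any():
        raise ValueError("no mitochondrial gene detected in the gene index")
    totals = t.total_counts().astype(float)
    if (totals <= 0).any():
        bad = list(t.cell_ids[totals <= 0][:10])
        raise ValueError(f"cells with zero total counts: {bad}")
    mt_counts = np.asarray(t.counts[:, mask].sum(axis=1)).ravel()
    return pd.Series(100.0 * mt_counts / totals, index=t.cell_ids, name="pctMT")


def classify_highmt(pctmt: pd.Series, threshold: float = 15.0) -> pd.Series:
    """HighMT iff pctMT strictly above the threshold (percent scale)."""
    return pd.Series(
        np.where(pctmt.to_numpy() > threshold, "HighMT", "LowMT"),
        index=pctmt.index,
        name="mt_status",
    )


def patient_odds_ratio(
    n_highmt_mal: int, n_lowmt_mal: int, n_highmt_tme: int, n_lowmt_tme: int
) -> tuple[float, bool]:
    """Cross-product odds ratio of HighMT between compartments.

    If any cell of the 2x2 table is zero, 0.5 is added to all four
    (Haldane-Anscombe) and the returned flag is True.
    """
    cells = np.array(
        [n_highmt_mal, n_lowmt_mal, n_highmt_tme, n_lowmt_tme], dtype=float
    )
    if (cells < 0).any():
        raise ValueError("negative counts")
    if cells.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    return (a / b) / (c / d), corrected


def patient_contingency(
    t: CellTable, mt_status: pd.Series
) -> list[PatientMTSummary]:
    """Per-patient HighMT/LowMT x malignant/TME counts with OR and fraction."""
    df = pd.DataFrame(
        {
            "patient_id": t.cell_meta["patient_id"].values,
            "compartment": t.cell_meta["compartment"].values,
            "mt_status": mt_status.reindex(t.cell_ids).values,
        }
    )
    out = []
    for pid, sub in df.groupby("patient_id", sort=True):
        n = {
            (m, c): int(((sub["mt_status"] == m) & (sub["compartment"] == c)).sum())
            for m in ("HighMT", "LowMT")
            for c in ("malignant", "TME")
        }
        s = PatientMTSummary(
            patient_id=pid,
            n_highmt_mal=n[("HighMT", "malignant")],
            n_lowmt_mal=n[("LowMT", "malignant")],
            n_highmt_tme=n[("HighMT", "TME")],
            n_lowmt_tme=n[("LowMT", "TME")],
        )
        n_mal = s.n_highmt_mal + s.n_lowmt_mal
        if n_mal > 0:
            s.highmt_malignant_fraction = s.n_highmt_mal / n_mal
        if sum(s.counts) > 0:
            s.odds_ratio, s.or_corrected = patient_odds_ratio(*s.counts)
        out.append(s)
    return out


def annotate_case_control(
    summaries: list[PatientMTSummary],
    or_threshold: float = 2.0,
    frac_threshold: float = 0.15,
    min_compartment: int = 30,
    min_highmt: int = 20,
) -> list[PatientMTSummary]:
    """Assign case/control/excluded status in place and return the list.

    Exclusion: fewer than ``min_compartment`` cells in either compartment, or
    fewer than ``min_highmt`` HighMT cells in total. Case: OR strictly above
    ``or_threshold`` AND HighMT malignant fraction at least ``frac_threshold``.
    """
    for s in summaries:
        n_mal = s.n_highmt_mal + s.n_lowmt_mal
        n_tme = s.n_highmt_tme + s.n_lowmt_tme
        n_high = s.n_highmt_mal + s.n_highmt_tme
        if n_mal < min_compartment:
            s.status, s.exclusion_reason = "excluded", f"malignant<{min_compartment}"
        elif n_tme < min_compartment:
            s.status, s.exclusion_reason = "excluded", f"TME<{min_compartment}"
        elif n_high < min_highmt:
            s.status, s.exclusion_reason = "excluded", f"HighMT<{min_highmt}"
        elif (
            s.odds_ratio > or_threshold
            and s.highmt_malignant_fraction >= frac_threshold
        ):
            s.status, s.exclusion_reason = "case", None
        else:
            s.status, s.exclusion_reason = "control", None
    return summaries


def summaries_to_frame(summaries: list[PatientMTSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "n_highmt_mal": s.n_highmt_mal,
                "n_lowmt_mal": s.n_lowmt_mal,
                "n_highmt_tme": s.n_highmt_tme,
                "n_lowmt_tme": s.n_lowmt_tme,
                "odds_ratio": s.odds_ratio,
                "or_corrected": s.or_corrected,
                "highmt_malignant_fraction": s.highmt_malignant_fraction,
                "status": s.status,
                "exclusion_reason": s.exclusion_reason,
            }
            for s in summaries
        ]
    ).set_index("patient_id")


def clinical_association(
    summaries: list[PatientMTSummary], clinical: pd.Series
) -> pd.DataFrame:
    """Mann-Whitney U on per-patient HighMT malignant fractions between each
    pair of clinical groups.

    ``clinical`` maps patient_id -> label. Groups with fewer than two patients
    are skipped with a warning. Returns a DataFrame with one row per compared
    label pair (U and two-sided p for the first-named group).
    """
    frac = {
        s.patient_id: s.highmt_malignant_fraction
        for s in summaries
        if np.isfinite(s.highmt_malignant_fraction)
    }
    groups: dict[str, list[float]] = {}
    for pid, lab in clinical.items():
        if pid in frac:
            groups.setdefault(str(lab), []).append(frac[pid])
    usable = {}
    for lab, vals in sorted(groups.items()):
        if len(vals) < 2:
            warnings.warn(f"clinical group {lab!r} has <2 patients; skipped")
            continue
        usable[lab] = vals
    rows = []
    labs = list(usable)
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            a, b = usable[labs[i]], usable[labs[j]]
            res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "group_a": labs[i],
                    "group_b": labs[j],
                    "n_a": len(a),
                    "n_b": len(b),
                    "U": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)
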