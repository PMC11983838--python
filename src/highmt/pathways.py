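"""Pathway dysregulation between HighMT and LowMT malignant metacells.

Each pathway is summarized per study by the difference of median signature
scores (HighMT minus LowMT) over malignant metacells; the resulting pathway x
study matrix is clustered with Ward linkage on Euclidean distances. The
xenobiotic-metabolism comparison scores the three phases (CYP oxidation,
UGT/GST conjugation, ABC efflux) and tests HighMT vs LowMT per phase and
study with a two-sided Mann-Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats

from .core import GeneSet, GeneSetCollection, NormalizedMatrix
from .scoring import ScoreVector, score_signature

__all__ = [
    "PathwayDeltaMatrix",
    "pathway_delta",
    "delta_matrix",
    "cluster_pathways",
    "xenobiotic_phase_comparison",
]


@dataclass
class PathwayDeltaMatrix:
    """Pathway x study matrix of median-score deltas, NaN where undefined."""

    deltas: pd.DataFrame
    linkage: np.ndarray | None = None

    def ordered_pathways(self) -> list[str]:
        """Pathways sorted by median delta across studies, descending."""
        return list(
            self.deltas.median(axis=1, skipna=True).sort_values(ascending=False).index
        )


def pathway_delta(scores: ScoreVector | pd.Series, labels: pd.Series) -> float:
    """median(HighMT scores) - median(LowMT scores); NaN if a group is empty."""
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    lab = labels.reindex(s.index)
    hi = s[lab == "HighMT"]
    lo = s[lab == "LowMT"]
    if hi.empty or lo.empty:
        warnings.warn("empty HighMT or LowMT group; delta undefined")
        return float("nan")
    return float(hi.median() - lo.median())


def delta_matrix(
    matrices: dict[str, NormalizedMatrix],
    labels: dict[str, pd.Series],
    pathways: GeneSetCollection,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> PathwayDeltaMatrix:
    """Score every pathway in every study and tabulate median deltas.

    ``matrices`` maps study -> normalized malignant-metacell matrix;
    ``labels`` maps study -> HighMT/LowMT labels on the same observations.
    Control-gene binning is per study (each study's own expression ranks).
    """
    out = {}
    for study, norm in matrices.items():
        col = {}
        for sig in pathways:
            try:
                sv = score_signature(
                    norm, sig, n_bins=n_bins, ctrl_size=ctrl_size, seed=seed
                )
            except ValueError:
                col[sig.name] = float("nan")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                col[sig.name] = pathway_delta(sv, labels[study])
        out[study] = col
    return PathwayDeltaMatrix(deltas=pd.DataFrame(out))


def cluster_pathways(
    m: PathwayDeltaMatrix, drop_incomplete: bool = True
) -> np.ndarray:
    """Ward linkage over pathway row-vectors (Euclidean distances).

    Rows with missing entries are dropped by default; pass
    ``drop_incomplete=False`` to raise on missing values instead.
    """
    df = m.deltas
    if df.isna().any().any():
        if not drop_incomplete:
            raise ValueError("delta matrix has missing entries")
        df = df.dropna(axis=0)
    if len(df) < 2:
        raise ValueError("need at least two complete pathway rows to cluster")
    linkage = scipy.cluster.hierarchy.linkage(
        df.to_numpy(), method="ward", metric="euclidean"
    )
    m.linkage = linkage
    return linkage


def xenobiotic_phase_comparison(
    norm: NormalizedMatrix,
    phase_sets: list[GeneSet],
    labels: pd.Series,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mann-Whitney U of phase-signature scores, HighMT vs LowMT metacells.

    Returns one row per phase with U, two-sided p and the median difference;
    phases whose gene set misses the matrix entirely are skipped with a
    warning.
    """
    rows = []
    for sig in phase_sets:
        if not sig.intersect(norm.gene_ids):
            warnings.warn(f"phase set {sig.name!r} absent from matrix; skipped")
            continue
        sv = score_signature(norm, sig, n_bins=n_bins, ctrl_size=ctrl_size, seed=seed)
        lab = labels.reindex(sv.scores.index)
        hi = sv.scores[lab == "HighMT"]
        lo = sv.scores[lab == "LowMT"]
        if hi.empty or lo.empty:
            warnings.warn(f"{sig.name!r}: empty HighMT or LowMT group; skipped")
            continue
        res = scipy.stats.mannwhitneyu(hi, lo, alternative="two-sided")
        rows.append(
            {
                "phase": sig.name,
                "n_highmt": len(hi),
                "n_lowmt": len(lo),
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "median_delta": float(hi.median() - lo.median()),
            }
        )
    return pd.DataFrame(rows)
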