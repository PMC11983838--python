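"""Bin-controlled gene-signature scoring and score-based association.

The scorer follows the Tirosh-style control-gene scheme popularized by the
single-cell ecosystem: genes are ranked by mean expression over the scored
observations and cut into ``n_bins`` equal-size bins; each signature gene
contributes ``ctrl_size`` control genes sampled (with replacement, seeded)
from the non-signature genes of its bin, and the score is the mean signature
expression minus the mean over the unique control-gene set.

When a bin contains no non-signature gene, the control pool widens to the
nearest bins that still hold non-signature genes. A signature covering every
gene takes the full gene index as its control set, making its score
identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import GeneSet, NormalizedMatrix

__all__ = [
    "ScoreVector",
    "score_signature",
    "build_meta_signature",
    "point_biserial",
    "assign_by_max_score",
]


@dataclass
class ScoreVector:
    name: str
    scores: pd.Series  # indexed by observation id
    n_bins: int
    ctrl_size: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.scores)


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank genes by mean expression and cut into equal-size bins."""
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=int)
    # equal-size by rank; sizes differ by at most one
    bins[order] = np.floor(
        np.arange(len(mean_expr)) * n_bins / len(mean_expr)
    ).astype(int)
    return bins


def score_signature(
    n: NormalizedMatrix,
    sig: GeneSet,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int | None = 0,
) -> ScoreVector:
    """Score observations for a signature against bin-matched controls."""
    if n_bins > n.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes {n.n_genes}")
    sig_genes = sig.intersect(n.gene_ids)
    if not sig_genes:
        raise ValueError(f"signature {sig.name!r} has no gene in the matrix")
    rng = np.random.default_rng(seed)
    mean_expr = n.values.mean(axis=0)
    bins = _expression_bins(mean_expr, n_bins)
    sig_idx = np.array([n.gene_ids.get_loc(g) for g in sig_genes])
    in_sig = np.zeros(n.n_genes, dtype=bool)
    in_sig[sig_idx] = True

    ctrl: set[int] = set()
    if not (~in_sig).any():
        # signature covers every gene: the whole index is its own control,
        # making the score identically zero
        ctrl.update(range(n.n_genes))
    else:
        for j in sig_idx:
            pool = np.nonzero((bins == bins[j]) & ~in_sig)[0]
            width = 1
            while len(pool) == 0:
                # bin exhausted by the signature: widen to neighboring bins
                near = np.abs(bins - bins[j]) <= width
                pool = np.nonzero(near & ~in_sig)[0]
                width += 1
            ctrl.update(rng.choice(pool, size=ctrl_size, replace=True).tolist())
    ctrl_idx = np.fromiter(ctrl, dtype=int)
    scores = n.values[:, sig_idx].mean(axis=1) - n.values[:, ctrl_idx].mean(axis=1)
    return ScoreVector(
        name=sig.name,
        scores=pd.Series(scores, index=n.cell_ids, name=sig.name),
        n_bins=n_bins,
        ctrl_size=ctrl_size,
        seed=seed,
    )


def build_meta_signature(sets: list[GeneSet], name: str = "meta") -> GeneSet:
    """Exact intersection of two or more gene sets."""
    if len(sets) < 2:
        raise ValueError("meta-signature requires at least two gene sets")
    common = frozenset.intersection(*(s.genes for s in sets))
    if not common:
        raise ValueError(
            "gene sets share no common gene; supply larger or related sets"
        )
    return GeneSet(name=name, genes=common)


def point_biserial(score: ScoreVector | pd.Series, group) -> tuple[float, float]:
    """Point-biserial correlation of a score with a binary grouping.

    Equals the Pearson correlation of the score with the 0/1-coded group;
    the p-value comes from the t distribution with n-2 degrees of freedom.
    """
    s = score.scores if isinstance(score, ScoreVector) else score
    x = np.asarray(s, dtype=float)
    g = np.asarray(group)
    if g.dtype != bool:
        uniq = sorted(pd.unique(g).tolist())
        if len(uniq) != 2:
            raise ValueError(f"group must be binary; got {len(uniq)} levels")
        g = g == uniq[1]
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    if np.ptp(x) == 0:
        raise ValueError("score has zero variance")
    r, p = scipy.stats.pearsonr(x, g.astype(float))
    return float(r), float(p)


def assign_by_max_score(scores: dict[str, pd.Series]) -> pd.DataFrame:
    """Label each observation by its maximal score; lexicographic tie-break.

    Returns a DataFrame with columns ``label`` and boolean ``tie``.
    """
    if not scores:
        raise ValueError("no score vectors supplied")
    df = pd.DataFrame(
        {k: (v.scores if isinstance(v, ScoreVector) else v) for k, v in scores.items()}
    )
    df = df[sorted(df.columns)]
    arr = df.to_numpy()
    best = arr.max(axis=1)
    tie = (arr == best[:, None]).sum(axis=1) > 1
    label = df.columns[arr.argmax(axis=1)]  # argmax takes first = lexicographic
    return pd.DataFrame({"label": label, "tie": tie}, index=df.index)
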