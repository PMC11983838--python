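"""Patch-grid summaries of malignant pctMT in spatial cell tables.

Cells carry pixel coordinates, a pctMT value, total counts and a malignant
flag. The field is tiled by an origin-anchored grid of ``patch_px`` squares
(half-open intervals); each patch is summarized by the median pctMT of its
malignant cells, and patches with fewer than ``min_cells`` malignant cells
are excluded. A Spearman check of pctMT against total counts, per
compartment, guards against depth confounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "PatchSummary",
    "assign_patches",
    "patch_median_pctmt",
    "counts_confounder_check",
]

SPATIAL_COLUMNS = ("x", "y", "pctmt", "malignant_flag")


@dataclass
class PatchSummary:
    patch: tuple[int, int]
    n_malignant: int
    median_pctmt: float  # NaN when excluded
    excluded: bool
    bounds_px: tuple[float, float, float, float]  # x0, y0, x1, y1


def _validate(t: pd.DataFrame) -> None:
    missing = [c for c in SPATIAL_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"spatial table missing columns: {missing}")
    if (t["x"] < 0).any() or (t["y"] < 0).any():
        raise ValueError("negative pixel coordinates")


def assign_patches(t: pd.DataFrame, patch_px: float = 1000.0) -> pd.DataFrame:
    """Assign every cell to patch (floor(x/p), floor(y/p)); grid at origin."""
    _validate(t)
    if patch_px <= 0:
        raise ValueError("patch_px must be positive")
    out = t.copy()
    out["patch_i"] = np.floor(out["x"].to_numpy() / patch_px).astype(int)
    out["patch_j"] = np.floor(out["y"].to_numpy() / patch_px).astype(int)
    return out


def patch_median_pctmt(
    t: pd.DataFrame, patch_px: float = 1000.0, min_cells: int = 10
) -> list[PatchSummary]:
    """Median malignant pctMT per patch; sparse patches are excluded.

    Only patches containing at least one cell appear; a patch is excluded
    (median NaN) when it has fewer than ``min_cells`` malignant cells.
    """
    cells = assign_patches(t, patch_px)
    out = []
    for (i, j), sub in cells.groupby(["patch_i", "patch_j"], sort=True):
        mal = sub.loc[sub["malignant_flag"].astype(bool), "pctmt"]
        excluded = len(mal) < min_cells
        out.append(
            PatchSummary(
                patch=(int(i), int(j)),
                n_malignant=int(len(mal)),
                median_pctmt=float("nan") if excluded else float(mal.median()),
                excluded=excluded,
                bounds_px=(
                    i * patch_px,
                    j * patch_px,
                    (i + 1) * patch_px,
                    (j + 1) * patch_px,
                ),
            )
        )
    return out


def summaries_to_frame(summaries: list[PatchSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patch_i": s.patch[0],
                "patch_j": s.patch[1],
                "n_malignant": s.n_malignant,
                "median_pctmt": s.median_pctmt,
                "excluded": s.excluded,
            }
            for s in summaries
        ]
    )


def counts_confounder_check(
    t: pd.DataFrame, method: str = "spearman", min_n: int = 3
) -> pd.DataFrame:
    """Correlation of pctMT with total counts, per compartment.

    Spearman by default (Pearson via ``method``); compartments with fewer
    than ``min_n`` cells are skipped. Returns one row per compartment.
    """
    _validate(t)
    if "total_counts" not in t.columns:
        raise ValueError("spatial table missing total_counts")
    rows = []
    for name, sub in (
        ("malignant", t[t["malignant_flag"].astype(bool)]),
        ("non_malignant", t[~t["malignant_flag"].astype(bool)]),
    ):
        if len(sub) < min_n:
            continue
        x = sub["pctmt"].to_numpy(dtype=float)
        y = sub["total_counts"].to_numpy(dtype=float)
        if method == "spearman":
            rho, p = scipy.stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = scipy.stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {"compartment": name, "n": len(sub), "rho": float(rho), "p": float(p)}
        )
    return pd.DataFrame(rows)
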