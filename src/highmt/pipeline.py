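"""End-to-end orchestration over synthetic or user-supplied cohorts.

``run_pipeline`` executes the stages in dependency order — simulate, QC,
pctMT/case-control, signature scoring, metacells, pathway deltas, bulk vs
bulkified testing, drug association, spatial patches — writes every result
as TSV/JSON under an output directory, and records a run manifest (config
snapshot, seeds, output digests) sufficient to reproduce the run
bit-identically. ``compare_filtering_strategies`` contrasts pctMT-free QC,
threshold QC and an external keep-list on the same cohort.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import scipy.stats

from . import bulk, drugs, mito, pathways, qc, scoring, spatial
from .core import CellTable, GeneSet, GeneSetCollection, write_counts
from .metacell import build_metacells, label_metacells
from .mito import summaries_to_frame
from .synthetic import SynthConfig, mt_gene_set, simulate_bulk_pair, \
    simulate_cell_lines, simulate_cohort, simulate_spatial

__all__ = ["RunManifest", "run_pipeline", "compare_filtering_strategies",
           "default_config"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, path: Path) -> None:
        self.digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def default_config(seed: int = 0) -> dict:
    """Named defaults for every stage (thresholds on their native scales)."""
    return {
        "seed": seed,
        "synthetic": {
            "stress_effect": 0.8,
            "junk_fraction": 0.05,
            "planted_pathway_effects": {"PW_PLANTED": 0.8},
            "mt_excess": {"P00": 3.0},
            "drug_params": {"drugA": 0.6, "drugB": 0.0, "drugC": -0.5,
                            "drugD": 0.0, "drugE": 0.2},
        },
        "qc": {"n_mads": 5.0, "min_counts": 1500, "max_counts": 50000,
               "min_genes": 500},
        "mito": {"highmt_threshold": 15.0, "or_threshold": 2.0,
                 "frac_threshold": 0.15, "min_compartment": 30,
                 "min_highmt": 20},
        "scoring": {"n_bins": 25, "ctrl_size": 50},
        "metacell": {"target_size": 25, "highmt_frac": 0.30,
                     "malignant_frac": 0.50},
        "bulk": {"B": 200, "pool_size": 200, "epsilon": 0.01,
                 "correction": "bonferroni", "mode": "sum_log1p"},
        "drugs": {"k": 15, "B": 200},
        "spatial": {"patch_px": 1000.0, "min_cells": 10},
        "comparison": {"pctmt_filter_threshold": 15.0},
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def compare_filtering_strategies(
    t: CellTable,
    program: GeneSet,
    threshold: float = 15.0,
    external_keep: pd.Series | None = None,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> dict:
    """Contrast QC strategies by the score distribution of a gene program.

    ``t`` must already be pctMT-annotated and pctMT-free-QC-filtered. The
    three strategies are: keep everything (pctMT-free), drop cells above the
    pctMT threshold, and an externally supplied keep-list. The program is
    scored once on the full table (identical controls) and the per-strategy
    malignant-cell score distributions are compared with two-sided
    Mann-Whitney U tests.
    """
    if "pctMT" not in t.cell_meta.columns:
        raise ValueError("annotate pctMT before comparing strategies")
    from .core import normalize_cp10k_log1p

    norm = normalize_cp10k_log1p(t)
    sv = scoring.score_signature(
        norm, program, n_bins=n_bins, ctrl_size=ctrl_size, seed=seed
    )
    mal = t.cell_meta["compartment"] == "malignant"
    keep = {
        "pctmt_free": pd.Series(True, index=t.cell_ids),
        "threshold": t.cell_meta["pctMT"] <= threshold,
    }
    if external_keep is not None:
        keep["external"] = external_keep.reindex(t.cell_ids).fillna(False).astype(bool)
    dists = {
        name: sv.scores[(k & mal).to_numpy()] for name, k in keep.items()
    }
    out = {"n_kept_malignant": {k: int(len(v)) for k, v in dists.items()}}
    for a, b in (("pctmt_free", "threshold"), ("pctmt_free", "external")):
        if b not in dists:
            continue
        if dists[a].empty or dists[b].empty:
            out[f"{a}_vs_{b}"] = {"p": float("nan")}
            continue
        res = scipy.stats.mannwhitneyu(dists[a], dists[b], alternative="two-sided")
        out[f"{a}_vs_{b}"] = {
            "U": float(res.statistic),
            "p": float(res.pvalue),
            "mean_shift": float(dists[b].mean() - dists[a].mean()),
        }
    return out


def run_pipeline(config: dict | None = None, outdir: str | Path = "highmt_run",
                 write_cohort: bool = False) -> RunManifest:
    """Run every stage on a synthetic cohort and write results under outdir."""
    cfg = _merge(default_config(), config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed)

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kw)
        manifest.record(path)
        manifest.stages.append(name)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        # --- simulate -----------------------------------------------------
        scfg = SynthConfig(seed=seed, **cfg["synthetic"])
        table, truth = simulate_cohort(scfg)
        if write_cohort:
            write_counts(table, outdir / "cohort")
        mt_set = mt_gene_set(scfg)

        # --- QC -----------------------------------------------------------
        filtered, report = qc.run_qc(table, **cfg["qc"])
        save(report.flags.astype(int), "qc_flags.tsv", index_label="cell_id")

        # --- pctMT / case-control ------------------------------------------
        mcfg = cfg["mito"]
        pct = mito.compute_pctmt(filtered, mt_set)
        status = mito.classify_highmt(pct, threshold=mcfg["highmt_threshold"])
        filtered.cell_meta["pctMT"] = pct
        filtered.cell_meta["mt_status"] = status
        summaries = mito.annotate_case_control(
            mito.patient_contingency(filtered, status),
            or_threshold=mcfg["or_threshold"],
            frac_threshold=mcfg["frac_threshold"],
            min_compartment=mcfg["min_compartment"],
            min_highmt=mcfg["min_highmt"],
        )
        save(summaries_to_frame(summaries), "patient_summary.tsv")

        # --- stress scoring ------------------------------------------------
        from .core import normalize_cp10k_log1p

        norm = normalize_cp10k_log1p(filtered)
        stress = GeneSet("stress", frozenset(truth.stress_genes))
        sv = scoring.score_signature(norm, stress, seed=seed, **cfg["scoring"])
        filtered.cell_meta["stress_score"] = sv.scores
        mal = filtered.cell_meta["compartment"] == "malignant"
        pb = {}
        if mal.any() and (status[mal.to_numpy()] == "HighMT").nunique() > 1:
            r, p = scoring.point_biserial(
                sv.scores[mal.to_numpy()],
                (status[mal.to_numpy()] == "HighMT").to_numpy(),
            )
            pb = {"point_biserial_r": r, "p": p}
        save(
            filtered.cell_meta[["patient_id", "compartment", "pctMT",
                                "mt_status", "stress_score"]],
            "cell_annotations.tsv",
            index_label="cell_id",
        )

        # --- metacells -----------------------------------------------------
        mcc = cfg["metacell"]
        mc = build_metacells(filtered, target_size=mcc["target_size"], seed=seed)
        mc = label_metacells(
            mc, filtered, status,
            highmt_frac=mcc["highmt_frac"], malignant_frac=mcc["malignant_frac"],
        )
        save(mc.meta, "metacells.tsv")
        membership = pd.DataFrame(
            [(m, c) for m, cells in mc.membership.items() for c in cells],
            columns=["metacell_id", "cell_id"],
        )
        save(membership, "metacell_membership.tsv", index=False)

        # --- pathway deltas on malignant metacells -------------------------
        mal_mc = mc.meta["malignant_label"].to_numpy(dtype=bool)
        path_result = None
        if mal_mc.any():
            sub_norm = mc.normalized()
            sub = pd.Index(mc.metacell_ids[mal_mc])
            from .core import NormalizedMatrix

            mal_norm = NormalizedMatrix(
                values=sub_norm.values[mal_mc], gene_ids=sub_norm.gene_ids,
                cell_ids=sub,
            )
            labels = pd.Series(
                mc.meta.loc[sub, "highmt_label"].to_numpy(), index=sub
            )
            sets = GeneSetCollection(
                [GeneSet(n, frozenset(g)) for n, g in truth.pathway_genes.items()]
                + [GeneSet("stress_pw", frozenset(truth.stress_genes))]
            )
            dm = pathways.delta_matrix(
                {"synthetic": mal_norm}, {"synthetic": labels}, sets,
                seed=seed, **cfg["scoring"],
            )
            save(dm.deltas, "pathway_deltas.tsv")
            path_result = dm

        # --- bulk vs bulkified ----------------------------------------------
        bcfg = cfg["bulk"]
        bulks = simulate_bulk_pair(scfg, table)
        results = bulk.run_residual_tests(
            table, bulks, mt_set, mode=bcfg["mode"], B=bcfg["B"],
            pool_size=bcfg["pool_size"], epsilon=bcfg["epsilon"],
            correction=bcfg["correction"], seed=seed,
        )
        save(
            pd.DataFrame(
                [
                    {
                        "patient_id": r.patient_id,
                        "degree": r.degree_selected,
                        "mt_mean_residual": r.mt_mean_residual,
                        "null_lo": r.null_ci95[0],
                        "null_hi": r.null_ci95[1],
                        "p_raw": r.p_raw,
                        "p_adj": r.p_adj,
                    }
                    for r in results
                ]
            ).set_index("patient_id"),
            "bulk_residuals.tsv",
        )

        # --- drugs -----------------------------------------------------------
        dcfg = cfg["drugs"]
        dtable = simulate_cell_lines(scfg)
        dres = drugs.analyze_drug_response(
            dtable, k=dcfg["k"], B=dcfg["B"], seed=seed
        )
        save(dres.correlations, "drug_correlations.tsv", index=False)

        # --- spatial ----------------------------------------------------------
        pcfg = cfg["spatial"]
        stable = simulate_spatial(scfg)
        patches = spatial.patch_median_pctmt(
            stable, patch_px=pcfg["patch_px"], min_cells=pcfg["min_cells"]
        )
        save(spatial.summaries_to_frame(patches), "spatial_patches.tsv", index=False)
        confound = spatial.counts_confounder_check(stable)
        save(confound, "spatial_confounder.tsv", index=False)

        # --- strategy comparison ----------------------------------------------
        comparison = compare_filtering_strategies(
            filtered, stress,
            threshold=cfg["comparison"]["pctmt_filter_threshold"],
            external_keep=report.keep.reindex(filtered.cell_ids),
            seed=seed, **cfg["scoring"],
        )

    summary = {
        "stress_point_biserial": pb,
        "strategy_comparison": comparison,
        "drug_top": dres.top,
        "drug_bottom": dres.bottom,
        "drug_permutation": dres.permutation,
        "n_case": sum(s.status == "case" for s in summaries),
        "n_control": sum(s.status == "control" for s in summaries),
        "n_excluded": sum(s.status == "excluded" for s in summaries),
        "pathway_order": path_result.ordered_pathways() if path_result else [],
    }
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=float, sort_keys=True) + "\n")
    manifest.record(spath)
    manifest.write(outdir / "manifest.json")
    return manifest
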