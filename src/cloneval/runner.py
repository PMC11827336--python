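"""Directory-based pipeline stages tying the modules together.

Each stage reads its inputs from, and writes its outputs to, a working
directory using the plain-text formats in :mod:`cloneval.io`, so stages
can be re-run independently (from the CLI or programmatically) and every
artifact is inspectable.  A manifest records the configuration hash, the
seed and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .mixedmodel import REMLOptions
from .pipeline import stagewise_evaluation
from .qc import QCThresholds, filter_markers_and_samples, intersect_panels, verify_and_correct_pedigree
from .relmat import DEFAULT_BLEND_ALPHA, blend, numerator_A, subset_A22, vanraden_Ga, vitezica_Gd
from .replication import fit_single_stage, replication_study
from .simulate import SimulationConfig, simulate_cpt
from .traits import add_volume_columns

log = logging.getLogger(__name__)

__all__ = [
    "stage_simulate",
    "stage_qc",
    "stage_grm",
    "stage_stagewise",
    "stage_single",
    "stage_replication",
    "run_pipeline",
    "STAGES",
]

STAGES = ["simulate", "qc", "grm", "stagewise", "single", "replication"]


def _update_manifest(outdir: Path, stage: str, info: Dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.setdefault("stages", {})[stage] = info
    cio.write_json(manifest, path)


def _timed(outdir: Path, stage: str, info: Dict, t0: float) -> None:
    info["wall_time_s"] = round(time.perf_counter() - t0, 3)
    _update_manifest(outdir, stage, info)
    log.info("stage %s done in %.2fs", stage, info["wall_time_s"])


# ----------------------------------------------------------------------
def stage_simulate(config: SimulationConfig, outdir: Path) -> Dict:
    t0 = time.perf_counter()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_cpt(config)
    pheno = add_volume_columns(ds.phenotypes)
    cio.write_phenotypes(pheno, outdir / "phenotypes.csv")
    cio.write_dosage_matrix(ds.genotyping.panel_a, outdir / "genotypes_panel_a.tsv")
    cio.write_dosage_matrix(ds.genotyping.panel_b, outdir / "genotypes_panel_b.tsv")
    cio.write_pedigree(ds.declared_pedigree, outdir / "pedigree_declared.csv")
    cio.write_pedigree(ds.truth_pedigree, outdir / "pedigree_truth.csv")
    (outdir / "founders.txt").write_text("\n".join(ds.founders.samples) + "\n")
    (outdir / "controls.txt").write_text("\n".join(ds.controls.samples) + "\n")
    cio.write_json(
        {
            "true_variances": dataclasses.asdict(config.true_variances),
            "realized_variances": ds.truth.realized_variances,
            "breeding_values": {k: v for k, v in ds.truth.breeding_values.items()},
            "dominance_deviations": {
                k: v for k, v in ds.truth.dominance_deviations.items()
            },
        },
        outdir / "truth.json",
    )
    cfg_hash = cio.config_hash(dataclasses.asdict(config))
    import numpy

    from . import __version__

    _update_manifest(
        outdir,
        "config",
        {
            "hash": cfg_hash,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "versions": {"cloneval": __version__, "numpy": numpy.__version__},
        },
    )
    _timed(
        outdir,
        "simulate",
        {"n_trees": len(pheno), "n_genotyped": len(ds.genotyped_ids), "hash": cfg_hash},
        t0,
    )
    return {"dataset": ds, "phenotypes": pheno}


def stage_qc(outdir: Path, thresholds: Optional[QCThresholds] = None, run_qc: bool = True) -> Dict:
    t0 = time.perf_counter()
    outdir = Path(outdir)
    panel_a = cio.read_dosage_matrix(outdir / "genotypes_panel_a.tsv")
    panel_b = cio.read_dosage_matrix(outdir / "genotypes_panel_b.tsv")
    merged = intersect_panels(panel_a, panel_b)
    if run_qc:
        filtered, report = filter_markers_and_samples(merged, thresholds)
    else:
        from .qc import QCReport

        filtered = merged
        report = QCReport(merged.n_markers, {}, 0, merged.n_markers, merged.n_samples)
    declared = cio.read_pedigree(outdir / "pedigree_declared.csv")
    founders = (outdir / "founders.txt").read_text().split()
    corrected, conflicts = verify_and_correct_pedigree(
        declared, filtered, founders, thresholds
    )
    cio.write_dosage_matrix(filtered, outdir / "genotypes_qc.tsv")
    cio.write_json(report.to_dict(), outdir / "qc_report.json")
    cio.write_pedigree(corrected, outdir / "pedigree_corrected.csv")
    conflicts.to_csv(outdir / "pedigree_conflicts.csv", index=False)
    _timed(
        outdir,
        "qc",
        {"markers_out": filtered.n_markers, "samples_out": filtered.n_samples},
        t0,
    )
    return {"genotypes": filtered, "report": report, "pedigree": corrected, "conflicts": conflicts}


def stage_grm(outdir: Path, alpha: float = DEFAULT_BLEND_ALPHA) -> Dict:
    t0 = time.perf_counter()
    outdir = Path(outdir)
    g = cio.read_dosage_matrix(outdir / "genotypes_qc.tsv")
    ped = cio.read_pedigree(outdir / "pedigree_corrected.csv")
    Ga = vanraden_Ga(g)
    Gd = vitezica_Gd(g, freqs=Ga.allele_freqs)
    A = numerator_A(ped)
    A22 = subset_A22(A, list(g.samples))
    Gstar = blend(Ga, A22, alpha)
    cio.write_matrix_triplet(Ga, outdir / "grm_ga.txt")
    cio.write_matrix_triplet(Gd, outdir / "grm_gd.txt")
    cio.write_matrix_triplet(Gstar, outdir / "grm_gstar.txt")
    _timed(outdir, "grm", {"n_genotyped": len(g.samples), "alpha": alpha}, t0)
    return {"Ga": Ga, "Gd": Gd, "A22": A22, "Gstar": Gstar}


def _load_kernels(outdir: Path):
    Gstar = cio.read_matrix_triplet(outdir / "grm_gstar.txt")
    Gd = cio.read_matrix_triplet(outdir / "grm_gd.txt")
    return Gstar, Gd


def stage_stagewise(
    outdir: Path,
    response: str = "vol_dm3",
    estimate_spatial: bool = True,
    n_select: int = 30,
    options: Optional[REMLOptions] = None,
) -> Dict:
    t0 = time.perf_counter()
    outdir = Path(outdir)
    pheno = cio.read_phenotypes(outdir / "phenotypes.csv")
    Gstar, Gd = _load_kernels(outdir)
    result = stagewise_evaluation(
        pheno,
        Gstar,
        Gd,
        response=response,
        estimate_spatial=estimate_spatial,
        n_select=n_select,
        stage1_options=options,
        stage2_options=options,
    )
    result["adjusted_means"].to_csv(outdir / "adjusted_means.csv", index=False)
    params = result["parameters"].as_dict()
    params.update(
        {f"sigma2_{k}": v for k, v in result["variance_components"].as_dict().items()}
    )
    sel = result["selection"]
    params.update(
        {
            "selection_differential": sel.differential,
            "selection_response": sel.response,
            "selection_response_pct": sel.response_pct,
            "base_mean": sel.base_mean,
            "selected_mean": sel.selected_mean,
        }
    )
    cio.write_json(params, outdir / "parameters.json")
    cio.write_json(result["fit"].to_json_dict(), outdir / "stage2_fit.json")
    result["fit"].blups_frame().to_csv(outdir / "stage2_blups.csv", index=False)
    ranked = result["genotypic_values"].sort_values(ascending=False)
    ranked.rename("genotypic_value").to_csv(outdir / "ranked_genotypes.csv")
    _timed(outdir, "stagewise", {"n_means": len(result["adjusted_means"])}, t0)
    return result


def stage_single(
    outdir: Path,
    response: str = "vol_dm3",
    options: Optional[REMLOptions] = None,
) -> Dict:
    t0 = time.perf_counter()
    outdir = Path(outdir)
    pheno = cio.read_phenotypes(outdir / "phenotypes.csv")
    Gstar, Gd = _load_kernels(outdir)
    controls = (outdir / "controls.txt").read_text().split()
    fit = fit_single_stage(pheno, Gstar, Gd, response, options, exclude=controls)
    cio.write_json(
        {
            "components": fit.components,
            "sigma_p2": fit.sigma_p2,
            "h2_a": fit.h2_a,
            "delta2": fit.delta2,
            "H2": fit.H2,
            "accuracy_additive": fit.accuracy_additive,
            "accuracy_dominance": fit.accuracy_dominance,
        },
        outdir / "single_stage.json",
    )
    _timed(outdir, "single", {"n_trees": len(pheno)}, t0)
    return {"fit": fit}


def stage_replication(
    outdir: Path,
    response: str = "vol_dm3",
    ks: Optional[Sequence[int]] = None,
    top_ns: Sequence[int] = (10, 20, 30),
    options: Optional[REMLOptions] = None,
) -> Dict:
    t0 = time.perf_counter()
    outdir = Path(outdir)
    pheno = cio.read_phenotypes(outdir / "phenotypes.csv")
    Gstar, Gd = _load_kernels(outdir)
    controls = (outdir / "controls.txt").read_text().split()
    total = int(pheno["replicate"].max())
    ks = list(ks) if ks is not None else list(range(total, 0, -1))
    top_ns = [n for n in top_ns if n <= len(set(pheno["genotype_id"]))]
    result = replication_study(
        pheno, Gstar, Gd, response, ks=ks, top_ns=top_ns, options=options, exclude=controls
    )
    result.summary.to_csv(outdir / "replication_summary.csv")
    result.rankings.to_csv(outdir / "replication_rankings.csv")
    result.coincidence.to_csv(outdir / "replication_coincidence.csv")
    result.min_selection.rename("min_selection_size").to_csv(
        outdir / "replication_min_selection.csv"
    )
    _timed(outdir, "replication", {"ks": ks}, t0)
    return {"study": result}


# ----------------------------------------------------------------------
def run_pipeline(
    config: SimulationConfig,
    outdir: Path,
    until: str = "replication",
    thresholds: Optional[QCThresholds] = None,
    run_qc: bool = True,
    alpha: float = DEFAULT_BLEND_ALPHA,
    response: str = "vol_dm3",
    estimate_spatial: bool = True,
    ks: Optional[Sequence[int]] = None,
    top_ns: Sequence[int] = (10, 20, 30),
    options: Optional[REMLOptions] = None,
) -> Dict:
    """Execute the pipeline from simulation up to (and including) ``until``."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    outdir = Path(outdir)
    results: Dict = {}
    stop = STAGES.index(until)
    try:
        results["simulate"] = stage_simulate(config, outdir)
        if stop >= 1:
            results["qc"] = stage_qc(outdir, thresholds, run_qc)
        if stop >= 2:
            results["grm"] = stage_grm(outdir, alpha)
        if stop >= 3:
            results["stagewise"] = stage_stagewise(
                outdir, response, estimate_spatial, options=options
            )
        if stop >= 4:
            results["single"] = stage_single(outdir, response, options)
        if stop >= 5:
            results["replication"] = stage_replication(
                outdir, response, ks, top_ns, options
            )
    except Exception as exc:
        done = set(results)
        failed = next(s for s in STAGES if s not in done)
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc
    return results
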