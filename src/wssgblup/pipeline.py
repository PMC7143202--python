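"""End-to-end pipeline: filters → relationships → (REML) → WssGBLUP → GWAS.

Stages mirror the analysis workflow: restrict trait records to the configured
interval, drop low-MAF SNPs, build A⁻¹/A22/G/H⁻¹, estimate or accept variance
components, iterate weighted ssGBLUP, scan sliding windows and select regions,
optionally map them to genes.  Every stage writes its artifact into the run
directory, plus a machine-readable manifest, so a rerun with the same config
is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .genomic import filter_maf, center_Z
from .gwas import (
    map_windows_to_genes,
    run_wssgblup,
    select_windows,
    window_scan,
    windows_to_frame,
)
from .mixed_model import (
    ModelError,
    ModelSpec,
    PhenotypeTable,
    VarianceComponents,
    build_design,
    estimate_reml,
    solve_mme,
)
from .pedigree import build_A_inverse, subset_A22

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    pedigree: str = ""
    genotypes: str = ""
    snp_map: str = ""
    phenotypes: str = ""
    annotation: str | None = None
    out_dir: str = "run"
    model_kind: str = "primiparous"
    maf_threshold: float = 0.05
    trait_bounds: tuple = (270.0, 700.0)
    n_iter: int = 5
    gwas_iteration: int = 2
    window_sizes: tuple = (1, 5, 10, 20, 50)
    threshold_pct: float = 0.20
    blend_alpha: float = 0.95
    accuracy_mode: str = "sqrt"
    pedigree_only: bool = False
    estimate_variances: bool = True
    sigma_a2: float | None = None
    sigma_pe2: float | None = None
    sigma_e2: float | None = None
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def filter_phenotypes(pheno: PhenotypeTable, bounds=(270.0, 700.0)) -> PhenotypeTable:
    """Keep records with trait value inside the closed interval [lower, upper]."""
    lo, hi = bounds
    if lo >= hi:
        raise ModelError("invalid trait bounds")
    keep = (pheno.table["y"] >= lo) & (pheno.table["y"] <= hi)
    n_removed = int((~keep).sum())
    logger.info("trait bounds [%.0f, %.0f]: removed %d of %d records",
                lo, hi, n_removed, len(pheno))
    if not keep.any():
        raise ModelError("no records remain after trait filtering")
    return PhenotypeTable(pheno.table.loc[keep].reset_index(drop=True))


def run_pipeline(cfg: PipelineConfig, genotyped_ids=None):
    """Execute the full analysis and write artifacts under ``cfg.out_dir``.

    ``genotyped_ids`` defaults to every animal present in the genotype file.
    Returns a dict of in-memory results for programmatic use.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ped = wio.read_pedigree(cfg.pedigree)
    pheno = wio.read_phenotypes(cfg.phenotypes)
    pheno = filter_phenotypes(pheno, cfg.trait_bounds)

    spec = ModelSpec(model_kind=cfg.model_kind,
                     relationship="A" if cfg.pedigree_only else "H")
    # nested factors (herds within countries) make X rank deficient after the
    # reference-level constraints; prune redundant columns like production
    # evaluation software does with its generalized inverses
    design = build_design(pheno, spec, ped, on_rank_deficiency="drop")
    A_inv = build_A_inverse(ped)

    if cfg.estimate_variances:
        vc = estimate_reml(design, A_inv)
        wio.write_json({
            "sigma_a2": vc.sigma_a2, "sigma_pe2": vc.sigma_pe2, "sigma_e2": vc.sigma_e2,
            "heritability": vc.heritability, "standard_errors": vc.standard_errors,
            "converged": vc.converged, "loglik_trajectory": vc.loglik_trajectory,
        }, out / "reml.json")
    else:
        if cfg.sigma_a2 is None or cfg.sigma_e2 is None:
            raise ModelError("fixed variance components requested but not provided")
        vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_e2, cfg.sigma_pe2 or 0.0)

    results = {"config": cfg, "variance_components": vc, "pedigree": ped}

    if cfg.pedigree_only:
        sol = solve_mme(design, A_inv, vc, accuracy_mode=cfg.accuracy_mode)
        wio.write_solutions(sol, out / "ebv_pblup.tsv")
        wio.write_fixed_effects(sol, out / "fixed_effects.tsv")
        results["solution"] = sol
        _write_manifest(cfg, out, stages=["filter", "relationships", "reml", "pblup"])
        return results

    geno, snp_map = wio.read_genotypes(cfg.genotypes, cfg.snp_map)
    geno, snp_map = filter_maf(geno, snp_map, cfg.maf_threshold)
    if genotyped_ids is None:
        genotyped_ids = geno.animal_ids
    else:
        pos = {a: i for i, a in enumerate(geno.animal_ids.tolist())}
        sel = [pos[a] for a in genotyped_ids]
        geno = type(geno)(geno.values[sel], np.asarray(genotyped_ids), geno.snp_ids)
    Zc = center_Z(geno, snp_map)
    A22, A22_inv = subset_A22(ped, geno.animal_ids)

    iters = run_wssgblup(
        design, A_inv, A22, A22_inv, Zc, snp_map, geno.animal_ids, vc,
        n_iter=cfg.n_iter, blend_alpha=cfg.blend_alpha, accuracy_mode=cfg.accuracy_mode,
    )
    for it in iters:
        wio.write_solutions(it.solution, out / f"gebv_iter{it.iteration}.tsv")
    pd.DataFrame({
        "iteration": [it.iteration for it in iters],
        "mean_accuracy": [it.mean_accuracy for it in iters],
    }).to_csv(out / "accuracy_by_iteration.tsv", sep="\t", index=False)

    gwas_iter = min(cfg.gwas_iteration, cfg.n_iter)
    effects = iters[gwas_iter - 1].effects
    windows = window_scan(effects, Zc, snp_map, vc.sigma_a2, cfg.window_sizes)
    windows_to_frame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    top = select_windows([w for w in windows if w.size == max(cfg.window_sizes)],
                         cfg.threshold_pct)
    if cfg.annotation:
        top = map_windows_to_genes(top, wio.read_annotation(cfg.annotation))
    windows_to_frame(top).to_csv(out / "selected_regions.tsv", sep="\t", index=False)

    results.update({"iterations": iters, "windows": windows, "selected": top,
                    "snp_map": snp_map, "Zc": Zc})
    _write_manifest(cfg, out, stages=["filter", "maf", "relationships", "reml",
                                      "wssgblup", "window_scan", "selection"]
                    + (["gene_mapping"] if cfg.annotation else []))
    return results


def _write_manifest(cfg: PipelineConfig, out: Path, stages) -> None:
    import platform

    import numpy
    import pandas
    import scipy

    wio.write_json({
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": stages,
        "n_iter": cfg.n_iter,
        "window_sizes": list(cfg.window_sizes),
        "seed": cfg.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }, out / "manifest.json")
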