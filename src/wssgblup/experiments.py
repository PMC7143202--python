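"""Simulation studies exercising the pipeline under known truth.

Each study fixes its generating conditions as package defaults (documented in
docs/methods.md) and varies only the seed, so the same study can back a test,
an analysis script and the acceptance report.  All randomness flows from the
seeds passed in.

Problem sizes are scaled to a desk machine: the variance-component recovery
study uses ~1000 records per replicate, the QTL-detection study 2000 genotyped
animals × 5000 SNPs, the null studies smaller panels; each function documents
its own sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genomic import center_Z, filter_maf
from .gwas import run_wssgblup, select_windows, window_scan
from .mixed_model import ModelSpec, VarianceComponents, build_design, estimate_reml, solve_mme
from .pedigree import RelationshipMatrix, build_A_inverse, prune_pedigree, subset_A22
from .simulate import SimulationConfig, simulate_dataset

TRAIT_TOTAL_VARIANCE = 3930.0  # σa²+σe² on the calving-interval scale (days²)

#: low-heritability recovery study: calving-interval-scale generating values
#: (σa²=201.3, σe²=3728.7, h²≈0.051) on an AI-sire half-sib population
REML_RECOVERY_CONFIG = SimulationConfig(
    n_founders=320, n_generations=2, litter_rate=4.0, max_sires_per_generation=20,
    qtl_variance_fraction=0.0, n_snp=20, n_chromosomes=2,
    sigma_a2=201.3, sigma_e2=3728.7, seed=0,
)

#: QTL-detection study: 5 QTL carrying 40% of a moderately heritable trait's
#: additive variance (h²=0.30), 5000 SNPs on 5 chromosomes, ~2000 genotyped
QTL_STUDY_CONFIG = SimulationConfig(
    n_founders=400, n_generations=2, litter_rate=4.0, max_sires_per_generation=20,
    n_snp=5000, n_chromosomes=5, qtl_count=5, qtl_variance_fraction=0.4,
    sigma_a2=0.30 * TRAIT_TOTAL_VARIANCE, sigma_e2=0.70 * TRAIT_TOTAL_VARIANCE,
    genotyping_fraction=0.85, seed=0,
)

#: null window study: same structure, no QTL, reduced panel
NULL_STUDY_CONFIG = replace(
    QTL_STUDY_CONFIG, n_founders=160, litter_rate=3.0, max_sires_per_generation=12,
    n_snp=1500, qtl_count=0, qtl_variance_fraction=0.0, genotyping_fraction=0.9,
)


def _pedigree_reml(cfg: SimulationConfig):
    ds = simulate_dataset(cfg)
    ped = prune_pedigree(ds.pedigree, ds.phenotypes.table["animal_id"].unique())
    design = build_design(ds.phenotypes, ModelSpec("primiparous", "A"), ped,
                          on_rank_deficiency="drop")
    A_inv = RelationshipMatrix(build_A_inverse(ped).dense(), ped.ids, is_inverse=True)
    return ds, ped, design, A_inv


def reml_recovery_study(seeds) -> pd.DataFrame:
    """Estimate h² by pedigree AI-REML on replicates generated at h²≈0.05."""
    rows = []
    for seed in seeds:
        cfg = replace(REML_RECOVERY_CONFIG, seed=int(seed))
        ds, ped, design, A_inv = _pedigree_reml(cfg)
        vc = estimate_reml(design, A_inv, max_iter=100)
        rows.append({
            "seed": int(seed), "n_records": len(design.y), "n_animals": len(ped),
            "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2,
            "h2": vc.heritability, "converged": vc.converged,
            "realized_h2": ds.truth.realized_h2,
        })
    return pd.DataFrame(rows)


@dataclass
class QtlStudyResult:
    seed: int
    top_window_hits_qtl: bool
    accuracy_by_iteration: list      # corr(GEBV, true BV), unphenotyped genotyped animals
    pblup_accuracy: float            # corr(EBV, true BV) on the same candidates
    top_window_pct: float
    n_selected_regions: int
    chrom_max_pct: dict              # per-chromosome max 50-SNP window %


def _ss_setup(cfg: SimulationConfig):
    ds = simulate_dataset(cfg)
    ped = ds.pedigree
    geno, snp_map = filter_maf(ds.genotypes, ds.snp_map, 0.05)
    pos = {a: i for i, a in enumerate(geno.animal_ids.tolist())}
    sel = [pos[a] for a in ds.genotyped_ids.tolist()]
    geno = type(geno)(geno.values[sel], ds.genotyped_ids, geno.snp_ids)
    # frequencies re-observed in the genotyped sample
    geno, snp_map = filter_maf(geno, snp_map.__class__(snp_map.table.drop(columns="freq")),
                               0.05)
    Zc = center_Z(geno, snp_map)
    design = build_design(ds.phenotypes, ModelSpec("primiparous", "H"), ped,
                          on_rank_deficiency="drop")
    A_inv = RelationshipMatrix(build_A_inverse(ped).dense(), ped.ids, is_inverse=True)
    A22, A22_inv = subset_A22(ped, geno.animal_ids)
    return ds, ped, geno, snp_map, Zc, design, A_inv, A22, A22_inv


def qtl_detection_study(seeds, n_iter: int = 2, window_size: int = 50,
                        threshold_pct: float = 0.20) -> list[QtlStudyResult]:
    """WssGBLUP + window scan on data with 5 strong QTL; truth-based scoring.

    The top ``window_size``-SNP window at iteration 2 is checked for overlap
    with a true QTL.  Accuracy is scored on the standard validation target —
    genotyped animals *without* phenotype records (selection candidates),
    where genomic information actually operates; pedigree BLUP on identical
    records is the baseline (for candidates it reduces to parent averages).
    """
    out = []
    for seed in seeds:
        cfg = replace(QTL_STUDY_CONFIG, seed=int(seed))
        ds, ped, geno, snp_map, Zc, design, A_inv, A22, A22_inv = _ss_setup(cfg)
        vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_e2)
        tbv = pd.Series(ds.truth.true_breeding_values, index=ped.ids)
        iters = run_wssgblup(design, A_inv, A22, A22_inv, Zc, snp_map,
                             geno.animal_ids, vc, n_iter=n_iter,
                             compute_pev=False, true_bv=tbv)
        # pedigree BLUP baseline on identical records
        pblup = solve_mme(design, A_inv, vc, compute_pev=False)
        recorded = set(ds.phenotypes.table["animal_id"].tolist())
        cand = np.array([a for a in geno.animal_ids.tolist() if a not in recorded])
        t = tbv.loc[cand].to_numpy()
        acc_by_iter = [
            float(np.corrcoef(it.solution.ebv.loc[cand].to_numpy(), t)[0, 1])
            for it in iters
        ]
        pblup_acc = float(np.corrcoef(pblup.ebv.loc[cand].to_numpy(), t)[0, 1])

        gwas_iter = min(2, n_iter)
        effects = iters[gwas_iter - 1].effects
        windows = window_scan(effects, Zc, snp_map, vc.sigma_a2, (window_size,))
        top = max(windows, key=lambda w: w.pct_variance)
        # map original QTL columns to post-MAF panel positions
        qtl_ids = set(ds.genotypes.snp_ids[ds.truth.qtl_indices].tolist())
        panel_pos = {s: j for j, s in enumerate(geno.snp_ids.tolist())}
        qtl_cols = {panel_pos[s] for s in qtl_ids if s in panel_pos}
        hit = any(top.first_snp <= q <= top.last_snp for q in qtl_cols)
        selected = select_windows(windows, threshold_pct)
        chrom_max = {}
        for w in windows:
            chrom_max[w.chrom] = max(chrom_max.get(w.chrom, 0.0), w.pct_variance)
        out.append(QtlStudyResult(
            seed=int(seed), top_window_hits_qtl=hit,
            accuracy_by_iteration=acc_by_iter,
            pblup_accuracy=pblup_acc,
            top_window_pct=top.pct_variance,
            n_selected_regions=len(selected),
            chrom_max_pct=chrom_max,
        ))
    return out


def null_window_study(seeds, window_size: int = 50) -> pd.DataFrame:
    """No-QTL replicates: which chromosome carries the top window is recorded.

    Under the null the argmax chromosome should look exchangeable across
    chromosomes (no systematic peak).
    """
    rows = []
    for seed in seeds:
        cfg = replace(NULL_STUDY_CONFIG, seed=int(seed))
        ds, ped, geno, snp_map, Zc, design, A_inv, A22, A22_inv = _ss_setup(cfg)
        vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_e2)
        iters = run_wssgblup(design, A_inv, A22, A22_inv, Zc, snp_map,
                             geno.animal_ids, vc, n_iter=2, compute_pev=False)
        windows = window_scan(iters[1].effects, Zc, snp_map, vc.sigma_a2, (window_size,))
        chrom_max = {}
        for w in windows:
            chrom_max[w.chrom] = max(chrom_max.get(w.chrom, 0.0), w.pct_variance)
        argmax_chrom = max(chrom_max, key=chrom_max.get)
        row = {"seed": int(seed), "argmax_chrom": argmax_chrom}
        row.update({f"max_pct_chr{c}": v for c, v in chrom_max.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def window_noise_study(seeds, window_sizes=(1, 5, 10, 20, 50)) -> pd.DataFrame:
    """Per-SNP-scale noise of window percentages on LD-free genotypes.

    Uses an unpedigreed (founder-only) population so SNP columns are
    independent; fits one plain ssGBLUP round, back-solves effects and scans
    all window sizes.  Because the window statistic is a sum over SNPs, raw
    window variance grows with window size mechanically; noise is therefore
    measured on the per-SNP scale, i.e. the variance across windows of
    (window % / window size).
    """
    rows = []
    for seed in seeds:
        cfg = replace(
            NULL_STUDY_CONFIG, n_founders=400, n_generations=0, n_snp=1500,
            genotyping_fraction=1.0, seed=int(seed),
        )
        ds, ped, geno, snp_map, Zc, design, A_inv, A22, A22_inv = _ss_setup(cfg)
        vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_e2)
        iters = run_wssgblup(design, A_inv, A22, A22_inv, Zc, snp_map,
                             geno.animal_ids, vc, n_iter=1, compute_pev=False)
        windows = window_scan(iters[0].effects, Zc, snp_map, vc.sigma_a2, window_sizes)
        row = {"seed": int(seed)}
        for n_win in window_sizes:
            vals = np.array([w.pct_variance / w.size for w in windows if w.size == n_win])
            row[f"var_per_snp_pct_w{n_win}"] = float(vals.var())
        rows.append(row)
    return pd.DataFrame(rows)
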