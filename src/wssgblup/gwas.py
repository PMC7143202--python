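"""Weighted single-step GWAS: SNP back-solving, reweighting, window scan.

The iterative scheme (weights D start at identity):

1. build the weighted genomic relationship matrix G* from current D;
2. run ssGBLUP for the whole pedigree (H⁻¹ in the mixed-model equations);
3. back-solve SNP effects from the GEBVs of genotyped animals,
   û = D Z′ (Z D Z′)⁻¹ â_g;
4. reweight, d_i = û_i²·2p_i(1−p_i), normalized so Σd_i = M;
5. repeat (default 5 iterations; iteration 2 is used for the GWAS scan).

Association is then read off sliding SNP windows: the genetic value of a
window for each genotyped animal is Σ_j Z_cj û_j over the window's SNPs, and
the window's share of additive genetic variance is the empirical variance of
those values across animals divided by σa², as a percentage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from .genomic import (
    GenotypeError,
    SnpMap,
    SnpWeights,
    blend_G,
    build_G,
    build_H_inverse,
)
from .mixed_model import MMESolution, VarianceComponents, solve_mme
from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

WEIGHT_EPS = 1e-8  # floor for zero-effect SNPs so D stays invertible


@dataclass
class SnpEffects:
    """Back-solved per-SNP allele substitution effects with an iteration tag."""

    u: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if not np.isfinite(self.u).all():
            raise GenotypeError("SNP effects must be finite")


@dataclass
class WindowResult:
    chrom: object
    first_snp: int      # column index into the SNP panel
    last_snp: int       # inclusive
    first_bp: int
    last_bp: int
    size: int
    pct_variance: float
    iteration: int = 1
    genes: list = field(default_factory=list)


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive on both ends."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(self.table.columns):
            raise GenotypeError(f"annotation must have columns {sorted(required)}")
        if (self.table["start"] > self.table["end"]).any():
            raise GenotypeError("gene start must be <= end")


def backsolve_snp_effects(a_g: np.ndarray, Zc: np.ndarray, weights: SnpWeights,
                          snp_map: SnpMap, iteration: int = 1) -> SnpEffects:
    """û = D Z′ (Z D Z′)⁻¹ â_g.

    Uses the exact (unblended) weighted system.  When allele frequencies are
    observed in-sample, Z has zero column sums, so the all-ones vector is an
    exact null vector of Z D Z′ (the GEBV mean cannot be carried by SNP
    effects); that known deficiency is removed by a rank-one deflation
    S + c·11′, which leaves D Z′ S⁺ â_g unchanged because Z′1 = 0.  Any
    remaining singularity falls back to a small declared ridge (1e−8 of the
    mean diagonal).
    """
    a_g = np.asarray(a_g, dtype=float)
    if Zc.shape[0] != len(a_g):
        raise GenotypeError("GEBV vector length does not match genotype rows")
    if Zc.shape[1] != len(weights.d) or len(snp_map) != Zc.shape[1]:
        raise GenotypeError("weights/map length does not match SNP columns")
    ZD = Zc * weights.d
    S = ZD @ Zc.T
    S = 0.5 * (S + S.T)
    n = S.shape[0]
    # detect the mean deficiency directly: Cholesky can "succeed" on the
    # numerically semi-definite S and then amplify roundoff along 1
    s_scale = float(np.trace(S)) / n
    if np.abs(S @ np.ones(n)).max() < 1e-8 * s_scale * n:
        S = S + (s_scale / n) * np.ones((n, n))
        logger.debug("mean direction deflated from ZDZ'")
    try:
        t = la.cho_solve(la.cho_factor(S, lower=True), a_g)
    except la.LinAlgError:
        ridge = 1e-8 * s_scale
        logger.warning("ZDZ' singular; adding ridge %.3e", ridge)
        t = la.cho_solve(la.cho_factor(S + ridge * np.eye(n), lower=True), a_g)
    return SnpEffects(weights.d * (Zc.T @ t), iteration)


def update_weights(effects: SnpEffects, snp_map: SnpMap) -> SnpWeights:
    """d_i = û_i²·2p_i(1−p_i), normalized so Σd_i = M (the SNP count)."""
    p = snp_map.freq
    d = effects.u**2 * 2.0 * p * (1.0 - p)
    if d.sum() == 0:
        warnings.warn("all SNP effects are zero; returning uniform weights")
        return SnpWeights(np.ones(len(d)), effects.iteration + 1)
    d = np.maximum(d, WEIGHT_EPS)
    d = d * (len(d) / d.sum())
    return SnpWeights(d, effects.iteration + 1)


@dataclass
class IterationResult:
    iteration: int
    weights: SnpWeights
    effects: SnpEffects
    solution: MMESolution
    mean_accuracy: float               # PEV-based, mean over genotyped animals
    accuracy_vs_truth: float | None    # corr(GEBV, true BV) if truth supplied


def run_wssgblup(design, A_inv: RelationshipMatrix, A22: RelationshipMatrix,
                 A22_inv: RelationshipMatrix, Zc: np.ndarray, snp_map: SnpMap,
                 genotyped_ids: np.ndarray, vc: VarianceComponents,
                 n_iter: int = 5, blend_alpha: float = 0.95,
                 accuracy_mode: str = "sqrt", compute_pev: bool = True,
                 true_bv: pd.Series | None = None) -> list[IterationResult]:
    """The full weighted ssGBLUP loop; returns every iteration's artifacts.

    Iteration 1 uses D = I and therefore equals a plain ssGBLUP run.  ``Zc``
    rows must be ordered like ``genotyped_ids``, which must be a subset of the
    pedigree ids in ``A_inv``.
    """
    if n_iter < 1:
        raise GenotypeError("n_iter must be >= 1")
    genotyped_ids = np.asarray(genotyped_ids)
    id_pos = {a: i for i, a in enumerate(A_inv.ids.tolist())}
    genotyped_index = np.array([id_pos[a] for a in genotyped_ids.tolist()])
    weights = SnpWeights.identity(Zc.shape[1], iteration=1)
    out: list[IterationResult] = []
    for it in range(1, n_iter + 1):
        G = build_G(Zc, snp_map, weights, animal_ids=genotyped_ids)
        Gb = blend_G(G, A22, alpha=blend_alpha)
        Gb_inv = RelationshipMatrix(np.linalg.inv(Gb.dense()), genotyped_ids, is_inverse=True)
        H_inv = build_H_inverse(A_inv, A22_inv, Gb_inv, genotyped_index)
        sol = solve_mme(design, H_inv, vc, compute_pev=compute_pev,
                        accuracy_mode=accuracy_mode)
        a_g = sol.ebv.loc[genotyped_ids].to_numpy()
        effects = backsolve_snp_effects(a_g, Zc, weights, snp_map, iteration=it)
        mean_acc = float(sol.accuracy.loc[genotyped_ids].mean()) if compute_pev else float("nan")
        acc_truth = None
        if true_bv is not None:
            t = true_bv.loc[genotyped_ids].to_numpy()
            acc_truth = float(np.corrcoef(a_g, t)[0, 1])
        out.append(IterationResult(it, weights, effects, sol, mean_acc, acc_truth))
        weights = update_weights(effects, snp_map)
    return out


def window_scan(effects: SnpEffects, Zc: np.ndarray, snp_map: SnpMap,
                sigma_a2: float, window_sizes=(1, 5, 10, 20, 50),
                sliding: bool = True) -> list[WindowResult]:
    """Percentage of additive genetic variance per sliding SNP window.

    Windows advance one SNP at a time (``sliding=False`` gives distinct,
    non-overlapping windows), never span chromosomes, and windows truncated
    at a chromosome end are dropped.  The per-window statistic is
    Var_animals(Σ_j Zc_j û_j) / σa² × 100 with the population (n) variance.
    """
    if sigma_a2 <= 0:
        raise GenotypeError("sigma_a2 must be positive for the window scan")
    if Zc.shape[1] != len(snp_map):
        raise GenotypeError("SNP map length does not match genotype columns")
    T = Zc * effects.u  # per-animal per-SNP genetic contribution
    chrom = snp_map.chrom
    bp = snp_map.bp
    results: list[WindowResult] = []
    start = 0
    for c in pd.unique(chrom):
        k = int((chrom == c).sum())
        sl = slice(start, start + k)
        Tc = T[:, sl]
        S = np.cumsum(Tc, axis=1)
        S = np.hstack([np.zeros((Tc.shape[0], 1)), S])
        for n_win in window_sizes:
            if n_win > k:
                logger.info("chromosome %s has %d SNPs < window size %d; skipped", c, k, n_win)
                continue
            starts = np.arange(0, k - n_win + 1, 1 if sliding else n_win)
            Wv = S[:, starts + n_win] - S[:, starts]  # animals × windows
            var = Wv.var(axis=0)  # ddof=0, population variance over animals
            pct = var / sigma_a2 * 100.0
            for j, s0 in enumerate(starts):
                i0, i1 = start + s0, start + s0 + n_win - 1
                results.append(WindowResult(
                    chrom=c, first_snp=i0, last_snp=i1,
                    first_bp=int(bp[i0]), last_bp=int(bp[i1]),
                    size=n_win, pct_variance=float(pct[j]),
                    iteration=effects.iteration,
                ))
        start += k
    return results


def select_windows(results: list[WindowResult], threshold_pct: float = 0.20
                   ) -> list[WindowResult]:
    """Windows at or above the variance threshold, merged where they overlap.

    Overlapping qualifying windows on one chromosome are merged into a single
    region spanning their combined bp range and reporting the maximum window
    percentage.
    """
    if threshold_pct < 0:
        raise GenotypeError("threshold must be >= 0")
    survivors = [w for w in results if w.pct_variance >= threshold_pct]
    survivors.sort(key=lambda w: (str(w.chrom), w.first_snp))
    merged: list[WindowResult] = []
    for w in survivors:
        if merged and str(merged[-1].chrom) == str(w.chrom) and w.first_snp <= merged[-1].last_snp:
            top = merged[-1]
            merged[-1] = WindowResult(
                chrom=top.chrom,
                first_snp=top.first_snp,
                last_snp=max(top.last_snp, w.last_snp),
                first_bp=top.first_bp,
                last_bp=max(top.last_bp, w.last_bp),
                size=max(top.last_snp, w.last_snp) - top.first_snp + 1,
                pct_variance=max(top.pct_variance, w.pct_variance),
                iteration=top.iteration,
            )
        else:
            merged.append(w)
    return merged


def map_windows_to_genes(regions: list[WindowResult], annotation: GeneAnnotation
                         ) -> list[WindowResult]:
    """Attach genes whose [start, end] intersects each region (1-based, inclusive).

    A gene abutting the region boundary (gene.start == region.last_bp) counts
    as overlapping.  Unknown chromosome names in the regions are an error.
    """
    ann = annotation.table
    known = set(str(c) for c in ann["chrom"].unique())
    unmatched = sorted({str(r.chrom) for r in regions} - known)
    if unmatched and len(regions):
        raise GenotypeError(f"chromosome names not present in annotation: {unmatched}")
    out = []
    for r in regions:
        sub = ann[ann["chrom"].astype(str) == str(r.chrom)]
        hit = sub[(sub["start"] <= r.last_bp) & (sub["end"] >= r.first_bp)]
        out.append(WindowResult(
            chrom=r.chrom, first_snp=r.first_snp, last_snp=r.last_snp,
            first_bp=r.first_bp, last_bp=r.last_bp, size=r.size,
            pct_variance=r.pct_variance, iteration=r.iteration,
            genes=hit["gene_id"].tolist(),
        ))
    return out


def windows_to_frame(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": w.chrom, "start_bp": w.first_bp, "end_bp": w.last_bp,
            "first_snp": w.first_snp, "last_snp": w.last_snp, "n_snp": w.size,
            "pct_variance": w.pct_variance, "iteration": w.iteration,
            "genes": ";".join(map(str, w.genes)),
        }
        for w in results
    ])
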