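"""Genomic relationship machinery: QC, VanRaden G, blending, single-step H⁻¹.

The genomic relationship matrix is built from centered gene content,

    G = Z D Z′ / Σ_i 2 p_i (1 − p_i),

with Z the allele-frequency-centered 0/1/2 matrix, D a diagonal matrix of
per-SNP variance weights (identity for plain VanRaden G) and p_i the observed
allele frequency at SNP i.  The single-step inverse relationship matrix is

    H⁻¹ = A⁻¹ + [0 0; 0  G_b⁻¹ − A22⁻¹]

with the correction added into the genotyped block; G_b is G blended with a
small proportion of A22 to guarantee invertibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals × SNP matrix of 0/1/2 gene content."""

    values: np.ndarray  # int8 or float, shape (n_animals, n_snp)
    animal_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.animal_ids = np.asarray(self.animal_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.values.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise GenotypeError("genotype matrix shape does not match id counts")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise GenotypeError("genotypes must be coded 0/1/2 with no missing values")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


@dataclass
class SnpMap:
    """Per-SNP map: id, chromosome, bp position and (after QC) allele frequency."""

    table: pd.DataFrame  # columns: snp_id, chrom, bp, [freq]

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "bp"}
        if not required.issubset(self.table.columns):
            raise GenotypeError(f"SNP map must have columns {sorted(required)}")
        for _, sub in self.table.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["bp"].to_numpy()) > 0):
                raise GenotypeError("bp positions must be strictly increasing within chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def freq(self) -> np.ndarray:
        if "freq" not in self.table.columns:
            raise GenotypeError("allele frequencies not yet recorded; run filter_maf first")
        return self.table["freq"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy()


@dataclass
class SnpWeights:
    """Positive per-SNP variance weights (diagonal of D) with an iteration tag."""

    d: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if (self.d <= 0).any():
            raise GenotypeError("SNP weights must be strictly positive")

    @classmethod
    def identity(cls, n_snp: int, iteration: int = 1) -> "SnpWeights":
        return cls(np.ones(n_snp), iteration)


def observed_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Allele frequency of the '2' allele per SNP from observed genotype means."""
    return geno.values.mean(axis=0) / 2.0


def filter_maf(geno: GenotypeMatrix, snp_map: SnpMap, threshold: float = 0.05
               ) -> tuple[GenotypeMatrix, SnpMap]:
    """Drop SNPs with minor allele frequency below ``threshold``.

    The boundary is kept: MAF exactly equal to the threshold survives
    ("less than" excluded).  Observed frequencies are recorded on the map.
    """
    if not 0 <= threshold < 0.5:
        raise GenotypeError("MAF threshold must be in [0, 0.5)")
    if len(snp_map) != geno.n_snp:
        raise GenotypeError("SNP map length does not match genotype columns")
    p = observed_frequencies(geno)
    maf = np.minimum(p, 1 - p)
    keep = maf >= threshold if threshold > 0 else maf > 0
    # threshold 0 still drops monomorphic SNPs (frequency 0 or 1) so that
    # 0 < p < 1 holds downstream
    keep &= (p > 0) & (p < 1)
    if not keep.any():
        raise GenotypeError("all SNPs removed by the MAF filter")
    n_removed = int((~keep).sum())
    logger.info("MAF filter (threshold %.3f): %d of %d SNPs removed", threshold, n_removed, geno.n_snp)
    table = snp_map.table.loc[keep].copy().reset_index(drop=True)
    table["freq"] = p[keep]
    return (
        GenotypeMatrix(geno.values[:, keep], geno.animal_ids, geno.snp_ids[keep]),
        SnpMap(table),
    )


def center_Z(geno: GenotypeMatrix, snp_map: SnpMap) -> np.ndarray:
    """Gene content adjusted for allele frequencies: Z = genotype − 2p."""
    if len(snp_map) != geno.n_snp:
        raise GenotypeError("SNP map length does not match genotype columns")
    return geno.values.astype(float) - 2.0 * snp_map.freq


def compute_lambda(snp_map: SnpMap) -> float:
    """VanRaden's normalizing constant λ = 1 / Σ_i 2 p_i (1 − p_i)."""
    p = snp_map.freq
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise GenotypeError("zero heterozygosity; cannot normalize G")
    return 1.0 / denom


def build_G(Zc: np.ndarray, snp_map: SnpMap, weights: SnpWeights | None = None,
            animal_ids=None) -> RelationshipMatrix:
    """(Weighted) genomic relationship matrix G = Z D Z′ · λ."""
    n_animals, n_snp = Zc.shape
    if len(snp_map) != n_snp:
        raise GenotypeError("SNP map length does not match centered matrix columns")
    if weights is None:
        weights = SnpWeights.identity(n_snp)
    if len(weights.d) != n_snp:
        raise GenotypeError("weight vector length does not match SNP count")
    lam = compute_lambda(snp_map)
    ZD = Zc * weights.d  # broadcast over columns
    G = (ZD @ Zc.T) * lam
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    if animal_ids is None:
        animal_ids = np.arange(n_animals)
    return RelationshipMatrix(G, animal_ids)


def blend_G(G: RelationshipMatrix, A22: RelationshipMatrix, alpha: float = 0.95
            ) -> RelationshipMatrix:
    """G_b = α·G + (1−α)·A22; guards invertibility when animals > SNPs."""
    if not 0 < alpha <= 1:
        raise GenotypeError("blending alpha must be in (0, 1]")
    G.require_same_order(A22)
    Gb = alpha * G.dense() + (1.0 - alpha) * A22.dense()
    return RelationshipMatrix(Gb, G.ids)


def build_H_inverse(A_inv: RelationshipMatrix, A22_inv: RelationshipMatrix,
                    G_b_inv: RelationshipMatrix, genotyped_index: np.ndarray
                    ) -> RelationshipMatrix:
    """Single-step H⁻¹: A⁻¹ with (G_b⁻¹ − A22⁻¹) added into the genotyped block.

    ``genotyped_index`` gives the positions of the genotyped animals within the
    full pedigree ordering, in the order of G_b's rows.
    """
    n = len(A_inv.ids)
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if len(genotyped_index) and (genotyped_index.min() < 0 or genotyped_index.max() >= n):
        raise GenotypeError("genotyped index out of range of the pedigree ordering")
    if len(genotyped_index) != len(G_b_inv.ids):
        raise GenotypeError("genotyped index length does not match G dimension")
    G_b_inv.require_same_order(A22_inv)
    if (A_inv.ids[genotyped_index] != G_b_inv.ids).any():
        raise GenotypeError("genotyped ids do not match the pedigree ids at genotyped_index")
    H_inv = A_inv.dense().copy()
    if len(genotyped_index):
        H_inv[np.ix_(genotyped_index, genotyped_index)] += G_b_inv.dense() - A22_inv.dense()
    return RelationshipMatrix(H_inv, A_inv.ids, is_inverse=True)
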