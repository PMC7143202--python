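"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats:

* pedigree CSV — columns ``animal,sire,dam``; 0 or NA marks an unknown parent;
* genotypes — PLINK ``.raw``-style TSV (``animal_id`` + one 0/1/2 column per
  SNP) with a companion ``.map``-style TSV (``chrom, snp_id, bp``);
* phenotypes CSV — ``animal_id,y,herd,year,season,country,parity,age``;
* gene annotation — BED (0-based half-open, converted to 1-based inclusive
  on read) or a 4-column 1-based TSV with header ``gene_id,chrom,start,end``;
* matrices — coordinate ``(i, j, value)`` TSV;
* results — per-animal solution TSV, window TSV, truth/manifest JSON.

Readers log animal/SNP/record counts so pipeline bookkeeping is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic import GenotypeError, GenotypeMatrix, SnpMap
from .gwas import GeneAnnotation
from .mixed_model import PhenotypeTable
from .pedigree import Pedigree, RelationshipMatrix
from .simulate import SimulationTruth

logger = logging.getLogger(__name__)


# --- pedigree ---------------------------------------------------------------

def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path)
    if not {"animal", "sire", "dam"}.issubset(df.columns):
        raise GenotypeError("pedigree CSV needs columns animal,sire,dam")
    ped = Pedigree.from_parent_ids(df["animal"].tolist(), df["sire"].tolist(), df["dam"].tolist())
    logger.info("read pedigree: %d animals (%d founders)", len(ped), int(ped.is_founder().sum()))
    return ped


# --- genotypes + map --------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, snp_map: SnpMap, geno_path, map_path) -> None:
    df = pd.DataFrame(geno.values, columns=geno.snp_ids)
    df.insert(0, "animal_id", geno.animal_ids)
    df.to_csv(geno_path, sep="\t", index=False)
    snp_map.table[["chrom", "snp_id", "bp"]].to_csv(map_path, sep="\t", index=False)


def read_genotypes(geno_path, map_path) -> tuple[GenotypeMatrix, SnpMap]:
    df = pd.read_csv(geno_path, sep="\t")
    if df.columns[0] != "animal_id":
        raise GenotypeError("genotype TSV must start with an animal_id column")
    vals = df.iloc[:, 1:].to_numpy()
    if pd.isna(vals).any():
        raise GenotypeError("missing genotypes are not accepted; impute upstream")
    geno = GenotypeMatrix(vals.astype(np.int8), df["animal_id"].to_numpy(),
                          np.asarray(df.columns[1:]))
    mp = pd.read_csv(map_path, sep="\t")
    if not {"chrom", "snp_id", "bp"}.issubset(mp.columns):
        raise GenotypeError("map TSV needs columns chrom,snp_id,bp")
    if list(mp["snp_id"]) != list(geno.snp_ids):
        raise GenotypeError("SNP ids in map and genotype files disagree")
    logger.info("read genotypes: %d animals x %d SNPs", geno.n_animals, geno.n_snp)
    return geno, SnpMap(mp[["snp_id", "chrom", "bp"]].copy())


# --- phenotypes -------------------------------------------------------------

def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    pheno = PhenotypeTable(df)
    logger.info("read phenotypes: %d records on %d animals",
                len(pheno), df["animal_id"].nunique())
    return pheno


# --- gene annotation --------------------------------------------------------

def read_annotation(path) -> GeneAnnotation:
    """BED (0-based half-open) or 1-based TSV with header gene_id,chrom,start,end."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene_id"],
                         usecols=[0, 1, 2, 3])
        # BED start is 0-based, end exclusive -> 1-based inclusive
        df["start"] = df["start"].astype(int) + 1
        df["end"] = df["end"].astype(int)
    else:
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "chrom", "start", "end"}.issubset(df.columns):
            raise GenotypeError("annotation TSV needs columns gene_id,chrom,start,end")
    logger.info("read annotation: %d genes on %d chromosomes",
                len(df), df["chrom"].nunique())
    return GeneAnnotation(df[["gene_id", "chrom", "start", "end"]].copy())


# --- matrices ---------------------------------------------------------------

def write_matrix_coo(mat: RelationshipMatrix, path) -> None:
    m = mat.matrix
    coo = sp.coo_matrix(m) if not sp.issparse(m) else m.tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(
        path, sep="\t", index=False)


# --- results ----------------------------------------------------------------

def write_solutions(sol, path) -> None:
    df = pd.DataFrame({
        "animal_id": sol.ebv.index,
        "ebv": sol.ebv.to_numpy(),
    })
    if sol.pev is not None:
        df["pev"] = sol.pev.to_numpy()
        df["reliability"] = sol.reliability.to_numpy()
        df["accuracy"] = sol.accuracy.to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_fixed_effects(sol, path) -> None:
    pd.DataFrame({"effect": sol.fixed_effects.index,
                  "estimate": sol.fixed_effects.to_numpy()}).to_csv(path, sep="\t", index=False)


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "true_breeding_values": np.asarray(truth.true_breeding_values).tolist(),
        "qtl_indices": np.asarray(truth.qtl_indices).tolist(),
        "qtl_effects": np.asarray(truth.qtl_effects).tolist(),
        "true_variance_components": truth.true_variance_components,
        "realized_h2": truth.realized_h2,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimulationTruth:
    d = json.loads(Path(path).read_text())
    return SimulationTruth(
        true_breeding_values=np.asarray(d["true_breeding_values"]),
        qtl_indices=np.asarray(d["qtl_indices"], dtype=int),
        qtl_effects=np.asarray(d["qtl_effects"]),
        true_variance_components=d["true_variance_components"],
        realized_h2=d["realized_h2"],
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=str))
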