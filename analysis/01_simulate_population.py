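"""Simulate the working population and write its files under results/simdata/.

Generates a multi-generation AI-sire cattle population with 5 QTL hidden
among 5000 SNPs and a bounded calving-interval-like trait, then reports the
basic bookkeeping (animals, records, genotyped share, realized heritability).
"""

from pathlib import Path

from wssgblup import io as wio
from wssgblup.experiments import QTL_STUDY_CONFIG
from wssgblup.simulate import simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "simdata"


def main(seed: int = 1) -> None:
    cfg = QTL_STUDY_CONFIG
    cfg = type(cfg)(**{**cfg.__dict__, "seed": seed})
    ds = simulate_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    wio.write_pedigree(ds.pedigree, OUT / "pedigree.csv")
    wio.write_genotypes(ds.genotypes, ds.snp_map, OUT / "genotypes.tsv", OUT / "snps.map.tsv")
    wio.write_phenotypes(ds.phenotypes, OUT / "phenotypes.csv")
    wio.write_truth(ds.truth, OUT / "truth.json")
    (OUT / "genotyped_ids.txt").write_text("\n".join(map(str, ds.genotyped_ids)) + "\n")
    print(f"animals:            {len(ds.pedigree)}")
    print(f"records:            {len(ds.phenotypes)}")
    print(f"genotyped animals:  {len(ds.genotyped_ids)}")
    print(f"SNPs simulated:     {ds.genotypes.n_snp}")
    print(f"true QTL columns:   {ds.truth.qtl_indices.tolist()}")
    print(f"realized h2:        {ds.truth.realized_h2:.4f}")
    print(f"files -> {OUT}")


if __name__ == "__main__":
    import sys

    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
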