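# wssgblup

Weighted single-step genomic BLUP (WssGBLUP) and window-based GWAS for a
bounded, low-heritability fertility trait — the calving interval of dairy
cows — together with a gene-dropping simulator that provides populations with
known truth.

**Who this is for.** Animal-breeding researchers and students who want a
transparent, fully tested desk-scale implementation of the single-step
machinery: the pedigree numerator relationship matrix A and its sparse
Henderson inverse, the VanRaden genomic relationship matrix G, the combined
relationship matrix H, Henderson's mixed-model equations, AI-REML variance
components, PEV-based accuracy, iterative SNP reweighting, and a
sliding-window scan for the share of additive genetic variance carried by
genomic regions.

## The model

The trait y (days between successive calvings, restricted to 270–700 d) is
analysed with a single-trait animal model

    y = Xb + Za + e,          var(a) = K σa²,  var(e) = I σe²

where b holds herd-year-season, country (and, for the repeatability model of
multiparous cows, parity) effects plus linear and quadratic regressions on
age at first calving; for multiparous cows a permanent-environment effect pe
with var(pe) = I σpe² is added. K = A for pedigree BLUP, or the single-step
H for ssGBLUP:

    H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹],      G = Z D Z′ / Σᵢ 2pᵢ(1−pᵢ)

with Z the frequency-centered gene content, D per-SNP weights and A22 the
pedigree relationships of genotyped animals. WssGBLUP iterates: solve the
MME, back-solve SNP effects û = D Z′ (Z D Z′)⁻¹ â_g, reweight
dᵢ = ûᵢ²·2pᵢ(1−pᵢ) (normalized so Σd = number of SNPs), rebuild G*, repeat —
five iterations by default, with iteration 2 used for the GWAS scan. The
percentage of additive genetic variance explained by a window of n
consecutive SNPs is Var(Σⱼ Z_j ûⱼ)/σa² × 100 over sliding windows of
n ∈ {1, 5, 10, 20, 50}; windows at or above 0.20% are reported as associated
regions and intersected with a gene annotation. See `docs/methods.md` for
every numerical choice.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated data
and write their tables under `results/`:

```bash
python analysis/01_simulate_population.py    # population + genotypes + truth
python analysis/02_variance_components.py    # AI-REML recovery at h² = 0.05
python analysis/03_wssgblup_evaluation.py    # accuracy by iteration vs PBLUP
python analysis/04_window_gwas.py            # window scan + region selection
python analysis/05_null_and_noise.py         # null behaviour of the scan
```

`analysis/04_window_gwas.py` (seed 1) prints:

```
windows scanned: 23875; regions >= 0.20% (50-SNP): 19
top 50-SNP window: chr5 63.90-69.04 Mb explaining 2.87% of additive variance; overlaps true QTL: True
true QTL panel columns: [426, 2096, 2181, 3123, 4554]
QTL inside selected regions: 5/5
```

The top 50-SNP window carries 2.87% of the additive genetic variance and
contains one of the five simulated QTL; all five QTL fall inside the selected
regions at the 0.20% threshold. `analysis/02_variance_components.py` reports
the per-replicate AI-REML estimates at the generating scale (σa² = 201.3,
σe² = 3728.7): mean ĥ² = 0.040 over 10 replicates against the generating
0.051, with single low-h² replicates collapsing to the boundary as expected
at ~1000 records each. `analysis/03_wssgblup_evaluation.py` scores GEBV
accuracy (correlation with true breeding values of genotyped candidates
without records) at iterations 1 and 2 against pedigree BLUP on the same
records — e.g. seeds 0–4 give iteration 2 ≥ iteration 1 in 4/5 seeds and a
mean gain of +0.042 over pedigree BLUP.

The same machinery is scriptable through the CLI
(`wssgblup simulate | reml | gblup | wssgwas | full`); every run directory
receives the effective config and a manifest with versions and seeds.

## File formats

All interchange is plain text; readers enforce these layouts and log counts:

| file | format |
|---|---|
| pedigree | CSV `animal,sire,dam`; `0` or `NA` = unknown parent; parents listed before offspring |
| genotypes | TSV, first column `animal_id`, then one 0/1/2 column per SNP (PLINK `.raw` style); no missing values |
| SNP map | TSV `chrom,snp_id,bp`, bp strictly increasing within chromosome |
| phenotypes | CSV `animal_id,y,herd,year,season,country,parity,age` |
| gene annotation | BED (`chrom,start,end,gene_id`, 0-based half-open) or TSV with header `gene_id,chrom,start,end` (1-based inclusive) |
| outputs | per-animal solution TSV (`animal_id,ebv,pev,reliability,accuracy`), window TSV (`chrom,start_bp,end_bp,first_snp,last_snp,n_snp,pct_variance,iteration,genes`), REML report JSON, run manifest JSON |

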