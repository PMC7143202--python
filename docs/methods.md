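# Methods

`wssgblup` implements genetic evaluation of a bounded, low-heritability
fertility trait (calving interval, days between successive calvings) by
single-step genomic BLUP, with iterative SNP reweighting and a sliding-window
scan for genomic regions that carry additive genetic variance. A gene-dropping
simulator provides populations with known truth for every statistical claim
the package makes about itself.

## Models

Two single-trait animal models are supported.

**Primiparous (one record per cow):**

    y_ijk = μ + HYS_i + con_j + b1·age_k + b2·age_k² + a_k + e_ijk

**Multiparous (repeatability model):** the same terms plus the fixed effect
of parity and a random permanent-environment effect `pe` per cow, uncorrelated
with `a`.

`HYS` is the herd-year-season contemporary group, `con` the country, and `age`
the age at first calving (months; centered before squaring so the linear and
quadratic regressors are not collinear — this changes only the intercept/linear
parametrization, not the fit). Random effects:

    var(a) = K σa²,   var(pe) = I σpe²,   var(e) = I σe²

with K = A (pedigree numerator relationship matrix) for pedigree BLUP or
K = H for single-step GBLUP:

    H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]

A is built by the tabular recursion (the oracle) or, where only inbreeding is
needed, by a Meuwissen–Luo style ancestor recursion; A⁻¹ by Henderson's rules
with per-animal Mendelian-sampling variances that account for parental
inbreeding, so it is the exact inverse of the tabular A. Unknown parents are
treated as unrelated founders (no unknown-parent groups). A22 and its inverse
are obtained by direct dense factorization — the deliberate scaling boundary
of this package (tens of thousands of animals are out of scope).

The genomic relationship matrix uses centered gene content:

    G = Z D Z′ / Σ_i 2 p_i (1 − p_i)

with allele frequencies p observed in the genotyped sample (base-population
frequencies are unavailable in practice), D a diagonal matrix of per-SNP
variance weights (identity for plain G), and SNPs below 5% minor allele
frequency removed beforehand (the boundary value 0.05 is kept). Because more
animals than SNPs, relatedness, and exact column centering can make G
singular, G is blended as `G_b = α·G + (1−α)·A22` with α = 0.95 by default;
no additional mean/variance tuning of G toward A22 is applied, and no τ/ω
scaling of the genotyped block of H⁻¹.

## Mixed-model equations, PEV and accuracy

The MME are assembled dense (desk scale) and solved by Cholesky
factorization. PEV per animal comes exactly from the coefficient-matrix
inverse diagonal; reliability is r² = 1 − PEV/σa² and accuracy is √r² by
default. Because the accuracy formula in circulation can also be read as
reporting r² itself, a literal mode (`--accuracy-literal`) returns r²;
neither reading is asserted as canonical. σa² (not σa²(1+F_i)) is used in the
denominator; for unphenotyped inbred animals this can push reliability
marginally below 0, which is clipped with a logged warning.

Nested fixed factors (herds within countries make country a linear function
of the HYS cells) leave X rank deficient after drop-first constraints. The
default contract raises an estimability error naming the confounded factors;
the pipeline instead prunes redundant columns by pivoted QR, which is what
production evaluation software effectively does with generalized inverses.
Fitted values and random-effect solutions are unaffected by the choice.

## REML

Variance components are estimated by average-information REML with EM-REML
fallback. All quantities come from the R⁻¹-scaled MME: the restricted
log-likelihood (up to a constant) is

    −2ℓ = log|C| + n log σe² + q log σa² (+ q_pe log σpe²) + y′Py,

first derivatives use the exact trace identities
(tr(P Z K Z′) = q/σa² − tr(K⁻¹ C^aa)/σa⁴·σa² …), and the AI matrix is built
from extra MME solves with the data vectors Zâ/σa², Z_pe p̂/σpe², ê/σe².
The AI step is taken on the **log-variance scale** (the Newton step
pre/post-multiplied by the current parameter values), which keeps every
component positive and is well conditioned when a component approaches zero —
with raw AI steps, a small true σa² makes the quadratic approximation
repeatedly propose negative values and the algorithm degenerates into an
EM crawl. Steps are clipped to ±4 on the log scale and backtracked (up to 6
halvings) if the likelihood would decrease; a failed step falls back to EM,
which never decreases the likelihood. Convergence: maximum relative parameter
change < 1e−8, cap 500 iterations (non-convergence is flagged on the result
with the full likelihood trajectory, never raised). Components are floored at
1e−6 of the phenotypic variance. Standard errors come from the inverse AI
matrix at convergence. Exactness was verified against the closed-form ANOVA
estimators on balanced one-way data and against a brute-force V-matrix GLS
oracle for the BLUE/BLUP themselves.

## Weighted single-step GWAS

The iterative scheme (weights start at identity, so iteration 1 *is* plain
ssGBLUP):

1. build G* from current weights, blend, invert, assemble H⁻¹;
2. solve the MME for all animals; take GEBVs â_g of genotyped animals;
3. back-solve SNP effects û = D Z′ (Z D Z′)⁻¹ â_g;
4. reweight d_i = û_i²·2p_i(1−p_i), floor zero-effect SNPs at 1e−8, normalize
   so Σd_i = M (keeps the trace scale of G* stable across iterations);
5. repeat — 5 iterations by default, with iteration 2 used for the GWAS scan
   (the evaluation literature repeatedly finds accuracy peaks at iteration 2
   and declines as large-effect SNPs soak up ever more weight).

The back-solve uses the *unblended* weighted system, so the reconstruction
Z·û = â_g is exact whenever that system is full rank. One structural caveat
is handled explicitly: with in-sample allele frequencies Z has exact zero
column sums, so the all-ones vector is a null vector of ZDZ′ — the *mean* of
the GEBVs cannot be carried by SNP effects at all. That known deficiency is
removed by a rank-one deflation S + c·11′ (exact: Z′1 = 0 means the deflation
cannot leak into û); any residual singularity falls back to a declared ridge
of 1e−8 of the mean diagonal.

**Window scan.** For each chromosome, sliding (step-1) windows of
n ∈ {1, 5, 10, 20, 50} consecutive SNPs; the genetic value of a window for
animal k is Σ_{j∈window} Z_kj û_j and the window's share of additive variance
is the empirical (population, divisor n) variance of those values across
genotyped animals divided by the total additive variance σa², ×100. Windows
truncated at chromosome ends are dropped; chromosomes shorter than the window
produce none (logged). Windows at or above the 0.20% threshold are reported;
overlapping survivors on a chromosome are merged into one region spanning
their combined bp range and carrying the maximum window percentage. Regions
are intersected with a gene annotation (BED, 0-based half-open, converted on
read; or 1-based TSV) using closed-interval semantics on both sides. A
non-overlapping ("distinct") window mode exists behind a flag.

Note the window statistic is a sum over member SNPs, so for independent SNPs
its mean and raw cross-window variance both grow with window size
mechanically. "Smaller windows are noisier" is therefore a per-SNP-scale
statement, and the window-noise study measures the variance across windows of
(window % / window size) — a moving average whose sampling variance shrinks
like 1/n. Under linkage, a window's percentage is deliberately *not* the sum
of its single-SNP members (covariances count), which the tests assert on a
constructed LD example.

## The simulator

`simulate_dataset` generates, deterministically per config+seed:

* **Pedigree** — discrete generations, random mating; founders unknown-parent;
  each dam mated to one sire per generation producing `litter_rate` offspring;
  an optional AI-style bottleneck (`max_sires_per_generation`) caps the number
  of sires, producing the large paternal half-sib families typical of dairy
  cattle. Both sexes guaranteed in every breeding generation.
* **Genotypes** — founder allele frequencies ~ Uniform(0.05, 0.95); gene
  dropping with Haldane recombination at 1 cM/Mb (100 Mb chromosomes = 1
  Morgan), one crossover process per meiosis per chromosome, no mutation, so
  every offspring allele is traceable to a parent allele. An unknown parent
  contributes a fresh population gamete.
* **Phenotypes** — records for non-founder females (all animals when the
  pedigree has no sex metadata); trait = μ + HYS + country (+ parity) +
  b1·age_c + b2·age_c² + TBV (+ pe) + e. TBV is an explicit-QTL part
  (`qtl_count` loci, effects rescaled so their in-sample variance is exactly
  `qtl_variance_fraction`·σa²) plus a polygenic remainder dropped down the
  pedigree with inbreeding-adjusted Mendelian sampling. HYS cells are built
  with ≥3 records each (target size 8) so contemporary groups stay estimable;
  herds are nested in countries. Ages ~ Uniform(22, 36) months; season is a
  1–4 categorical; effect spreads (HYS 15 d, country 8 d, parity 4 d) are
  fixed design choices. Records outside the trait bounds (270–700 d by
  default) have their residual re-drawn (keeps the linear model exact);
  truncation is available behind `bound_mode="truncate"`.
* **Truth** — per-animal true breeding values, QTL columns and effects, the
  generating variance components, and the realized heritability
  var(TBV)/var(y − fixed part) on the produced records.

What the simulator does **not** emulate: selection and assortative mating,
mutation, genotyping error or missingness, genotype imputation, dominance or
epistasis, and real bovine LD structure (LD arises only from pedigree and the
recombination model). Passing tests therefore demonstrate correctness of the
machinery and qualitative behaviour of the method under the stated generating
conditions, not performance on real cattle data.

## Study problem sizes

Chosen once for a single-CPU desk machine and kept fixed:

* **Variance-component recovery** — generating values σa² = 201.3,
  σe² = 3728.7 (h² ≈ 0.051, the calving-interval scale), 320 founders, two
  generations, litter 4, 20 sires/generation → ~950 records and ~1100–1500
  pedigree animals per replicate after pruning to informative animals;
  10 replicates. Mean ĥ² recovers the generating 0.05 within ±0.02; single
  replicates are noisy at this n (a few collapse to the boundary), which is
  the honest behaviour of low-h² REML at ~1000 records.
* **QTL detection / iteration profile** — 5 QTL carrying 40% of σa², h² = 0.30,
  5000 SNPs on 5 chromosomes, ~2000 genotyped of ~2800 animals, ~1200 records;
  10 replicates, 2 WssGBLUP iterations. Detection = top 50-SNP window at
  iteration 2 contains a true QTL column. Accuracy is corr(GEBV, true BV)
  over genotyped animals *without* phenotype records — the standard forward-
  validation target (selection candidates), for which pedigree BLUP reduces
  to parent averages; scoring on all genotyped animals instead lets each
  animal's own record dominate both predictors and washes out the genomic
  contribution. The PEV-based accuracy of the real-data formula is available
  from the same solutions.
* **Null exchangeability** — same structure with no QTL at a reduced size
  (1500 SNPs, ~600 genotyped), 20 replicates; the chromosome carrying the top
  window is tested for uniformity by a χ² goodness-of-fit at p > 0.01.
* **Window noise** — 400 unpedigreed (founder-only) animals × 1500 SNPs so
  columns are independent, 20 replicates, one ssGBLUP round.

## Known limitations

* Dense linear algebra throughout: practical to a few thousand animals/SNPs.
* No unknown-parent groups or metafounders; no APY-style G approximations.
* Single-trait models only; no Bayesian alternatives.
* REML near a variance boundary returns the floored value with a flag rather
  than a formal boundary test.
* The GEBV mean is not recoverable from SNP effects (see back-solve note);
  window percentages, built from centered contrasts, are unaffected.
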