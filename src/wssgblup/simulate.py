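"""Gene-dropping simulator for livestock-style data with known truth.

Emulates the structure the evaluation models assume: a multi-generation
pedigree, biallelic SNPs dropped through the pedigree with Haldane
recombination (1 cM/Mb), and a bounded, low-heritability trait with
herd-year-season / country / parity fixed effects, an age-at-first-calving
covariate, an additive genetic value split between a handful of explicit QTL
and a polygenic remainder, and (for repeated records) a permanent-environment
effect.  A :class:`SimulationTruth` records breeding values, causal loci and
realized variance components for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix, SnpMap
from .mixed_model import PhenotypeTable
from .pedigree import UNKNOWN, Pedigree, compute_inbreeding, mendelian_sampling_variance

CM_PER_MB = 1.0  # Haldane map scaling: 1 cM per Mb, so 100 Mb = 1 Morgan


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic dataset.

    Variance defaults are on the calving-interval scale in days² (low
    heritability, h² ≈ 0.05); the trait is bounded to 270–700 d like a
    calving interval.
    """

    n_founders: int = 80
    n_generations: int = 4
    litter_rate: float = 2.0
    n_snp: int = 1000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    qtl_count: int = 5
    qtl_variance_fraction: float = 0.3
    sigma_a2: float = 201.3
    sigma_pe2: float = 0.0
    sigma_e2: float = 3728.7
    n_herds: int = 8
    n_years: int = 4
    n_seasons: int = 4
    n_countries: int = 4
    genotyping_fraction: float = 0.6
    trait_bounds: tuple = (270.0, 700.0)
    seed: int = 0
    # secondary knobs (not part of the core condition set)
    mean: float = 395.0
    age_slope: float = -1.5          # d per month of age at first calving
    age_quad: float = 0.08           # d per month², on centered age
    hys_sd: float = 15.0             # spread of herd-year-season effects, d
    country_sd: float = 8.0
    parity_sd: float = 4.0
    max_parity: int = 4
    bound_mode: str = "resample"     # or "truncate"
    hys_target_size: int = 8         # records per herd-year-season cell (min 3)
    max_sires_per_generation: int | None = None  # AI-style sire bottleneck; None = all males

    def __post_init__(self) -> None:
        if min(self.sigma_a2, self.sigma_pe2, self.sigma_e2) < 0:
            raise ConfigurationError("variance components must be non-negative")
        if not 0 <= self.qtl_variance_fraction <= 1:
            raise ConfigurationError("qtl_variance_fraction must be in [0, 1]")
        if not 0 < self.genotyping_fraction <= 1:
            raise ConfigurationError("genotyping_fraction must be in (0, 1]")
        if self.trait_bounds[0] >= self.trait_bounds[1]:
            raise ConfigurationError("trait_bounds lower must be below upper")
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.bound_mode not in ("resample", "truncate"):
            raise ConfigurationError(f"unknown bound_mode {self.bound_mode!r}")


@dataclass
class SimulationTruth:
    true_breeding_values: np.ndarray      # per pedigree animal
    qtl_indices: np.ndarray               # SNP column indices of causal loci
    qtl_effects: np.ndarray               # allele-substitution effects
    true_variance_components: dict
    realized_h2: float
    record_tbv: np.ndarray = field(default=None, repr=False)  # per record


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders (generation 0) have unknown parents; each dam of the previous
    generation is mated to one random sire per generation and produces
    ``litter_rate`` offspring on average.  Both sexes are guaranteed in every
    breeding generation.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    n_male = cfg.n_founders // 2
    if cfg.n_generations >= 1 and (n_male == 0 or cfg.n_founders - n_male == 0):
        raise ConfigurationError("need at least one founder of each sex to breed")
    sex = np.array([0] * n_male + [1] * (cfg.n_founders - n_male))  # 0=male, 1=female
    rng.shuffle(sex)
    sires: list[int] = [UNKNOWN] * cfg.n_founders
    dams: list[int] = [UNKNOWN] * cfg.n_founders
    sexes = list(sex)
    generation = [0] * cfg.n_founders
    prev = list(range(cfg.n_founders))
    base_extra = int(cfg.litter_rate)
    frac = cfg.litter_rate - base_extra
    for g in range(1, cfg.n_generations + 1):
        males = [i for i in prev if sexes[i] == 0]
        females = [i for i in prev if sexes[i] == 1]
        if not males or not females:
            raise ConfigurationError(f"generation {g - 1} lacks one sex; cannot mate")
        if cfg.max_sires_per_generation is not None and len(males) > cfg.max_sires_per_generation:
            # artificial-insemination style bottleneck: few sires, large half-sib groups
            males = [males[j] for j in rng.choice(len(males), cfg.max_sires_per_generation,
                                                  replace=False)]
        new: list[int] = []
        for dam in females:
            sire = males[rng.integers(len(males))]
            n_off = base_extra + (1 if rng.random() < frac else 0)
            for _ in range(n_off):
                idx = len(sires)
                sires.append(sire)
                dams.append(dam)
                sexes.append(int(rng.random() < 0.5))
                generation.append(g)
                new.append(idx)
        if not new:
            raise ConfigurationError("litter_rate too small; no offspring produced")
        # keep the next breeding generation two-sexed
        if g < cfg.n_generations:
            new_sexes = {sexes[i] for i in new}
            if len(new_sexes) == 1:
                sexes[new[0]] = 1 - sexes[new[0]]
        prev = new
    ids = np.arange(1, len(sires) + 1)
    ped = Pedigree(ids, np.array(sires), np.array(dams))
    ped.sex = np.array(sexes)
    ped.generation = np.array(generation)
    return ped


def _snp_map(cfg: SimulationConfig, rng: np.random.Generator) -> SnpMap:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snp // cfg.n_chromosomes)
    per_chrom[: cfg.n_snp % cfg.n_chromosomes] += 1
    rows = []
    snp_counter = 0
    for c in range(1, cfg.n_chromosomes + 1):
        m = per_chrom[c - 1]
        # unique positions by oversampling; collisions are negligible for m << L
        pos = np.unique(rng.integers(1, cfg.chromosome_length_bp + 1, size=2 * m + 16))
        while len(pos) < m:
            extra = rng.integers(1, cfg.chromosome_length_bp + 1, size=2 * m)
            pos = np.unique(np.concatenate([pos, extra]))
        bp = np.sort(rng.choice(pos, size=m, replace=False))
        for pos in bp:
            snp_counter += 1
            rows.append((f"snp{snp_counter}", c, int(pos)))
    return SnpMap(pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"]))


def _gamete(hap: np.ndarray, snp_map: SnpMap, rng: np.random.Generator,
            chrom_slices: list) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes (Haldane model)."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    for chrom_slice, bp, morgans in chrom_slices:
        n_xo = rng.poisson(morgans)
        start = rng.integers(2)
        if n_xo == 0:
            phase = np.full(len(bp), start)
        else:
            xo = np.sort(rng.uniform(0, morgans, size=n_xo))
            pos_m = bp * (CM_PER_MB / 1e8)  # bp -> Morgans at 1 cM/Mb
            phase = (start + np.searchsorted(xo, pos_m)) % 2
        seg = hap[:, chrom_slice]
        out[chrom_slice] = np.where(phase == 0, seg[0], seg[1])
    return out


def simulate_genotypes(ped: Pedigree, cfg: SimulationConfig
                       ) -> tuple[GenotypeMatrix, SnpMap]:
    """Drop founder haplotypes through the pedigree, one meiosis at a time.

    Founder allele frequencies ~ Uniform(0.05, 0.95); every offspring allele
    is traceable to a parent allele (no mutation).  A parent recorded as
    unknown contributes a fresh population gamete drawn from the founder
    frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    snp_map = _snp_map(cfg, rng)
    m = len(snp_map)
    p = rng.uniform(0.05, 0.95, size=m)
    n = len(ped)
    hap = np.empty((n, 2, m), dtype=np.int8)

    chrom_slices = []
    start = 0
    for c, sub in snp_map.table.groupby("chrom", sort=False):
        k = len(sub)
        bp = sub["bp"].to_numpy(dtype=float)
        morgans = cfg.chromosome_length_bp * CM_PER_MB / 1e8
        chrom_slices.append((slice(start, start + k), bp, morgans))
        start += k

    for i in range(n):
        for which, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent == UNKNOWN:
                hap[i, which] = (rng.random(m) < p).astype(np.int8)
            else:
                hap[i, which] = _gamete(hap[parent], snp_map, rng, chrom_slices)
    geno = GenotypeMatrix(hap.sum(axis=1), ped.ids, snp_map.table["snp_id"].to_numpy())
    geno.haplotypes = hap  # kept for allele-conservation checks
    return geno, snp_map


def _assign_contemporary_groups(records: pd.DataFrame, cfg: SimulationConfig,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Herd/year/season/country codes with every HYS cell holding ≥ 3 records."""
    n = len(records)
    herds = rng.integers(1, cfg.n_herds + 1, size=n)
    # herds nested within countries
    herd_country = {h: 1 + (h - 1) % cfg.n_countries for h in range(1, cfg.n_herds + 1)}
    records = records.copy()
    records["herd"] = herds
    records["country"] = [herd_country[h] for h in herds]
    year = np.empty(n, dtype=int)
    season = np.empty(n, dtype=int)
    combos = [(yy, ss) for yy in range(1, cfg.n_years + 1) for ss in range(1, cfg.n_seasons + 1)]
    for _, idx in records.groupby("herd").groups.items():
        idx = np.asarray(list(idx))
        rng.shuffle(idx)
        # chunk the herd's records into cells of ~target size (>= 3 each)
        n_groups = max(len(idx) // max(cfg.hys_target_size, 3), 1)
        combo_ids = rng.choice(len(combos), size=n_groups, replace=len(combos) < n_groups)
        bounds = np.linspace(0, len(idx), n_groups + 1).astype(int)
        for g in range(n_groups):
            sel = idx[bounds[g]:bounds[g + 1]]
            yy, ss = combos[combo_ids[g]]
            year[sel] = yy
            season[sel] = ss
    records["year"] = year
    records["season"] = season
    return records


def simulate_phenotypes(ped: Pedigree, geno: GenotypeMatrix, cfg: SimulationConfig
                        ) -> tuple[PhenotypeTable, SimulationTruth]:
    """Trait records plus the truth object.

    TBV = QTL part (explicit allele-substitution effects on centered gene
    content, scaled to ``qtl_variance_fraction·σa²``) + polygenic part with
    pedigree covariance for the remainder.  Records go to non-founder females;
    with σpe² > 0 each cow gets 2–``max_parity`` parities (repeatability
    structure), otherwise a single record.
    """
    if cfg.sigma_a2 == 0 and cfg.qtl_variance_fraction > 0:
        raise ConfigurationError("qtl_variance_fraction > 0 requires sigma_a2 > 0")
    if (geno.animal_ids != ped.ids).any():
        raise ConfigurationError("genotypes must cover all pedigree animals, in order")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = len(ped)

    # --- QTL part of the breeding value
    qvf = cfg.qtl_variance_fraction
    qtl_target = qvf * cfg.sigma_a2
    if qtl_target > 0 and cfg.qtl_count > 0:
        qtl_idx = np.sort(rng.choice(geno.n_snp, size=cfg.qtl_count, replace=False))
        raw = rng.standard_normal(cfg.qtl_count)
        Zq = geno.values[:, qtl_idx].astype(float)
        Zq = Zq - Zq.mean(axis=0)
        g_raw = Zq @ raw
        v = g_raw.var()
        scale = np.sqrt(qtl_target / v) if v > 0 else 0.0
        qtl_eff = raw * scale
        g_qtl = g_raw * scale
    else:
        qtl_idx = np.array([], dtype=int)
        qtl_eff = np.array([])
        g_qtl = np.zeros(n)

    # --- polygenic part, dropped down the pedigree with Mendelian sampling
    sigma_poly = (1.0 - qvf) * cfg.sigma_a2
    a_poly = np.zeros(n)
    if sigma_poly > 0:
        F = compute_inbreeding(ped)
        d = mendelian_sampling_variance(ped, F=F)
        eps = rng.standard_normal(n)
        for i in range(n):
            s, dm = ped.sire[i], ped.dam[i]
            mid = 0.0
            if s != UNKNOWN:
                mid += 0.5 * a_poly[s]
            if dm != UNKNOWN:
                mid += 0.5 * a_poly[dm]
            a_poly[i] = mid + eps[i] * np.sqrt(d[i] * sigma_poly)
    tbv = g_qtl + a_poly

    # --- who gets records
    sex = getattr(ped, "sex", None)
    generation = getattr(ped, "generation", None)
    if sex is None or generation is None:
        eligible = np.arange(n)  # externally built pedigree: everyone records
    else:
        eligible = np.where((sex == 1) & (generation >= 1))[0]
        if len(eligible) == 0:
            eligible = np.arange(n)
    repeated = cfg.sigma_pe2 > 0
    rows = []
    for i in eligible:
        n_par = int(rng.integers(2, cfg.max_parity + 1)) if repeated else 1
        for par in range(1, n_par + 1):
            rows.append((ped.ids[i], i, par))
    rec = pd.DataFrame(rows, columns=["animal_id", "_idx", "parity"])
    rec = _assign_contemporary_groups(rec, cfg, rng)

    # --- fixed-effect values
    hys_keys = rec["herd"].astype(str) + ":" + rec["year"].astype(str) + ":" + rec["season"].astype(str)
    uniq_hys = hys_keys.unique()
    hys_eff = dict(zip(uniq_hys, rng.normal(0, cfg.hys_sd, size=len(uniq_hys))))
    country_eff = {c: v for c, v in zip(range(1, cfg.n_countries + 1),
                                        rng.normal(0, cfg.country_sd, size=cfg.n_countries))}
    parity_eff = {pr: v for pr, v in zip(range(1, cfg.max_parity + 1),
                                         rng.normal(0, cfg.parity_sd, size=cfg.max_parity))}
    age_by_animal = {i: rng.uniform(22.0, 36.0) for i in eligible}
    rec["age"] = [age_by_animal[i] for i in rec["_idx"]]
    age_c = rec["age"].to_numpy() - np.mean(list(age_by_animal.values()))

    fixed = (
        cfg.mean
        + hys_keys.map(hys_eff).to_numpy()
        + rec["country"].map(country_eff).to_numpy()
        + (rec["parity"].map(parity_eff).to_numpy() if repeated else 0.0)
        + cfg.age_slope * age_c
        + cfg.age_quad * age_c**2
    )
    pe_by_animal = {i: rng.normal(0, np.sqrt(cfg.sigma_pe2)) if repeated else 0.0
                    for i in eligible}
    pe = np.array([pe_by_animal[i] for i in rec["_idx"]])
    tbv_rec = tbv[rec["_idx"].to_numpy()]

    lo, hi = cfg.trait_bounds
    e = rng.normal(0, np.sqrt(cfg.sigma_e2), size=len(rec))
    y = fixed + tbv_rec + pe + e
    if cfg.bound_mode == "resample":
        for _ in range(1000):
            bad = (y < lo) | (y > hi)
            if not bad.any():
                break
            e[bad] = rng.normal(0, np.sqrt(cfg.sigma_e2), size=int(bad.sum()))
            y = fixed + tbv_rec + pe + e
        y = np.clip(y, lo, hi)  # pathological cells only
    else:
        y = np.clip(y, lo, hi)

    rec["y"] = y
    pheno = PhenotypeTable(rec.drop(columns=["_idx"])[
        ["animal_id", "y", "herd", "year", "season", "country", "parity", "age"]
    ])
    resid = y - fixed
    realized_h2 = float(tbv_rec.var() / resid.var()) if resid.var() > 0 else float("nan")
    truth = SimulationTruth(
        true_breeding_values=tbv,
        qtl_indices=qtl_idx,
        qtl_effects=qtl_eff,
        true_variance_components={
            "sigma_a2": cfg.sigma_a2, "sigma_pe2": cfg.sigma_pe2, "sigma_e2": cfg.sigma_e2
        },
        realized_h2=realized_h2,
        record_tbv=tbv_rec,
    )
    return pheno, truth


def sample_genotyped_ids(ped: Pedigree, cfg: SimulationConfig) -> np.ndarray:
    """Random subset of non-founder animals marked as genotyped."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    candidates = np.where(~ped.is_founder())[0]
    if len(candidates) == 0:
        candidates = np.arange(len(ped))
    k = max(int(round(cfg.genotyping_fraction * len(candidates))), 1)
    chosen = np.sort(rng.choice(candidates, size=k, replace=False))
    return ped.ids[chosen]


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    snp_map: SnpMap
    phenotypes: PhenotypeTable
    truth: SimulationTruth
    genotyped_ids: np.ndarray


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Pedigree + genotypes + phenotypes + truth in one deterministic call."""
    ped = simulate_pedigree(cfg)
    geno, snp_map = simulate_genotypes(ped, cfg)
    pheno, truth = simulate_phenotypes(ped, geno, cfg)
    return SimulatedDataset(ped, geno, snp_map, pheno, truth,
                            sample_genotyped_ids(ped, cfg))
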