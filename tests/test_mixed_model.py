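"""Mixed-model equations, REML and accuracy against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from wssgblup.mixed_model import (
    DesignBundle,
    EstimabilityError,
    ModelError,
    ModelSpec,
    PhenotypeTable,
    VarianceComponents,
    build_design,
    compute_accuracy,
    estimate_reml,
    solve_mme,
)
from wssgblup.pedigree import RelationshipMatrix, build_A_inverse, build_A_tabular

from .conftest import random_pedigree


def make_pheno(ped, rng, n=None, model="primiparous"):
    """Random phenotype table over a subset of pedigree animals."""
    ids = ped.ids
    n = n or len(ids)
    chosen = rng.choice(ids, size=n, replace=(model == "multiparous"))
    df = pd.DataFrame({
        "animal_id": chosen,
        "y": rng.normal(400, 30, size=n),
        "herd": rng.integers(1, 3, size=n),
        "year": rng.integers(1, 3, size=n),
        "season": rng.integers(1, 3, size=n),
        "country": 1,
        "parity": 1,
        "age": rng.uniform(22, 36, size=n),
    })
    if model == "multiparous":
        df["parity"] = df.groupby("animal_id").cumcount() + 1
    return PhenotypeTable(df)


def gls_oracle(design, K, vc):
    """BLUE/BLUP from the joint covariance V = Z K Z' σa² (+ Zp Zp' σpe²) + I σe²."""
    Z = design.Z_animal.toarray()
    X, y = design.X, design.y
    V = Z @ K @ Z.T * vc.sigma_a2 + np.eye(len(y)) * vc.sigma_e2
    if design.Z_pe is not None:
        Zp = design.Z_pe.toarray()
        V += Zp @ Zp.T * vc.sigma_pe2
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = vc.sigma_a2 * K @ Z.T @ Vi @ (y - X @ b)
    return b, a


class TestDesign:
    def test_single_record_intercept(self):
        rng = np.random.default_rng(0)
        ped = random_pedigree(rng, 3, 0)
        df = pd.DataFrame({"animal_id": [ped.ids[1]], "y": [400.0], "herd": 1,
                           "year": 1, "season": 1, "country": 1, "parity": 1,
                           "age": [29.0]})
        d = build_design(PhenotypeTable(df), ModelSpec("primiparous", "A",
                                                       use_age_covariates=False), ped)
        assert d.X.shape == (1, 1) and d.X[0, 0] == 1.0
        assert d.Z_animal.toarray()[0, 1] == 1.0 and d.Z_animal.sum() == 1.0

    def test_primiparous_rejects_repeated_records(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(rng, 5, 0)
        df = pd.DataFrame({"animal_id": [ped.ids[0]] * 2, "y": [400.0, 410.0],
                           "herd": 1, "year": 1, "season": 1, "country": 1,
                           "parity": [1, 2], "age": 29.0})
        with pytest.raises(ModelError):
            build_design(PhenotypeTable(df), ModelSpec("primiparous", "A"), ped)

    def test_dummy_coding_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        ped = random_pedigree(rng, 10, 20)
        pheno = make_pheno(ped, rng, n=25)
        d = build_design(pheno, ModelSpec("primiparous", "A"), ped)
        df = pheno.table
        hys = df["herd"].astype(str) + ":" + df["year"].astype(str) + ":" + df["season"].astype(str)
        levels = pd.Categorical(hys).categories
        for lev in levels[1:]:
            col = d.fixed_names.index(f"hys[{lev}]")
            np.testing.assert_array_equal(d.X[:, col], (hys == lev).astype(float))

    def test_rank_deficiency_raises_by_default(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(rng, 10, 20)
        pheno = make_pheno(ped, rng, n=25)
        # make country a copy of herd -> confounded with HYS
        pheno.table["country"] = pheno.table["herd"]
        with pytest.raises(EstimabilityError):
            build_design(pheno, ModelSpec("primiparous", "A"), ped)
        d = build_design(pheno, ModelSpec("primiparous", "A"), ped,
                         on_rank_deficiency="drop")
        assert np.linalg.matrix_rank(d.X) == d.X.shape[1]


class TestSolveMME:
    def test_matches_gls_oracle_primiparous(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            ped = random_pedigree(rng, 8, 25)
            pheno = make_pheno(ped, rng, n=20)
            d = build_design(pheno, ModelSpec("primiparous", "A"), ped,
                             on_rank_deficiency="drop")
            A = build_A_tabular(ped).dense()
            Ainv = RelationshipMatrix(build_A_inverse(ped).dense(), ped.ids, True)
            vc = VarianceComponents(150.0, 3500.0)
            sol = solve_mme(d, Ainv, vc)
            b, a = gls_oracle(d, A, vc)
            np.testing.assert_allclose(sol.fixed_effects.to_numpy(), b, atol=1e-8)
            np.testing.assert_allclose(sol.ebv.to_numpy(), a, atol=1e-8)

    def test_matches_gls_oracle_repeatability(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, 8, 12)
        pheno = make_pheno(ped, rng, n=30, model="multiparous")
        d = build_design(pheno, ModelSpec("multiparous", "A"), ped,
                         on_rank_deficiency="drop")
        A = build_A_tabular(ped).dense()
        Ainv = RelationshipMatrix(build_A_inverse(ped).dense(), ped.ids, True)
        vc = VarianceComponents(150.0, 3000.0, sigma_pe2=80.0)
        sol = solve_mme(d, Ainv, vc)
        b, a = gls_oracle(d, A, vc)
        np.testing.assert_allclose(sol.fixed_effects.to_numpy(), b, atol=1e-8)
        np.testing.assert_allclose(sol.ebv.to_numpy(), a, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(rng, 8, 10)
        pheno = make_pheno(ped, rng, n=15)
        d = build_design(pheno, ModelSpec("primiparous", "A"), ped,
                         on_rank_deficiency="drop")
        Ainv = RelationshipMatrix(build_A_inverse(ped).dense(), ped.ids, True)
        sol = solve_mme(d, Ainv, VarianceComponents(1e-8, 3500.0), compute_pev=False)
        assert np.abs(sol.ebv.to_numpy()).max() < 1e-6


def test_uninformative_record_does_not_hurt_others():
    # a duplicated animal placed alone in a fresh HYS cell is absorbed by that
    # cell's fixed effect; nobody else's reliability may drop
    rng = np.random.default_rng(10)
    ped = random_pedigree(rng, 8, 12)
    pheno = make_pheno(ped, rng, n=15)
    vc = VarianceComponents(150.0, 3500.0)
    Ainv = RelationshipMatrix(build_A_inverse(ped).dense(), ped.ids, True)
    base = solve_mme(build_design(pheno, ModelSpec("primiparous", "A"), ped,
                                  on_rank_deficiency="drop"), Ainv, vc)
    unphenotyped = [a for a in ped.ids if a not in set(pheno.table["animal_id"])][0]
    extra = pheno.table.iloc[[0]].copy()
    extra["animal_id"] = unphenotyped
    extra["herd"], extra["year"], extra["season"] = 99, 99, 99  # singleton cell
    aug = PhenotypeTable(pd.concat([pheno.table, extra], ignore_index=True))
    sol = solve_mme(build_design(aug, ModelSpec("primiparous", "A"), ped,
                                 on_rank_deficiency="drop"), Ainv, vc)
    others = [a for a in ped.ids if a != unphenotyped]
    drop = (base.reliability.loc[others] - sol.reliability.loc[others]).max()
    assert drop < 1e-8


class TestAccuracy:
    def test_closed_forms(self):
        vc = VarianceComponents(100.0, 300.0)
        rel, acc = compute_accuracy(np.array([0.0, 100.0, 75.0]), vc)
        np.testing.assert_allclose(acc, [1.0, 0.0, 0.5])
        rel2, acc2 = compute_accuracy(np.array([75.0]), vc, mode="literal")
        assert acc2[0] == pytest.approx(0.25)

    def test_zero_sigma_a_raises(self):
        with pytest.raises(ModelError):
            compute_accuracy(np.array([1.0]), VarianceComponents(0.0, 1.0))


class TestREML:
    def _sire_design(self, y, sire_of_record, n_sires):
        n = len(y)
        X = np.ones((n, 1))
        Z = sp.csr_matrix((np.ones(n), (np.arange(n), sire_of_record)), shape=(n, n_sires))
        return DesignBundle(y=y, X=X, Z_animal=Z, Z_pe=None,
                            animal_ids=np.arange(n_sires), pe_ids=None,
                            fixed_names=["intercept"])

    def test_matches_balanced_anova(self):
        # balanced one-way random model: REML == ANOVA estimators
        rng = np.random.default_rng(7)
        s, m = 40, 10
        sire_eff = rng.normal(0, np.sqrt(50.0), size=s)
        y = np.repeat(sire_eff, m) + rng.normal(0, np.sqrt(200.0), size=s * m) + 300.0
        sire_of_record = np.repeat(np.arange(s), m)
        d = self._sire_design(y, sire_of_record, s)
        K_inv = RelationshipMatrix(np.eye(s), np.arange(s), True)
        est = estimate_reml(d, K_inv, tol=1e-10)
        ybar_i = y.reshape(s, m).mean(axis=1)
        msw = ((y.reshape(s, m) - ybar_i[:, None]) ** 2).sum() / (s * (m - 1))
        msb = m * ((ybar_i - y.mean()) ** 2).sum() / (s - 1)
        sigma_s_anova = (msb - msw) / m
        assert est.sigma_e2 == pytest.approx(msw, abs=1e-6)
        assert est.sigma_a2 == pytest.approx(sigma_s_anova, abs=1e-6)

    def test_repeatability_model_matches_nested_anova(self):
        # balanced nested design: sires / individuals / repeated records;
        # REML equals the nested ANOVA estimators when interior
        rng = np.random.default_rng(12)
        s, k, m = 30, 4, 3  # sires x individuals x records
        sire_eff = rng.normal(0, np.sqrt(60.0), s)
        ind_eff = rng.normal(0, np.sqrt(40.0), s * k)
        y = (np.repeat(sire_eff, k * m) + np.repeat(ind_eff, m)
             + rng.normal(0, np.sqrt(100.0), s * k * m) + 250.0)
        n = len(y)
        X = np.ones((n, 1))
        Za = sp.csr_matrix((np.ones(n), (np.arange(n), np.repeat(np.arange(s), k * m))),
                           shape=(n, s))
        Zp = sp.csr_matrix((np.ones(n), (np.arange(n), np.repeat(np.arange(s * k), m))),
                           shape=(n, s * k))
        d = DesignBundle(y=y, X=X, Z_animal=Za, Z_pe=Zp,
                         animal_ids=np.arange(s), pe_ids=np.arange(s * k),
                         fixed_names=["intercept"])
        est = estimate_reml(d, RelationshipMatrix(np.eye(s), np.arange(s), True),
                            tol=1e-10)
        cube = y.reshape(s, k, m)
        ind_mean = cube.mean(axis=2)
        sire_mean = cube.mean(axis=(1, 2))
        ms_within = ((cube - ind_mean[:, :, None]) ** 2).sum() / (s * k * (m - 1))
        ms_ind = m * ((ind_mean - sire_mean[:, None]) ** 2).sum() / (s * (k - 1))
        ms_sire = k * m * ((sire_mean - y.mean()) ** 2).sum() / (s - 1)
        sigma_e = ms_within
        sigma_pe = (ms_ind - ms_within) / m
        sigma_s = (ms_sire - ms_ind) / (k * m)
        assert est.sigma_e2 == pytest.approx(sigma_e, abs=1e-5)
        assert est.sigma_pe2 == pytest.approx(sigma_pe, abs=1e-5)
        assert est.sigma_a2 == pytest.approx(sigma_s, abs=1e-5)

    def test_null_heritability_shrinks_to_zero(self):
        # σa² = 0 truth: estimate collapses in most replicates
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(10):
            s, m = 25, 8
            y = rng.normal(0, np.sqrt(200.0), size=s * m)
            d = self._sire_design(y, np.repeat(np.arange(s), m), s)
            K_inv = RelationshipMatrix(np.eye(s), np.arange(s), True)
            est = estimate_reml(d, K_inv)
            if est.sigma_a2 < 0.05 * est.sigma_e2:
                hits += 1
        assert hits >= 9

    def test_loglik_monotone_trajectory(self):
        rng = np.random.default_rng(9)
        s, m = 20, 6
        y = np.repeat(rng.normal(0, 5, s), m) + rng.normal(0, 10, s * m)
        d = self._sire_design(y, np.repeat(np.arange(s), m), s)
        est = estimate_reml(d, RelationshipMatrix(np.eye(s), np.arange(s), True))
        ll = np.array(est.loglik_trajectory)
        assert np.all(np.diff(ll) >= -1e-7)
        assert est.standard_errors is not None
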