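"""WssGWAS operations: back-solve, reweighting, window scan, gene mapping."""

import numpy as np
import pandas as pd
import pytest

from wssgblup.genomic import GenotypeError, SnpMap, SnpWeights
from wssgblup.gwas import (
    GeneAnnotation,
    SnpEffects,
    WindowResult,
    backsolve_snp_effects,
    map_windows_to_genes,
    select_windows,
    update_weights,
    window_scan,
    windows_to_frame,
)


def make_map(n, chrom=None, freq=None):
    chrom = chrom if chrom is not None else np.ones(n, dtype=int)
    tab = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": chrom,
        "bp": np.concatenate([np.arange(1, (chrom == c).sum() + 1) * 1000
                              for c in pd.unique(chrom)]),
        "freq": freq if freq is not None else np.full(n, 0.5),
    })
    return SnpMap(tab)


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        Zc = rng.normal(size=(4, 10))
        u = backsolve_snp_effects(np.zeros(4), Zc, SnpWeights.identity(10), make_map(10))
        np.testing.assert_allclose(u.u, 0.0)

    def test_projection_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            Zc = rng.normal(size=(6, 20))
            a = rng.normal(size=6)
            w = SnpWeights(rng.uniform(0.5, 2.0, 20))
            u = backsolve_snp_effects(a, Zc, w, make_map(20))
            np.testing.assert_allclose(Zc @ u.u, a, atol=1e-8)

    def test_matches_dense_solve(self):
        Zc = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -1.0]])
        a = np.array([0.3, -0.7])
        d = np.array([1.0, 2.0, 0.5])
        u = backsolve_snp_effects(a, Zc, SnpWeights(d), make_map(3))
        S = Zc @ np.diag(d) @ Zc.T
        expected = np.diag(d) @ Zc.T @ np.linalg.solve(S, a)
        np.testing.assert_allclose(u.u, expected, atol=1e-12)


class TestWeights:
    def test_equal_effects_equal_frequencies_give_unit_weights(self):
        eff = SnpEffects(np.full(6, 0.3))
        w = update_weights(eff, make_map(6))
        np.testing.assert_allclose(w.d, 1.0)

    def test_normalization_sum_is_M(self):
        rng = np.random.default_rng(2)
        eff = SnpEffects(rng.normal(size=50))
        w = update_weights(eff, make_map(50, freq=rng.uniform(0.05, 0.95, 50)))
        assert w.d.sum() == pytest.approx(50.0, abs=1e-10)

    def test_hand_case(self):
        eff = SnpEffects(np.array([1.0, 2.0]))
        w = update_weights(eff, make_map(2))
        np.testing.assert_allclose(w.d, [0.4, 1.6])

    def test_all_zero_effects_warns_uniform(self):
        with pytest.warns(UserWarning):
            w = update_weights(SnpEffects(np.zeros(4)), make_map(4))
        np.testing.assert_allclose(w.d, 1.0)


class TestWindowScan:
    def test_zero_effects_zero_percent(self):
        rng = np.random.default_rng(3)
        Zc = rng.normal(size=(5, 12))
        res = window_scan(SnpEffects(np.zeros(12)), Zc, make_map(12), 100.0, (1, 5))
        assert all(w.pct_variance == 0 for w in res)

    def test_single_snp_windows_match_definition(self):
        rng = np.random.default_rng(4)
        Zc = rng.normal(size=(8, 6))
        u = rng.normal(size=6)
        res = window_scan(SnpEffects(u), Zc, make_map(6), 50.0, (1,))
        for w in res:
            direct = (Zc[:, w.first_snp] * u[w.first_snp]).var() / 50.0 * 100
            assert w.pct_variance == pytest.approx(direct, abs=1e-12)

    def test_bruteforce_two_chromosomes(self):
        rng = np.random.default_rng(5)
        chrom = np.array([1] * 7 + [2] * 5)
        Zc = rng.normal(size=(10, 12))
        u = rng.normal(size=12)
        m = make_map(12, chrom=chrom)
        res = window_scan(SnpEffects(u), Zc, m, 80.0, (3,))
        # windows never span chromosomes; values match a brute-force loop
        assert len(res) == (7 - 3 + 1) + (5 - 3 + 1)
        for w in res:
            cols = np.arange(w.first_snp, w.last_snp + 1)
            assert np.all(chrom[cols] == w.chrom)
            vals = Zc[:, cols] @ u[cols]
            assert w.pct_variance == pytest.approx(vals.var() / 80.0 * 100, abs=1e-10)

    def test_short_chromosome_produces_no_windows(self):
        rng = np.random.default_rng(6)
        chrom = np.array([1] * 3 + [2] * 10)
        Zc = rng.normal(size=(4, 13))
        res = window_scan(SnpEffects(rng.normal(size=13)), Zc,
                          make_map(13, chrom=chrom), 10.0, (5,))
        assert all(w.chrom == 2 for w in res)

    def test_nested_window_not_sum_under_ld(self):
        # two perfectly correlated SNPs: 2-SNP window variance includes covariance
        Zc = np.array([[1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]])
        u = np.array([1.0, 1.0])
        m = make_map(2)
        one = window_scan(SnpEffects(u), Zc, m, 1.0, (1,))
        two = window_scan(SnpEffects(u), Zc, m, 1.0, (2,))
        assert two[0].pct_variance != pytest.approx(sum(w.pct_variance for w in one))
        # orthogonal columns: additivity holds
        Zo = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        one_o = window_scan(SnpEffects(u), Zo, m, 1.0, (1,))
        two_o = window_scan(SnpEffects(u), Zo, m, 1.0, (2,))
        assert two_o[0].pct_variance == pytest.approx(
            sum(w.pct_variance for w in one_o), abs=1e-12)

    def test_invalid_sigma(self):
        with pytest.raises(GenotypeError):
            window_scan(SnpEffects(np.zeros(3)), np.zeros((2, 3)), make_map(3), 0.0)


class TestSelection:
    def _mk(self, chrom, first, last, pct, first_bp=None, last_bp=None):
        return WindowResult(chrom, first, last, first_bp or (first + 1) * 1000,
                            last_bp or (last + 1) * 1000, last - first + 1, pct)

    def test_threshold_zero_returns_all_merged(self):
        res = [self._mk(1, 0, 4, 0.1), self._mk(2, 0, 4, 0.05)]
        assert len(select_windows(res, 0.0)) == 2

    def test_all_below_threshold_empty(self):
        assert select_windows([self._mk(1, 0, 4, 0.1)], 0.2) == []

    def test_overlapping_windows_merge_with_max_pct(self):
        res = [self._mk(1, 0, 4, 0.25), self._mk(1, 2, 6, 0.4), self._mk(1, 10, 14, 0.3)]
        out = select_windows(res, 0.2)
        assert len(out) == 2
        assert out[0].first_snp == 0 and out[0].last_snp == 6
        assert out[0].pct_variance == pytest.approx(0.4)
        assert out[0].first_bp == 1000 and out[0].last_bp == 7000


class TestGeneMapping:
    def annotation(self):
        return GeneAnnotation(pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "chrom": [1, 1, 1, 2, 2],
            "start": [100, 5000, 9000, 100, 700],
            "end": [200, 6000, 9500, 300, 900],
        }))

    def test_disjoint_region_empty(self):
        r = WindowResult(2, 0, 1, 400, 600, 2, 1.0)
        out = map_windows_to_genes([r], self.annotation())
        assert out[0].genes == []

    def test_abutting_gene_included(self):
        r = WindowResult(1, 0, 1, 4000, 5000, 2, 1.0)  # gene g2 starts at 5000
        out = map_windows_to_genes([r], self.annotation())
        assert out[0].genes == ["g2"]

    def test_matches_bruteforce_all_pairs(self):
        regions = [WindowResult(1, 0, 1, 150, 5500, 2, 1.0),
                   WindowResult(2, 0, 1, 250, 800, 2, 0.5)]
        out = map_windows_to_genes(regions, self.annotation())
        ann = self.annotation().table
        for r, res in zip(regions, out):
            expected = [g.gene_id for g in ann.itertuples()
                        if g.chrom == r.chrom and g.start <= r.last_bp and g.end >= r.first_bp]
            assert res.genes == expected

    def test_chromosome_mismatch_raises(self):
        r = WindowResult("chrX", 0, 1, 1, 10, 2, 1.0)
        with pytest.raises(GenotypeError, match="chrX"):
            map_windows_to_genes([r], self.annotation())


def test_windows_to_frame_roundtrip_columns():
    w = WindowResult(1, 0, 4, 1000, 5000, 5, 0.33, iteration=2, genes=["a", "b"])
    df = windows_to_frame([w])
    assert df.loc[0, "genes"] == "a;b"
    assert df.loc[0, "n_snp"] == 5
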