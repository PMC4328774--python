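import numpy as np
import pandas as pd
import pytest

from phenodiet import geography as geo


def _profiles(seed=0, n=20, p=8):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(0, 1, (n, p)),
                        index=[f"I{i}" for i in range(n)],
                        columns=[f"S{j}" for j in range(p)])


class TestOrdination:
    def test_rank_one_matrix(self):
        u = np.arange(10.0)
        v = np.array([1.0, -2.0, 0.5])
        res = geo.pca_ordination(pd.DataFrame(np.outer(u, v)))
        assert res.explained_ratio[0] == pytest.approx(1.0)

    def test_variance_conservation_and_reconstruction(self, paper_run):
        sym = paper_run["sym"]
        res = geo.pca_ordination(sym)
        X = sym.values.to_numpy()
        Xc = X - X.mean(axis=0)
        total = Xc.var(axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total, rel=1e-10)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-10)

    def test_sign_convention_deterministic(self):
        df = _profiles(3)
        a = geo.pca_ordination(df)
        b = geo.pca_ordination(df)
        assert (a.loadings == b.loadings).all().all()
        for pc in a.loadings.columns[:3]:
            col = a.loadings[pc]
            assert col[col.abs().idxmax()] > 0

    def test_sites_separate_on_pc1(self, paper_run):
        """Between-site divergence dominates the ordination: site means
        differ more along PC1 than along PC2."""
        sym = paper_run["sym"]
        res = geo.pca_ordination(sym)
        sites = sym.site_labels
        gap = res.scores.groupby(sites).mean()
        d1 = abs(gap["PC1"].iloc[0] - gap["PC1"].iloc[1])
        d2 = abs(gap["PC2"].iloc[0] - gap["PC2"].iloc[1])
        assert d1 > d2
        assert geo.pc_anova(res.scores, sites) < 1e-3
        top = [s for s, _ in res.top_loadings]
        boosted = set(paper_run["truth"].config.site1_boosts) | set(
            paper_run["truth"].config.site2_boosts)
        assert len(set(top) & boosted) >= 5


class TestPCAnova:
    def test_separated_groups(self):
        scores = pd.DataFrame({"PC1": np.r_[np.zeros(10), np.ones(10) * 10]})
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=scores.index)
        assert geo.pc_anova(scores, labels) < 1e-10

    def test_calibrated_under_label_permutation(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({"PC1": rng.normal(0, 1, 30)})
        ps = []
        for _ in range(40):
            labels = pd.Series(rng.permutation(["a"] * 15 + ["b"] * 15),
                               index=scores.index)
            ps.append(geo.pc_anova(scores, labels))
        assert 0.2 < np.mean(ps) < 0.8


class TestLdaLoo:
    def test_separated_clusters_classify_perfectly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.2, (12, 5)),
                       rng.normal(3, 0.2, (12, 5))])
        df = pd.DataFrame(X, index=[f"I{i}" for i in range(24)])
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=df.index)
        assert geo.lda_loo_classification(df, labels).accuracy == 1.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(7)
        df = _profiles(seed=7, n=30, p=10)
        accs = []
        for _ in range(25):
            labels = pd.Series(rng.permutation(["a"] * 15 + ["b"] * 15),
                               index=df.index)
            accs.append(geo.lda_loo_classification(df, labels).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_paper_like_site_classification(self, paper_run):
        cls = geo.lda_loo_classification(paper_run["sym"],
                                         paper_run["ym"].site_labels, "site")
        assert cls.accuracy == 1.0

    def test_race_contrast_above_chance(self, paper_run):
        _, cls = geo.race_contrast(paper_run["sym"],
                                   paper_run["survey"].metadata, "MSH")
        assert cls.accuracy > 0.6


class TestDistances:
    def test_haversine_degree_at_equator(self):
        assert geo.haversine_m(0, 0, 1, 0) == pytest.approx(111_195, rel=1e-3)
        assert geo.haversine_m(45.5, -73.1, 45.5, -73.1) == 0.0

    def test_distance_matrices(self, paper_run):
        md = paper_run["survey"].metadata
        d = geo.geo_distance_matrix(md[md.site == "MSH"])
        assert np.allclose(d, d.T) and (np.diag(d) == 0).all()
        prof = paper_run["sym"].values
        dp = geo.phenotype_distance_matrix(prof)
        assert dp.iloc[0, 0] == 0.0
        dup = pd.concat([prof.iloc[:1], prof.iloc[:1]])
        dup.index = ["x", "y"]
        assert geo.phenotype_distance_matrix(dup).iloc[0, 1] == 0.0


class TestMantel:
    def _random_dm(self, rng, n=12):
        x = rng.normal(0, 1, (n, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        ids = [f"I{i}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_identical_matrices_give_unity(self):
        d = self._random_dm(np.random.default_rng(0))
        res = geo.mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_invariant_under_common_permutation(self):
        rng = np.random.default_rng(1)
        a, b = self._random_dm(rng), self._random_dm(rng)
        r0 = geo.mantel_test(a, b, n_perm=9, seed=0).r
        perm = rng.permutation(len(a))
        ids = [a.index[i] for i in perm]
        a2 = a.loc[ids, ids]
        b2 = b.loc[ids, ids]
        assert geo.mantel_test(a2, b2, n_perm=9, seed=0).r == pytest.approx(r0)

    def test_agrees_with_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        a, b = self._random_dm(rng), self._random_dm(rng)
        ours = geo.mantel_test(a, b, n_perm=99, seed=0)
        r, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(a.to_numpy(), ids=a.index),
            skbio_stats.DistanceMatrix(b.to_numpy(), ids=b.index),
            method="pearson", permutations=0)
        assert ours.r == pytest.approx(r, abs=1e-10)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for k in range(15):
            a, b = self._random_dm(rng, 14), self._random_dm(rng, 14)
            ps.append(geo.mantel_test(a, b, n_perm=199, seed=k).p_value)
        assert 0.2 < np.mean(ps) < 0.8

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        a, b = self._random_dm(rng), self._random_dm(rng)
        p1 = geo.mantel_test(a, b, n_perm=299, seed=3).p_value
        p2 = geo.mantel_test(a, b, n_perm=299, seed=3).p_value
        assert p1 == p2

    def test_asymmetric_matrix_rejected(self):
        d = self._random_dm(np.random.default_rng(0))
        bad = d.copy()
        bad.iloc[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            geo.mantel_test(bad, d)

    def test_spatial_field_detected_in_paper_like(self, paper_run):
        """With the generator's spatial field on, profile distance is
        positively associated with geographic distance."""
        md = paper_run["survey"].metadata
        sym = paper_run["sym"]
        rs, ps = [], []
        for site in ("MSH", "Silwood"):
            sub = md[md.site == site]
            dg = geo.geo_distance_matrix(sub)
            dp = geo.phenotype_distance_matrix(sym.values.loc[dg.index])
            res = geo.mantel_test(dg, dp, n_perm=499, seed=1)
            rs.append(res.r)
            ps.append(res.p_value)
        assert np.mean(rs) > 0.05
        assert min(ps) < 0.05
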