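import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodiet import correlation_tradeoffs as ct


def _means(seed=0, n_iso=20, n_sub=6):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(0, 1, (n_iso, n_sub)),
                        index=[f"I{i}" for i in range(n_iso)],
                        columns=[f"S{j}" for j in range(n_sub)])


class TestCorrelationMatrix:
    def test_duplicate_and_negated_columns(self):
        means = _means()
        means["dup"] = means["S0"]
        means["neg"] = -means["S0"]
        m = ct.genetic_correlation_matrix(means)
        assert m.r.at["S0", "dup"] == pytest.approx(1.0)
        assert m.r.at["S0", "neg"] == pytest.approx(-1.0)
        assert np.allclose(m.r, m.r.T)
        assert np.allclose(np.diag(m.r), 1.0)

    def test_too_few_isolates_rejected(self):
        with pytest.raises(ValueError):
            ct.genetic_correlation_matrix(_means(n_iso=2))

    def test_zero_variance_columns_dropped(self):
        means = _means()
        means["flat"] = 1.0
        m = ct.genetic_correlation_matrix(means)
        assert m.dropped == ["flat"] and "flat" not in m.r.columns

    def test_paper_like_matrix_tracks_generator_structure(self, paper_run):
        """Realized correlations agree with the implied pooled structure
        at Fisher-z accuracy for n = 45 isolates."""
        ym, truth = paper_run["ym"], paper_run["truth"]
        means = ym.isolate_means[truth.retained]
        m = ct.genetic_correlation_matrix(means)
        imp = truth.implied_correlations
        core, anc = truth.core, truth.ancillary
        cc = m.r.loc[core, core].to_numpy()[np.triu_indices(len(core), 1)]
        ca = m.r.loc[core, anc].to_numpy().ravel()
        # 3 SE tolerance on category means (pairs are dependent, so the
        # naive SE is conservative only elementwise; use a broad band)
        assert cc.mean() == pytest.approx(imp["core/core"], abs=0.1)
        assert ca.mean() == pytest.approx(imp["core/ancillary"], abs=0.07)


class TestPermutationNull:
    def test_null_centered_at_zero(self):
        means = _means(seed=5, n_iso=15, n_sub=8)
        m = ct.genetic_correlation_matrix(means)
        res = ct.mean_correlation_with_null(m, means, n_perm=400, seed=2)
        se = res.null_distribution.std() / np.sqrt(len(res.null_distribution))
        assert abs(res.null_distribution.mean()) < 4 * se + 1e-3

    def test_shared_factor_is_detected(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, 30)
        means = pd.DataFrame(
            {f"S{j}": f + rng.normal(0, 0.3, 30) for j in range(6)})
        m = ct.genetic_correlation_matrix(means)
        res = ct.mean_correlation_with_null(m, means, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.observed_stat > max(np.abs(res.null_distribution))

    def test_independent_data_not_flagged(self):
        means = _means(seed=42, n_iso=40, n_sub=10)
        m = ct.genetic_correlation_matrix(means)
        res = ct.mean_correlation_with_null(m, means, n_perm=299, seed=1)
        assert res.p_value > 0.01
        assert abs(res.observed_stat) < 0.1

    def test_seeded_reproducibility(self):
        means = _means(seed=9)
        m = ct.genetic_correlation_matrix(means)
        a = ct.mean_correlation_with_null(m, means, n_perm=150, seed=7)
        b = ct.mean_correlation_with_null(m, means, n_perm=150, seed=7)
        assert (a.null_distribution == b.null_distribution).all()
        assert a.p_value == b.p_value


class TestCategoryContrast:
    def test_single_pair_within(self):
        means = _means()
        c = ct.category_contrast(means, ["S0", "S1"], ["S0", "S1"],
                                 n_perm=99, seed=0)
        expected = stats.pearsonr(means["S0"], means["S1"]).statistic
        assert c.mean_r == pytest.approx(expected) and c.n_pairs == 1

    def test_agrees_with_bruteforce_double_loop(self):
        means = _means(seed=3, n_iso=25, n_sub=6)
        cat_a, cat_b = ["S0", "S1", "S2"], ["S3", "S4", "S5"]
        pairs = [stats.pearsonr(means[a], means[b]).statistic
                 for a in cat_a for b in cat_b]
        c = ct.category_contrast(means, cat_a, cat_b, n_perm=49, seed=0)
        assert c.mean_r == pytest.approx(np.mean(pairs), abs=1e-12)
        assert c.sd_r == pytest.approx(np.std(pairs, ddof=1), abs=1e-12)

        within = [stats.pearsonr(means[a], means[b]).statistic
                  for i, a in enumerate(cat_a) for b in cat_a[i + 1:]]
        cw = ct.category_contrast(means, cat_a, cat_a, n_perm=49, seed=0)
        assert cw.mean_r == pytest.approx(np.mean(within), abs=1e-12)
        assert cw.n_pairs == 3

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            ct.category_contrast(_means(), ["S0", "S1"], ["S1", "S2"])

    def test_permutation_null_of_independent_data(self):
        ps = [
            ct.category_contrast(_means(seed=80 + k, n_iso=40, n_sub=8),
                                 ["S0", "S1", "S2"], ["S3", "S4", "S5"],
                                 n_perm=199, seed=k).p_value
            for k in range(6)
        ]
        # p-values are roughly uniform when the categories are independent
        assert 0.2 < np.mean(ps) <= 1.0

    def test_seeded_reproducibility(self):
        means = _means(seed=2)
        kw = dict(n_perm=120, seed=13)
        a = ct.category_contrast(means, ["S0", "S1"], ["S2", "S3"], **kw)
        b = ct.category_contrast(means, ["S0", "S1"], ["S2", "S3"], **kw)
        assert (a.mean_r, a.p_value) == (b.mean_r, b.p_value)


class TestStandardSuite:
    def _suite(self, paper_run, n_perm=199):
        ym, truth = paper_run["ym"], paper_run["truth"]
        means = ym.isolate_means[truth.retained]
        ann = {e.substrate: e.sugar_class
               for e in paper_run["survey"].plate_map.entries if e.is_carbon}
        diet_of = {s: ("core" if s in truth.core else "ancillary")
                   for s in truth.retained}
        sugar_of = {s: ann[s] for s in truth.retained}
        return ct.standard_contrast_suite(means, diet_of, sugar_of,
                                          n_perm=n_perm, seed=1)

    def test_paper_like_sign_pattern(self, paper_run):
        """Trade-offs appear as the (+, +, -, +, +, -) sign pattern over
        the six diet and sugar contrasts."""
        suite = self._suite(paper_run).set_index("contrast")
        assert suite.at["core/core", "mean_r"] > 0
        assert suite.at["ancillary/ancillary", "mean_r"] > 0
        assert suite.at["core/ancillary", "mean_r"] < 0
        assert suite.at["pentose/pentose", "mean_r"] > 0
        assert suite.at["hexose/hexose", "mean_r"] > 0
        assert suite.at["pentose/hexose", "mean_r"] < 0
        assert suite.at["core/ancillary", "p"] < 0.05
        assert suite.at["pentose/hexose", "p"] < 0.05

    def test_invariant_to_substrate_ordering(self, paper_run):
        ym, truth = paper_run["ym"], paper_run["truth"]
        means = ym.isolate_means[truth.retained]
        diet_of = {s: ("core" if s in truth.core else "ancillary")
                   for s in truth.retained}
        sugar_of = {s: "other" for s in truth.retained}
        a = ct.standard_contrast_suite(means, diet_of, sugar_of,
                                       n_perm=9, seed=0)
        b = ct.standard_contrast_suite(means[means.columns[::-1]], diet_of,
                                       sugar_of, n_perm=9, seed=0)
        pd.testing.assert_series_equal(
            a.set_index("contrast")["mean_r"].sort_index(),
            b.set_index("contrast")["mean_r"].sort_index(),
        )

    def test_missing_category_skipped(self):
        means = _means()
        suite = ct.standard_contrast_suite(
            means, {s: "ancillary" for s in means}, {s: "other" for s in means},
            n_perm=9, seed=0)
        assert list(suite["contrast"]) == ["ancillary/ancillary"]
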