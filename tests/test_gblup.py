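"""GBLUP REML: oracle equivalence, route equivalence, recovery, shrinkage."""

import numpy as np
import pandas as pd
import pytest

import traitgs as tg
from traitgs.gblup import RIDGE, IdentifiabilityError, ConditioningError
from traitgs.genotypes import RelationshipMatrix
from oracles import univariate_mme, bivariate_mme


def _ridged(a):
    return a.values + RIDGE * np.eye(len(a.genotype_ids))


class TestUnivariate:
    def test_blup_matches_dense_mme_oracle(self, tiny_grm):
        """The eigen-basis REML solution solves Henderson's equations."""
        rng = np.random.default_rng(0)
        n = len(tiny_grm.genotype_ids)
        y = pd.Series(rng.normal(0, 1, n), index=tiny_grm.genotype_ids)
        y.iloc[32:] = np.nan
        fit = tg.reml_univariate(y, tiny_grm, min_records=10)
        obs = np.flatnonzero(y.notna())
        mu, g = univariate_mme(y.dropna().to_numpy(), obs, _ridged(tiny_grm),
                               fit.sigma2_g, fit.sigma2_e)
        assert fit.mu == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(fit.gebv.to_numpy(), g, atol=1e-8)

    def test_constant_phenotype_degenerates(self, tiny_grm):
        y = pd.Series(3.0, index=tiny_grm.genotype_ids)
        fit = tg.reml_univariate(y, tiny_grm, min_records=10)
        assert fit.sigma2_g == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.gebv, 0.0, atol=1e-10)

    def test_h2_recovery_moderate(self, small_study, small_grm):
        fit = tg.reml_univariate(small_study.phenotypes["trait1"], small_grm)
        assert 0.05 < fit.h2_g < 0.75

    def test_shrinkage(self, small_study, small_grm):
        y = small_study.phenotypes["trait1"]
        fit = tg.reml_univariate(y, small_grm)
        assert fit.gebv.var(ddof=1) <= y.var(ddof=1)

    def test_too_few_records(self, tiny_grm):
        y = pd.Series(np.nan, index=tiny_grm.genotype_ids)
        y.iloc[:5] = 1.0
        with pytest.raises(ValueError):
            tg.reml_univariate(y, tiny_grm)


class TestPredictUnobserved:
    def test_duplicated_genotype_is_perfect_proxy(self):
        cfg = tg.SimulationConfig(n_genotypes=40, n_markers=300, seed=12)
        g = tg.simulate_genotypes(cfg)
        dos = np.vstack([g.dosages, g.dosages[0]])
        from traitgs.genotypes import GenotypeMatrix
        a = tg.vanraden_grm(GenotypeMatrix(dos, g.genotype_ids + ["COPY"],
                                           g.marker_ids))
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(0, 1, 41), index=a.genotype_ids)
        y["COPY"] = np.nan
        fit = tg.reml_univariate(y, a, min_records=10)
        pred = tg.predict_unobserved(fit, a, g.genotype_ids, ["COPY"])
        assert pred["COPY"] == pytest.approx(fit.gebv[g.genotype_ids[0]], abs=1e-4)

    def test_unrelated_genotype_predicts_zero(self):
        a_vals = np.eye(30) * 2.0  # no off-diagonal relationship at all
        a = RelationshipMatrix(a_vals, [f"G{i}" for i in range(30)])
        y = pd.Series(np.random.default_rng(2).normal(0, 1, 30), index=a.genotype_ids)
        y.iloc[-1] = np.nan
        fit = tg.reml_univariate(y, a, min_records=10)
        pred = tg.predict_unobserved(fit, a, a.genotype_ids[:-1], ["G29"])
        assert pred["G29"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_joint_missing_record_fit(self, small_study, small_grm):
        """Conditional-expectation route equals the joint BLUP on an 80/20 split."""
        rng = np.random.default_rng(3)
        ids = np.array(small_grm.genotype_ids)
        val = rng.choice(len(ids), size=40, replace=False)
        y = small_study.phenotypes["trait1"].copy()
        y.iloc[val] = np.nan
        fit = tg.reml_univariate(y, small_grm)
        observed = [g for g in ids if g not in set(ids[val])]
        pred = tg.predict_unobserved(fit, small_grm, observed, ids[val])
        np.testing.assert_allclose(pred.to_numpy(), fit.gebv.iloc[val].to_numpy(),
                                   atol=1e-8)

    def test_unknown_id_raises(self, small_grm, small_study):
        fit = tg.reml_univariate(small_study.phenotypes["trait1"], small_grm)
        with pytest.raises(KeyError):
            tg.predict_unobserved(fit, small_grm, small_grm.genotype_ids[:-1],
                                  ["NOT_A_GENOTYPE"])


class TestBivariate:
    def test_duplicated_trait_correlation_near_one(self, small_study, small_grm):
        y = small_study.phenotypes.copy()
        y["trait2"] = y["trait1"]
        fit = tg.reml_bivariate(y, small_grm)
        assert fit.cor_g >= 0.98

    def test_recovery_of_genetic_correlation(self, small_study, small_grm):
        fit = tg.reml_bivariate(small_study.phenotypes, small_grm)
        assert abs(fit.cor_g - small_study.realized_cor_g[0, 1]) < 0.2

    def test_canonical_and_ai_paths_agree_interior(self):
        """Both optimizers find the same interior REML optimum."""
        st = tg.simulate_study(tg.SimulationConfig(n_genotypes=200,
                                                   n_markers=1000, seed=2))
        a = tg.vanraden_grm(st.genotypes)
        f1 = tg.reml_bivariate(st.phenotypes, a, method="canonical")
        f2 = tg.reml_bivariate(st.phenotypes, a, method="ai", ll_tol=1e-11)
        assert f1.reml_loglik == pytest.approx(f2.reml_loglik, abs=1e-3)
        np.testing.assert_allclose(f1.G.values, f2.G.values, atol=5e-3)
        np.testing.assert_allclose(f1.R.values, f2.R.values, atol=5e-3)

    def test_paths_agree_at_psd_boundary(self, small_study, small_grm):
        """When the optimum sits on the PSD boundary (cor_g -> 1) the two
        paths agree up to the bending floor."""
        f1 = tg.reml_bivariate(small_study.phenotypes, small_grm,
                               method="canonical")
        f2 = tg.reml_bivariate(small_study.phenotypes, small_grm, method="ai",
                               ll_tol=1e-11)
        assert f1.reml_loglik == pytest.approx(f2.reml_loglik, abs=0.02)
        assert f1.cor_g == pytest.approx(f2.cor_g, abs=0.01)

    def test_monotone_likelihood_trace(self, small_study, small_grm):
        y = small_study.phenotypes.copy()
        y.iloc[:50, 0] = np.nan
        fit = tg.reml_bivariate(y, small_grm)
        diffs = np.diff(fit.trace)
        assert (diffs >= -1e-9).all()
        assert fit.converged

    def test_univariate_route_equivalence(self, small_study, small_grm):
        """A bivariate fit with the second trait fully missing collapses onto
        the univariate fit."""
        y = small_study.phenotypes.copy()
        y["trait2"] = np.nan
        bi = tg.reml_bivariate(y, small_grm, ll_tol=1e-13, par_tol=1e-9)
        uni = tg.reml_univariate(y["trait1"], small_grm)
        assert bi.G.values[0, 0] == pytest.approx(uni.sigma2_g, abs=1e-6)
        assert bi.R.values[0, 0] == pytest.approx(uni.sigma2_e, abs=1e-6)
        np.testing.assert_allclose(bi.gebv["trait1"], uni.gebv, atol=1e-5)

    def test_no_overlap_unidentifiable(self, small_grm):
        n = len(small_grm.genotype_ids)
        y = pd.DataFrame(np.random.default_rng(4).normal(0, 1, (n, 2)),
                         index=small_grm.genotype_ids, columns=["a", "b"])
        y.iloc[:100, 0] = np.nan
        y.iloc[100:, 1] = np.nan
        with pytest.raises(IdentifiabilityError):
            tg.reml_bivariate(y, small_grm)

    def test_shrinkage_both_traits(self, small_study, small_grm):
        fit = tg.reml_bivariate(small_study.phenotypes, small_grm)
        for t in small_study.phenotypes.columns:
            assert fit.gebv[t].var(ddof=1) <= small_study.phenotypes[t].var(ddof=1)


class TestBlupGivenComponents:
    G = np.array([[0.5, 0.3], [0.3, 0.8]])
    R = np.array([[0.7, 0.2], [0.2, 0.6]])

    def _toy(self, tiny_grm, seed=5):
        rng = np.random.default_rng(seed)
        n = len(tiny_grm.genotype_ids)
        y = pd.DataFrame(rng.normal(0, 1, (n, 2)), index=tiny_grm.genotype_ids,
                         columns=["focal", "secondary"])
        y.iloc[:10, 0] = np.nan     # focal missing, secondary present
        y.iloc[10:15, 1] = np.nan   # secondary missing
        y.iloc[15:18, :] = np.nan   # no records at all
        return y

    def test_matches_dense_mme_oracle(self, tiny_grm):
        y = self._toy(tiny_grm)
        gebv = tg.blup_given_components(y, tiny_grm, self.G, self.R)
        _, g_or = bivariate_mme(y, _ridged(tiny_grm), self.G, self.R)
        np.testing.assert_allclose(gebv.to_numpy(), g_or, atol=1e-8)

    def test_five_genotype_toy_oracle(self):
        a = RelationshipMatrix(np.eye(5) + 0.4, [f"G{i}" for i in range(5)])
        y = pd.DataFrame({"t1": [1.0, np.nan, 0.5, -0.2, np.nan],
                          "t2": [0.8, 1.2, np.nan, -0.5, 0.3]},
                         index=a.genotype_ids)
        gebv = tg.blup_given_components(y, a, self.G, self.R)
        _, g_or = bivariate_mme(y, a.values + RIDGE * np.eye(5), self.G, self.R)
        np.testing.assert_allclose(gebv.to_numpy(), g_or, atol=1e-8)

    def test_diagonal_components_decouple_traits(self, tiny_grm):
        y = self._toy(tiny_grm)
        gd = np.diag(np.diag(self.G))
        rd = np.diag(np.diag(self.R))
        joint = tg.blup_given_components(y, tiny_grm, gd, rd)
        obs = np.flatnonzero(y["focal"].notna())
        _, g_uni = univariate_mme(y["focal"].dropna().to_numpy(), obs,
                                  _ridged(tiny_grm), gd[0, 0], rd[0, 0])
        np.testing.assert_allclose(joint["focal"].to_numpy(), g_uni, atol=1e-8)

    def test_secondary_records_help_focal_prediction(self):
        """The trait-assisted mechanism: focal GEBV accuracy for focal-missing
        genotypes is higher when their secondary records are present."""
        g_cov = np.array([[0.3, 0.9 * np.sqrt(0.3 * 0.8)],
                          [0.9 * np.sqrt(0.3 * 0.8), 0.8]])
        r_cov = np.array([[0.7, 0.1], [0.1, 0.2]])
        wins, diffs = 0, []
        for rep in range(30):
            st = tg.simulate_study(tg.SimulationConfig(
                n_genotypes=150, n_markers=600, heritabilities=(0.3, 0.8),
                genetic_correlation=0.9, residual_correlation=0.3,
                n_qtl=600, seed=700 + rep))
            a = tg.vanraden_grm(st.genotypes)
            y = st.phenotypes.copy()
            miss = np.arange(100, 150)
            y.iloc[miss, 0] = np.nan
            with_sec = tg.blup_given_components(y, a, g_cov, r_cov)
            y2 = y.copy()
            y2.iloc[miss, 1] = np.nan
            without = tg.blup_given_components(y2, a, g_cov, r_cov)
            truth = st.true_breeding_values.iloc[miss, 0]
            r_with = np.corrcoef(with_sec.iloc[miss, 0], truth)[0, 1]
            r_without = np.corrcoef(without.iloc[miss, 0], truth)[0, 1]
            diffs.append(r_with - r_without)
            wins += r_with > r_without
        assert np.mean(diffs) > 0.05
        assert wins >= 27

    def test_singular_r_with_overlap_rejected(self, tiny_grm):
        y = self._toy(tiny_grm)
        r_sing = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ConditioningError):
            tg.blup_given_components(y, tiny_grm, self.G, r_sing)


class TestCorrelationSE:
    def test_se_small_at_moderate_n_strong_signal(self):
        st = tg.simulate_study(tg.SimulationConfig(
            n_genotypes=500, n_markers=2000, heritabilities=(0.5, 0.8),
            genetic_correlation=0.8, seed=31))
        a = tg.vanraden_grm(st.genotypes)
        fit = tg.reml_bivariate(st.phenotypes, a)
        se_g, se_r = tg.correlation_se(fit)
        assert np.isfinite(se_g) and np.isfinite(se_r)
        assert 0.0 <= se_g < 0.1
        assert se_r >= 0.0

    def test_ses_nonnegative_finite(self, small_study, small_grm):
        fit = tg.reml_bivariate(small_study.phenotypes, small_grm)
        se_g, se_r = tg.correlation_se(fit)
        for se in (se_g, se_r):
            assert np.isfinite(se) and se >= 0
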