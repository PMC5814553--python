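"""CV folds, derived statistics, and the five selection strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import traitgs as tg
from traitgs.strategies import PartitionError, UndefinedIndexError


class TestMakeFolds:
    def test_paper_panel_fold_sizes(self):
        scheme = tg.make_folds(453, 5, 2, seed=1)
        sizes = sorted(np.bincount(scheme.assignments[0]), reverse=True)
        assert sizes == [91, 91, 91, 90, 90]

    def test_exact_division(self):
        scheme = tg.make_folds(10, 5, 1, seed=2)
        assert np.bincount(scheme.assignments[0]).tolist() == [2] * 5

    def test_deterministic_and_exhaustive(self):
        s1 = tg.make_folds(50, 5, 3, seed=3)
        s2 = tg.make_folds(50, 5, 3, seed=3)
        np.testing.assert_array_equal(s1.assignments, s2.assignments)
        assert s1.fingerprint() == s2.fingerprint()
        assert set(s1.assignments.ravel()) == set(range(5))

    def test_n_smaller_than_k(self):
        with pytest.raises(PartitionError):
            tg.make_folds(4, 5, 1, seed=0)


class TestAucTrait:
    def test_direct_trapezoid(self):
        h = pd.DataFrame([[100.0, 200.0, 300.0, 400.0]], index=["g1"])
        assert tg.auc_trait(h, baseline=0.0)["g1"] == pytest.approx(800.0)

    def test_single_measurement(self):
        h = pd.DataFrame([[70.0]], index=["g1"])
        assert tg.auc_trait(h)["g1"] == pytest.approx(35.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 999))
    def test_scaling_linearity(self, scale, seed):
        h = pd.DataFrame(np.random.default_rng(seed).uniform(0, 300, (4, 5)))
        a1 = tg.auc_trait(h)
        a2 = tg.auc_trait(scale * h)
        np.testing.assert_allclose(a2, scale * a1, rtol=1e-10)

    def test_missing_measurement_propagates(self):
        h = pd.DataFrame([[100.0, np.nan, 300.0], [100.0, 200.0, 300.0]],
                         index=["g1", "g2"])
        with pytest.warns(UserWarning):
            a = tg.auc_trait(h)
        assert np.isnan(a["g1"]) and np.isfinite(a["g2"])


class TestIndirectIndex:
    def test_formula_matches_brute_force(self):
        rng = np.random.default_rng(5)
        g = pd.DataFrame(rng.normal(0, 2, (50, 2)), columns=["height", "moisture"])
        w = [0.84, -0.45]
        idx = tg.indirect_index(g, w)
        z = (g - g.mean()) / g.std(ddof=1)
        brute = w[0] * z["height"] + w[1] * z["moisture"]
        np.testing.assert_allclose(idx, brute, atol=1e-12)

    def test_identical_vectors_collinear(self):
        v = pd.Series(np.random.default_rng(6).normal(0, 1, 30))
        g = pd.DataFrame({"a": v, "b": v})
        idx = tg.indirect_index(g, [0.5, 0.5])
        assert abs(np.corrcoef(idx, v)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_single_trait_preserves_correlation(self):
        rng = np.random.default_rng(7)
        g = pd.DataFrame({"a": rng.normal(0, 3, 40)})
        target = rng.normal(0, 1, 40)
        idx = tg.indirect_index(g, [0.6])
        assert (np.corrcoef(idx, target)[0, 1]
                == pytest.approx(np.corrcoef(g["a"], target)[0, 1], abs=1e-12))

    def test_zero_variance_rejected(self):
        g = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            tg.indirect_index(g, [0.5, 0.5])


class TestCoincidence:
    def test_paper_chance_terms(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.normal(0, 1, 453))
        g = pd.Series(rng.normal(0, 1, 453))
        b, t, r, ci = tg.coincidence_index(x, g, 0.20, "top")
        assert (t, r) == (91, 18)

    def test_identical_ranking_gives_one(self):
        x = pd.Series(np.random.default_rng(9).normal(0, 1, 100))
        for direction in ("top", "bottom"):
            *_, ci = tg.coincidence_index(x, x.copy(), 0.2, direction)
            assert ci == pytest.approx(1.0)

    def test_null_distribution_centered_at_zero(self):
        rng = np.random.default_rng(10)
        x = pd.Series(rng.normal(0, 1, 453))
        cis = []
        for _ in range(10_000):
            g = pd.Series(rng.permutation(453).astype(float))
            *_, ci = tg.coincidence_index(x, g, 0.20, "top")
            cis.append(ci)
        assert abs(np.mean(cis)) < 0.02

    def test_degenerate_small_n(self):
        # n=4 at 90% intensity: T = R = 4, the index is undefined
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(UndefinedIndexError):
            tg.coincidence_index(x, x, 0.9, "top")


class TestExpectedSelectionAccuracy:
    def test_perfect_proxy(self):
        out = tg.expected_selection_accuracy(0.5, 1.0, 1.0, 0.4)
        assert out["ips"] == pytest.approx(1.0)

    def test_ps_identity_ratio(self):
        out = tg.expected_selection_accuracy(0.51, 0.9, 0.5, 0.51)
        assert out["ratio_ps"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        out = tg.expected_selection_accuracy(0.5, 0.9, 0.8, 0.6)
        assert out["ratio_ps"] == pytest.approx(1.2)
        assert out["ratio_ips"] == pytest.approx(0.6 / 0.72)

    def test_zero_denominator_marked(self):
        out = tg.expected_selection_accuracy(0.0, 0.9, 0.0, 0.6)
        assert np.isnan(out["ratio_ps"]) and np.isnan(out["ratio_ips"])


@pytest.fixture(scope="module")
def cv_panel():
    """A structured mid-size panel where marker prediction has real signal."""
    cfg = tg.SimulationConfig(n_genotypes=240, n_markers=1500,
                              heritabilities=(0.26, 0.9),
                              genetic_correlation=0.9,
                              residual_correlation=0.35,
                              n_subpops=8, fst=0.5, seed=42)
    study = tg.simulate_study(cfg)
    return study, tg.vanraden_grm(study.genotypes)


class TestRunStrategy:
    def test_uninformative_secondary_matches_standard(self):
        cfg = tg.SimulationConfig(n_genotypes=250, n_markers=1200,
                                  heritabilities=(0.4, 0.8),
                                  genetic_correlation=np.eye(2),
                                  residual_correlation=np.eye(2),
                                  n_qtl=1200, seed=43)
        study = tg.simulate_study(cfg)
        a = tg.vanraden_grm(study.genotypes)
        scheme = tg.make_folds(250, 5, 8, seed=44)
        res = tg.compare_strategies(
            study.phenotypes, a,
            [tg.StrategyName("standard", "trait1"),
             tg.StrategyName("trait_assisted", "trait1", ("trait2",))],
            scheme)
        assert abs(res["trait_assisted"].mean - res["standard"].mean) < 0.05

    def test_strategy_trait_mismatch(self, cv_panel):
        study, a = cv_panel
        scheme = tg.make_folds(240, 5, 1, seed=1)
        s = tg.StrategyName("standard", "not_a_trait")
        with pytest.raises(ValueError, match="not_a_trait"):
            tg.run_strategy(study.phenotypes, a, s, scheme)

    def test_full_data_components_mode_runs(self, cv_panel):
        study, a = cv_panel
        scheme = tg.make_folds(240, 5, 2, seed=5)
        s = tg.StrategyName("trait_assisted", "trait1", ("trait2",))
        res = tg.run_strategy(study.phenotypes, a, s, scheme,
                              components_mode="full_data")
        assert np.isfinite(res.accuracies).all()

    def test_multi_trait_indirect_runs(self):
        cfg = tg.SimulationConfig(n_genotypes=200, n_markers=1000, n_traits=3,
                                  heritabilities=(0.3, 0.8, 0.6),
                                  genetic_correlation=np.array(
                                      [[1, 0.8, 0.5], [0.8, 1, 0.4], [0.5, 0.4, 1]]),
                                  residual_correlation=np.eye(3),
                                  n_subpops=8, fst=0.5, seed=45)
        study = tg.simulate_study(cfg)
        a = tg.vanraden_grm(study.genotypes)
        scheme = tg.make_folds(200, 5, 2, seed=46)
        s = tg.StrategyName("multi_trait_indirect", "trait1",
                            ("trait2", "trait3"))
        res = tg.run_strategy(study.phenotypes, a, s, scheme)
        assert np.isfinite(res.accuracies).all()
        assert res.predictions.shape == (2, 200)

    def test_failed_repeat_flagged_and_excluded(self, cv_panel, monkeypatch):
        """A fold-fit failure marks that repeat NaN with a warning; the
        summary is computed over the surviving repeats."""
        import traitgs.strategies as sm
        study, a = cv_panel
        real = sm.reml_univariate
        calls = {"n": 0}

        def flaky(y, grm, **kw):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("synthetic failure")
            return real(y, grm, **kw)

        monkeypatch.setattr(sm, "reml_univariate", flaky)
        scheme = tg.make_folds(240, 5, 2, seed=55)
        with pytest.warns(UserWarning, match="excluded"):
            res = tg.run_strategy(study.phenotypes, a,
                                  tg.StrategyName("standard", "trait1"), scheme)
        assert np.isnan(res.accuracies[0])
        assert np.isfinite(res.accuracies[1])
        assert np.isfinite(res.mean)

    def test_strategy_name_validation(self):
        with pytest.raises(ValueError):
            tg.StrategyName("standard", "y", ("h",))
        with pytest.raises(ValueError):
            tg.StrategyName("multi_trait_indirect", "y", ("h",))
        with pytest.raises(ValueError):
            tg.StrategyName("nonsense", "y")


class TestTrainingFractionSweep:
    def test_sweep_behaviour(self, cv_panel):
        """Less training data cannot help standard GS, and with a strong
        genetic correlation trait-assisted stays ahead even at 20%."""
        study, a = cv_panel
        scheme = tg.make_folds(240, 5, 8, seed=47)
        std = tg.StrategyName("standard", "trait1")
        ta = tg.StrategyName("trait_assisted", "trait1", ("trait2",))
        std_sweep = tg.training_fraction_sweep(study.phenotypes, a, std, scheme,
                                               [0.2, 0.8])
        ta_sweep = tg.training_fraction_sweep(study.phenotypes, a, ta, scheme,
                                              [0.2])
        by_f = {r.training_fraction: r for r in std_sweep}
        assert by_f[0.2].mean < by_f[0.8].mean
        assert ta_sweep[0].mean > by_f[0.2].mean

    def test_consistency_with_fold_cv_at_default(self, cv_panel):
        study, a = cv_panel
        scheme = tg.make_folds(240, 5, 6, seed=48)
        std = tg.StrategyName("standard", "trait1")
        cv_res = tg.run_strategy(study.phenotypes, a, std, scheme)
        sweep = tg.training_fraction_sweep(study.phenotypes, a, std, scheme,
                                           [0.8])[0]
        assert abs(sweep.mean - cv_res.mean) < 0.12

    def test_tiny_fraction_skipped(self, cv_panel):
        study, a = cv_panel
        scheme = tg.make_folds(240, 5, 1, seed=49)
        std = tg.StrategyName("standard", "trait1")
        with pytest.warns(UserWarning, match="skipped"):
            out = tg.training_fraction_sweep(study.phenotypes, a, std, scheme,
                                             [0.05])
        assert out == []
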