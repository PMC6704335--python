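import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imputome as im
from imputome.signatures import (bh_adjust, kruskal_screen,
                                 pairwise_consistency, to_per_million)


def _profile(arrays, feature="f1"):
    """Stack group arrays into a one-feature profile + group labels."""
    vals, labels = [], []
    for g, arr in arrays.items():
        vals += list(arr)
        labels += [g] * len(arr)
    idx = [f"S{i}" for i in range(len(vals))]
    return (pd.DataFrame({feature: vals}, index=idx),
            pd.Series(labels, index=idx))


class TestKruskalScreen:
    def test_hand_h_statistic(self):
        """Groups {1,2} vs {3,4}: H = 2.4 by the rank formula."""
        prof, groups = _profile({"Vata": [1, 2], "Pitta": [3, 4]})
        out = kruskal_screen(prof, groups, alpha=1.0)
        assert out.loc[0, "h"] == pytest.approx(2.4)

    def test_constant_feature_never_a_candidate(self):
        prof, groups = _profile({"Vata": [5, 5], "Pitta": [5, 5]})
        out = kruskal_screen(prof, groups, alpha=1.0)
        assert out.empty

    def test_null_rejection_rate_near_alpha(self):
        """~alpha of 1000 simulated null features pass the screen."""
        rng = np.random.default_rng(0)
        n = 30
        prof = pd.DataFrame(rng.normal(size=(n, 1000)),
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"f{j}" for j in range(1000)])
        groups = pd.Series(["Vata"] * 10 + ["Pitta"] * 10 + ["Kapha"] * 10,
                           index=prof.index)
        rate = len(kruskal_screen(prof, groups, alpha=0.05)) / 1000
        assert 0.025 <= rate <= 0.075

    def test_small_group_rejected(self):
        prof, groups = _profile({"Vata": [1], "Pitta": [3, 4]})
        with pytest.raises(ValueError, match="at least 2"):
            kruskal_screen(prof, groups)


class TestPairwiseConsistency:
    def test_clearly_separated_passes_both_modes(self):
        vals = np.array([10, 11, 12, 13, 1, 2, 1.5, 2.5, 1, 2, 1.5, 2.5])
        groups = pd.Series(["Kapha"] * 4 + ["Pitta"] * 4 + ["Vata"] * 4)
        for mode in ("strict", "less-strict"):
            ok, top, pv = pairwise_consistency(vals, groups, mode)
            assert ok and top == "Kapha"
            assert all(p < 0.05 for p in pv.values())

    def test_single_contrast_splits_the_modes(self):
        arrays = {"Vata": [5.0, 6.0, 7.0, 8.0],
                  "Pitta": [0.0, 0.1, 0.2, 0.3],
                  "Kapha": [4.0, 5.5, 6.5, 7.5]}
        prof, groups = _profile(arrays)
        vals = prof["f1"].to_numpy()
        ok_loose, top, _ = pairwise_consistency(vals, groups, "less-strict")
        ok_strict, _, _ = pairwise_consistency(vals, groups, "strict")
        assert ok_loose and top == "Vata"
        assert not ok_strict

    def test_strict_implies_less_strict(self):
        rng = np.random.default_rng(1)
        groups = pd.Series(["Vata"] * 8 + ["Pitta"] * 8 + ["Kapha"] * 8)
        for _ in range(50):
            vals = rng.normal(size=24) + rng.choice([0, 1]) * np.repeat(
                rng.normal(size=3), 8)
            s, _, _ = pairwise_consistency(vals, groups, "strict")
            l, _, _ = pairwise_consistency(vals, groups, "less-strict")
            assert (not s) or l


class TestLdaEffectSize:
    def _cohort(self, delta, seed=0):
        rng = np.random.default_rng(seed)
        n = 40
        base = rng.normal(5e4, 5e3, size=(n, 3)).clip(min=0)
        labels = ["Vata"] * 20 + ["Pitta"] * 20
        base[:20, 0] += delta
        prof = pd.DataFrame(base, index=[f"S{i}" for i in range(n)],
                            columns=["sig", "noise1", "noise2"])
        return prof, pd.Series(labels, index=prof.index)

    def test_no_signal_scores_near_zero(self):
        prof, groups = self._cohort(0.0)
        prof["flat"] = 1000.0
        scores = im.lda_effect_size(prof, groups, seed=0)
        assert scores["flat"] == pytest.approx(0.0, abs=0.5)

    def test_planted_per_million_separation_scores_above_two(self):
        """Class means 1e5 vs ~1e2 on the per-million scale -> log LDA >= 2."""
        rng = np.random.default_rng(2)
        n = 30
        prof = pd.DataFrame({
            "planted": np.r_[rng.normal(1e5, 1e4, 15),
                             rng.normal(1e2, 20, 15)].clip(min=0),
            "noise": rng.normal(5e3, 1e3, 30),
        }, index=[f"S{i}" for i in range(n)])
        groups = pd.Series(["Kapha"] * 15 + ["Vata"] * 15, index=prof.index)
        scores = im.lda_effect_size(prof, groups, seed=0)
        assert scores["planted"] >= 2.0

    def test_label_swap_leaves_score_unchanged(self):
        prof, groups = self._cohort(2e4, seed=3)
        swapped = groups.map({"Vata": "Pitta", "Pitta": "Vata"})
        a = im.lda_effect_size(prof, groups, seed=5)
        b = im.lda_effect_size(prof, swapped, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_deterministic_under_seed(self):
        prof, groups = self._cohort(1e4, seed=4)
        a = im.lda_effect_size(prof, groups, seed=9)
        b = im.lda_effect_size(prof, groups, seed=9)
        pd.testing.assert_series_equal(a, b)


class TestLefse:
    def test_planted_pathway_recovered_with_direction(self, bundle,
                                                      l3_profile):
        meta = bundle.metadata
        idx = meta[meta["gender"] == "F"].index
        recs = im.lefse(l3_profile.data.loc[idx], meta.loc[idx, "group"],
                        level="L3", mode="strict", seed=1)
        by_id = {r.function_id: r for r in recs}
        kapha_planted = bundle.truth[(bundle.truth["group"] == "Kapha")
                                     & (bundle.truth["gender"] == "F")]
        for l3 in kapha_planted["level3"]:
            assert l3 in by_id
            assert by_id[l3].enriched_group == "Kapha"
            assert by_id[l3].lda_score >= 2.0
            assert by_id[l3].mode == "strict"

    def test_strict_subset_of_less_strict(self, bundle, l3_profile):
        meta = bundle.metadata
        for gender in ("F", "M"):
            idx = meta[meta["gender"] == gender].index
            groups = meta.loc[idx, "group"]
            strict = {r.function_id
                      for r in im.lefse(l3_profile.data.loc[idx], groups,
                                        mode="strict", seed=2)}
            loose = {r.function_id
                     for r in im.lefse(l3_profile.data.loc[idx], groups,
                                       mode="less-strict", seed=2)}
            assert strict <= loose


class TestStampAnova:
    def test_hand_eta_squared(self):
        """Groups {1,2} vs {3,4}: eta^2 = 4/5."""
        prof, groups = _profile({"Vata": [1, 2], "Pitta": [3, 4]})
        res = im.stamp_anova(prof, groups, return_all=True)
        assert res[0].eta_squared == pytest.approx(0.8)

    def test_bh_step_up_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_constant_feature_not_significant(self):
        prof, groups = _profile({"Vata": [5, 5], "Pitta": [5, 5]})
        assert im.stamp_anova(prof, groups) == []

    def test_zero_within_variance_floored(self):
        prof, groups = _profile({"Vata": [1.0, 1.0], "Pitta": [2.0, 2.0]})
        res = im.stamp_anova(prof, groups, return_all=True)
        assert res[0].anova_p == pytest.approx(1e-300)
        assert res[0].eta_squared == pytest.approx(1.0)

    def test_unequal_group_sizes_and_tukey_pairs(self, bundle, l3_profile):
        meta = bundle.metadata
        idx = meta[meta["gender"] == "F"].index
        res = im.stamp_anova(l3_profile.data.loc[idx],
                             meta.loc[idx, "group"], return_all=True)
        planted = set(bundle.truth[bundle.truth["gender"] == "F"]["level3"])
        sig = {r.function_id for r in res if r.bh_q <= 0.05}
        assert planted <= sig
        assert all(len(r.tukey_pairwise) == 3 for r in res)
        assert all(0 <= r.eta_squared <= 1 for r in res)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        n = 30
        prof = pd.DataFrame(rng.normal(size=(n, 1000)),
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"f{j}" for j in range(1000)])
        groups = pd.Series(["Vata"] * 10 + ["Pitta"] * 10 + ["Kapha"] * 10,
                           index=prof.index)
        res = im.stamp_anova(prof, groups, return_all=True)
        rate = np.mean([r.anova_p < 0.05 for r in res])
        assert 0.025 <= rate <= 0.075


class TestCssNormalize:
    def test_hand_example(self):
        prof = pd.DataFrame([[1.0, 2.0, 100.0]], index=["S1"],
                            columns=list("abc"))
        out = im.css_normalize(prof, quantile=0.5)
        np.testing.assert_allclose(
            out.loc["S1"], [1000 / 3, 2000 / 3, 100_000 / 3], rtol=1e-12)

    def test_identical_samples_scale_identically(self):
        prof = pd.DataFrame([[1.0, 5.0, 9.0]] * 2, index=["S1", "S2"],
                            columns=list("abc"))
        out = im.css_normalize(prof)
        np.testing.assert_allclose(out.loc["S1"], out.loc["S2"])

    def test_all_zero_sample_rejected(self):
        prof = pd.DataFrame([[0.0, 0.0]], index=["S1"], columns=list("ab"))
        with pytest.raises(ValueError, match="nonzero"):
            im.css_normalize(prof)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_preserves_within_sample_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 60, size=(3, 8)).astype(float)
        if not (vals.sum(axis=1) > 0).all():
            return
        prof = pd.DataFrame(vals, index=list("xyz"),
                            columns=[f"f{j}" for j in range(8)])
        out = im.css_normalize(prof)
        for s in prof.index:
            np.testing.assert_array_equal(np.argsort(prof.loc[s].to_numpy()),
                                          np.argsort(out.loc[s].to_numpy()))


class TestFilterFeatures:
    def test_all_zero_feature_removed(self):
        prof = pd.DataFrame({"keep": [3.0, 4, 5, 6], "zero": [0.0, 0, 0, 0]})
        out = im.filter_features(prof, im.FilterConfig(
            variance_drop_fraction=0.0))
        assert list(out.columns) == ["keep"]

    def test_prevalence_threshold_is_inclusive(self):
        """count >= 2 in 1 of 4 samples (25% >= 20%) is kept."""
        prof = pd.DataFrame({"edge": [2.0, 0, 0, 0], "out": [1.0, 1, 1, 1]})
        out = im.filter_features(prof, im.FilterConfig(
            variance_drop_fraction=0.0))
        assert list(out.columns) == ["edge"]

    def test_iqr_floor_rule_drops_exactly_one_of_ten(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(
            rng.integers(2, 50, size=(8, 10)).astype(float),
            columns=[f"f{j}" for j in range(10)])
        out = im.filter_features(prof, im.FilterConfig())
        assert out.shape[1] == 9
        iqr = prof.quantile(0.75) - prof.quantile(0.25)
        dropped = set(prof.columns) - set(out.columns)
        assert iqr[list(dropped)[0]] == iqr.min()

    def test_everything_removed_is_an_error(self):
        prof = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.0]})
        with pytest.raises(ValueError, match="survive"):
            im.filter_features(prof, im.FilterConfig())


class TestImportanceRank:
    def _planted(self, seed=0, n=36, m=20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, m))
        labels = np.repeat(["Vata", "Pitta", "Kapha"], n // 3)
        X[:, 0] = (labels == "Vata") * 4 + (labels == "Pitta") * 2 \
            + rng.normal(scale=0.05, size=n)
        prof = pd.DataFrame(X, index=[f"S{i}" for i in range(n)],
                            columns=[f"f{j:02d}" for j in range(m)])
        return prof, pd.Series(labels, index=prof.index)

    def test_separating_feature_ranked_first(self):
        prof, groups = self._planted()
        res = im.importance_rank(prof, groups, n_trees=150, seed=5)
        assert res.ranking.iloc[0]["feature"] == "f00"
        assert res.oob_error < 0.2

    def test_shuffled_labels_give_chance_error(self):
        prof, groups = self._planted(seed=1)
        rng = np.random.default_rng(7)
        shuffled = pd.Series(rng.permutation(groups.to_numpy()),
                             index=groups.index)
        res = im.importance_rank(prof, shuffled, n_trees=150, seed=5)
        chance = 1 - shuffled.value_counts(normalize=True).max()
        assert res.oob_error == pytest.approx(chance, abs=0.2)

    def test_ranking_is_stable_sort_with_lexicographic_ties(self):
        prof, groups = self._planted(seed=2)
        res = im.importance_rank(prof, groups, n_trees=60, seed=3)
        expected = sorted(res.importances.index,
                          key=lambda f: (-res.importances[f], f))
        assert list(res.ranking["feature"]) == expected[:len(res.ranking)]

    def test_n_top_larger_than_features_returns_all(self):
        prof, groups = self._planted(seed=3, m=5)
        res = im.importance_rank(prof, groups, n_top=30, n_trees=40, seed=1)
        assert len(res.ranking) == 5

    def test_deterministic_under_seed(self):
        prof, groups = self._planted(seed=4)
        a = im.importance_rank(prof, groups, n_trees=50, seed=2)
        b = im.importance_rank(prof, groups, n_trees=50, seed=2)
        pd.testing.assert_series_equal(a.importances, b.importances)


class TestBhProperties:
    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=40))
    def test_monotone_and_permutation_invariant(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q2 = bh_adjust(p[perm])
        np.testing.assert_allclose(q2, q[perm])
        assert (q >= p).all()
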