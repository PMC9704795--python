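import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connage.features import predictor_tags
from connage.parcellation import make_parcellation
from connage.plsr import nipals_fit, repeated_splits
from connage.profiles import (
    AgingProfile,
    align_signs,
    component_age_correlation,
    frontal_vs_rest_test,
    mean_loadings,
    network_mean_loadings,
    orient_reference,
)
from connage.synthetic import simulate_feature_cohort


@pytest.fixture(scope="module")
def fitted():
    cohort = simulate_feature_cohort(120, n_nodes=20, seed=0)
    X = cohort.X.to_numpy()
    y = cohort.age
    model = nipals_fit(X, y, 2)
    ensemble = repeated_splits(X, y, n_components=2, n_reps=20,
                               rng=np.random.default_rng(1))
    return cohort, X, y, model, ensemble


class TestOrientation:
    def test_scores_anticorrelate_with_age_after_orientation(self, fitted):
        _, X, y, model, _ = fitted
        base = model.predict(X).copy()
        oriented = orient_reference(model, y)
        for a in range(oriented.n_components):
            assert np.corrcoef(oriented.scores[:, a], y)[0, 1] <= 0
            assert oriented.y_loadings[a] <= 0
        assert np.allclose(oriented.predict(X), base, atol=1e-12)

    def test_positive_loading_means_age_related_decrease(self, fitted):
        cohort, X, y, model, _ = fitted
        oriented = orient_reference(model, y)
        # the strongest positively loaded predictor should fall with age
        j = int(np.argmax(oriented.x_loadings[:, 0]))
        slope = np.polyfit(y, X[:, j], 1)[0]
        assert slope < 0


class TestAlignment:
    def test_random_sign_flips_undone(self, fitted):
        _, _, y, model, ensemble = fitted
        ref = orient_reference(model, y)
        aligned_once = align_signs(ensemble, ref)
        rng = np.random.default_rng(2)
        flipped = align_signs(ensemble, ref)
        for rep in range(flipped.n_reps):
            for a in range(2):
                if rng.random() < 0.5:
                    flipped.loadings[rep, :, a] *= -1
                    flipped.weights[rep, :, a] *= -1
                    flipped.y_loadings[rep, a] *= -1
        realigned = align_signs(flipped, ref)
        assert np.allclose(realigned.loadings, aligned_once.loadings, atol=1e-12)

    def test_identical_models_identical_after_alignment(self, fitted):
        _, _, y, model, ensemble = fitted
        ref = orient_reference(model, y)
        aligned = align_signs(ensemble, ref)
        # all reps fit nearly the same structure: loading vectors should agree
        # in sign with the reference (correlation positive)
        for rep in range(aligned.n_reps):
            for a in range(2):
                r = np.corrcoef(aligned.loadings[rep, :, a], ref.x_loadings[:, a])[0, 1]
                assert r > 0

    def test_planted_loading_recovery(self):
        cohort = simulate_feature_cohort(200, n_nodes=20, seed=3)
        X, y = cohort.X.to_numpy(), cohort.age
        ref = orient_reference(nipals_fit(X, y, 2))
        ensemble = repeated_splits(X, y, n_components=2, n_reps=50,
                                   rng=np.random.default_rng(4))
        aligned = align_signs(ensemble, ref)
        profiles = mean_loadings(aligned, list(cohort.X.columns))
        planted = cohort.truth.component_loadings
        best = [
            max(abs(np.corrcoef(p.loadings["mean"], planted[k])[0, 1]) for k in range(2))
            for p in profiles
        ]
        assert min(best) >= 0.8


class TestMeanLoadings:
    def test_single_rep_mean_is_that_rep(self, fitted):
        cohort, _, y, model, ensemble = fitted
        from dataclasses import replace

        single = replace(
            ensemble,
            loadings=ensemble.loadings[:1],
            weights=ensemble.weights[:1],
            y_loadings=ensemble.y_loadings[:1],
            test_r=ensemble.test_r[:1],
            test_rmsep=ensemble.test_rmsep[:1],
            train_idx=ensemble.train_idx[:1],
            test_idx=ensemble.test_idx[:1],
        )
        profiles = mean_loadings(single, list(cohort.X.columns))
        assert np.allclose(profiles[0].loadings["mean"], ensemble.loadings[0, :, 0])
        assert np.allclose(profiles[0].loadings["sd"], 0.0)

    def test_mean_and_sd_match_direct_recompute(self, fitted):
        cohort, _, _, _, ensemble = fitted
        profiles = mean_loadings(ensemble, list(cohort.X.columns))
        for a, prof in enumerate(profiles):
            assert np.allclose(prof.loadings["mean"], ensemble.loadings[:, :, a].mean(axis=0))
            assert np.allclose(prof.loadings["sd"], ensemble.loadings[:, :, a].std(axis=0))
        assert profiles[0].cog_mean == pytest.approx(
            ensemble.loadings[:, -1, 0].mean()
        )


class TestNetworkSummaries:
    def _profile(self, values, tags):
        table = pd.DataFrame({"mean": values, "sd": 0.0}, index=tags.index)
        return AgingProfile(1, table, None, None)

    def test_constant_profile_gives_constant_averages(self):
        parc = make_parcellation(21)
        tags = predictor_tags(parc, with_cog=True)
        prof = self._profile(np.full(len(tags), 0.37), tags)
        out = network_mean_loadings(prof, tags)
        assert np.allclose(out.to_numpy(), 0.37)

    def test_matches_groupby_oracle(self, rng):
        parc = make_parcellation(21)
        tags = predictor_tags(parc, with_cog=True)
        prof = self._profile(rng.standard_normal(len(tags)), tags)
        out = network_mean_loadings(prof, tags)
        merged = prof.loadings.join(tags).dropna(subset=["network"])
        expected = merged.groupby(["network", "kind", "scope"])["mean"].mean()
        for net in out.index:
            for col in out.columns:
                kind, scope = col.rsplit("_", 1)
                assert out.at[net, col] == pytest.approx(expected.loc[(net, kind, scope)])

    def test_single_node_network_average_is_that_node(self, rng):
        parc = make_parcellation(21)
        tags = predictor_tags(parc, with_cog=False)
        # relabel so one network keeps a single node in the tag table
        single = tags[tags["node"] == 0].index
        tags.loc[tags["network"] == "VN", "network"] = "DMN"
        tags.loc[single, "network"] = "VN"
        prof = self._profile(rng.standard_normal(len(tags)), tags)
        out = network_mean_loadings(prof, tags)
        name = tags[tags["kind"].eq("SC") & tags["scope"].eq("intra") & tags["network"].eq("VN")].index[0]
        assert out.at["VN", "SC_intra"] == pytest.approx(prof.loadings.at[name, "mean"])


class TestFrontalTest:
    def _tags(self):
        return predictor_tags(make_parcellation(40), with_cog=True)

    def test_identical_groups_give_zero_t(self, rng):
        # hand-built family: frontal and rest carry the same value multiset
        pattern = rng.standard_normal(5)
        tags = pd.DataFrame(
            {
                "kind": "SC",
                "scope": "intra",
                "node": np.arange(10),
                "network": "VN",
                "lobe": ["frontal"] * 5 + ["other"] * 5,
            },
            index=[f"n{j:04d}_SC_intra" for j in range(10)],
        )
        table = pd.DataFrame({"mean": np.concatenate([pattern, pattern]), "sd": 0.0},
                             index=tags.index)
        prof = AgingProfile(1, table, None, None)
        t, p = frontal_vs_rest_test(prof, tags)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_frontal_shift_is_significant(self, rng):
        tags = self._tags()
        values = rng.standard_normal(len(tags))
        fam = tags["kind"].eq("SC") & tags["scope"].eq("intra")
        values[np.flatnonzero(fam & tags["lobe"].eq("frontal"))] += 3.0
        prof = AgingProfile(1, pd.DataFrame({"mean": values, "sd": 0.0}, index=tags.index), None, None)
        t, p = frontal_vs_rest_test(prof, tags)
        assert p < 0.001 and t > 0

    def test_matches_scipy_on_raw_groups(self, rng):
        tags = self._tags()
        values = rng.standard_normal(len(tags))
        prof = AgingProfile(1, pd.DataFrame({"mean": values, "sd": 0.0}, index=tags.index), None, None)
        t, p = frontal_vs_rest_test(prof, tags, kind="FCpos", scope="inter")
        fam = tags["kind"].eq("FCpos") & tags["scope"].eq("inter")
        a = values[np.flatnonzero(fam & tags["lobe"].eq("frontal"))]
        b = values[np.flatnonzero(fam & tags["lobe"].eq("other"))]
        expected = stats.ttest_ind(a, b)
        assert t == pytest.approx(expected.statistic, abs=1e-10)
        assert p == pytest.approx(expected.pvalue, abs=1e-10)

    def test_pooled_t_matches_textbook_formula(self, rng):
        a = rng.standard_normal(12) + 0.5
        b = rng.standard_normal(20)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        got = stats.ttest_ind(a, b).statistic  # kernel used by frontal_vs_rest_test
        assert got == pytest.approx(expected_t, abs=1e-10)


class TestAgeCorrelation:
    def test_score_equal_to_age_gives_unit_correlation(self, rng):
        age = rng.uniform(55, 85, 50)
        X = np.column_stack([age, 2.0 * age])  # score direction is exactly age
        model = nipals_fit(X, age, 1)
        (r, p), = component_age_correlation(model, age)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(8)
        n = 500
        X = rng.standard_normal((n, 10))
        y = rng.standard_normal(n)
        model = nipals_fit(X, y, 2)
        independent_age = rng.uniform(55, 85, n)
        rs = component_age_correlation(model, independent_age)
        assert all(abs(r) < 0.15 for r, _ in rs)

    def test_matches_pearson_kernel(self, fitted):
        _, _, y, model, _ = fitted
        rs = component_age_correlation(model, y)
        for a, (r, p) in enumerate(rs):
            expected = stats.pearsonr(model.scores[:, a], y)
            assert r == pytest.approx(expected.statistic, abs=1e-12)
            assert p == pytest.approx(expected.pvalue, abs=1e-12)
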