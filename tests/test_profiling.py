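import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitcalc.profiling import (
    PcaResult,
    RecurrenceThresholds,
    TumorProfile,
    build_feature_table,
    cluster_tumors,
    load_cohort_table,
    predict_recurrence,
    run_pca,
    summarize_cohort,
)
from pitcalc.protocol import SECRETAGOGUES
from pitcalc.scenarios import ANCHORED_PROFILES, anchored_profile


def _profile(tid, spont, non, mono, multi, diameter=3.0, stim_pct=None, rng=None):
    per_stim = stim_pct or {s: float(i * 7 % 40) for i, s in enumerate(SECRETAGOGUES)}
    return TumorProfile(
        tumor_id=tid, pct_spontaneous=spont, pct_non=non, pct_mono=mono,
        pct_multi=multi, per_stimulus_pct=per_stim, max_diameter_cm=diameter,
    )


def _random_profiles(n, rng):
    out = []
    for i in range(n):
        cat = rng.dirichlet([1, 1, 1]) * 100
        out.append(
            TumorProfile(
                tumor_id=f"t{i+1}",
                pct_spontaneous=float(rng.uniform(0, 60)),
                pct_non=float(cat[0]), pct_mono=float(cat[1]),
                pct_multi=100.0 - float(cat[0]) - float(cat[1]),
                per_stimulus_pct={s: float(rng.uniform(0, 60)) for s in SECRETAGOGUES},
                max_diameter_cm=float(rng.uniform(2, 7)),
            )
        )
    return out


class TestFeatureTable:
    def test_standardization_contract(self, rng):
        features, dropped = build_feature_table(_random_profiles(13, rng))
        assert features.shape == (13, 10)
        assert dropped == []
        np.testing.assert_allclose(features.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(features.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_identical_tumors_identical_rows(self, rng):
        profiles = _random_profiles(4, rng)
        twin = _random_profiles(1, rng)[0]
        twin2 = TumorProfile(
            tumor_id="twin2", pct_spontaneous=twin.pct_spontaneous, pct_non=twin.pct_non,
            pct_mono=twin.pct_mono, pct_multi=twin.pct_multi,
            per_stimulus_pct=dict(twin.per_stimulus_pct), max_diameter_cm=twin.max_diameter_cm,
        )
        features, _ = build_feature_table(profiles + [twin, twin2])
        np.testing.assert_allclose(features.loc[twin.tumor_id], features.loc["twin2"], atol=1e-12)

    def test_constant_feature_dropped_and_reported(self, rng):
        profiles = _random_profiles(5, rng)
        for p in profiles:
            p.max_diameter_cm = 4.2
        features, dropped = build_feature_table(profiles)
        assert dropped == ["max_diameter_cm"]
        assert "max_diameter_cm" not in features.columns

    def test_missing_feature_names_tumor(self, rng):
        profiles = _random_profiles(3, rng)
        profiles[1].per_stimulus_pct.pop("TRH")
        with pytest.raises(ValueError, match="t2.*TRH|TRH.*t2"):
            build_feature_table(profiles)

    def test_fewer_than_two_tumors_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_table(_random_profiles(1, rng))


class TestPca:
    def test_collinear_points_give_100_0(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 2.0, 4.0, 6.0]})
        res = run_pca(X)
        np.testing.assert_allclose(res.explained_pct, [100.0, 0.0], atol=1e-9)

    def test_explained_variance_sums_to_100(self, rng):
        X = pd.DataFrame(rng.normal(size=(13, 10)))
        res = run_pca(X)
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(res.explained_pct) <= 1e-9)

    def test_agrees_with_small_matrix_eigendecomposition_oracle(self, rng):
        """Independent oracle: dense eigendecomposition of the sample
        covariance via np.linalg.eig, compared up to sign."""
        for shape in [(4, 3), (5, 5), (6, 2)]:
            X = pd.DataFrame(rng.normal(size=shape))
            res = run_pca(X)
            cov = np.cov(X.to_numpy().T, ddof=1)
            cov = np.atleast_2d(cov)
            w, v = np.linalg.eig(cov)
            order = np.argsort(w)[::-1]
            w, v = np.real(w[order]), np.real(v[:, order])
            np.testing.assert_allclose(res.explained_pct, 100 * w / w.sum(), atol=1e-8)
            np.testing.assert_allclose(np.abs(res.loadings.to_numpy()), np.abs(v), atol=1e-8)

    def test_agrees_with_sklearn_reference(self, rng):
        from sklearn.decomposition import PCA

        X = pd.DataFrame(rng.normal(size=(13, 6)))
        res = run_pca(X)
        ref = PCA().fit(X.to_numpy())
        np.testing.assert_allclose(
            res.explained_pct, 100 * ref.explained_variance_ratio_, atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()), np.abs(ref.transform(X.to_numpy())), atol=1e-8
        )

    def test_two_latent_factor_cohort_concentrates_variance(self, rng):
        """A cohort driven by two latent axes (responsiveness, spontaneity)
        plus small noise puts >= 75% of variance on the first two PCs."""
        n = 13
        responsiveness = rng.uniform(-1, 1, n)
        spontaneity = rng.uniform(-1, 1, n)
        cols = {}
        for j in range(8):
            w1, w2 = rng.uniform(0.5, 1.5), rng.uniform(0.5, 1.5)
            if j % 2:
                cols[f"f{j}"] = w1 * responsiveness + 0.1 * rng.normal(size=n)
            else:
                cols[f"f{j}"] = w2 * spontaneity + 0.1 * rng.normal(size=n)
        X = pd.DataFrame(cols)
        X = (X - X.mean()) / X.std(ddof=1)
        res = run_pca(X)
        assert res.explained_pct[:2].sum() >= 75.0

    def test_sign_convention_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 4)))
        a, b = run_pca(X), run_pca(X)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for col in a.loadings.columns:
            j = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[j, col] > 0

    def test_degenerate_matrix_rejected(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            run_pca(X)

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            PcaResult(
                scores=pd.DataFrame(), loadings=pd.DataFrame(),
                explained_pct=np.array([30.0, 60.0]),
            )


class TestClustering:
    def test_two_tumors_single_merge(self, rng):
        features, _ = build_feature_table(_random_profiles(2, rng))
        order, labels = cluster_tumors(features)
        assert sorted(order) == ["t1", "t2"]
        assert set(labels.values()) == {1, 2}

    def test_identical_pair_merges_first(self, rng):
        X = pd.DataFrame(
            [[1.0, 0.2, 3.0], [0.1, 2.0, 1.0], [1.0, 0.2, 3.0]],
            index=["a", "b", "a2"], columns=["f1", "f2", "f3"],
        )
        order, labels = cluster_tumors(X)
        assert labels["a"] == labels["a2"] != labels["b"]
        ia, ia2 = order.index("a"), order.index("a2")
        assert abs(ia - ia2) == 1

    def test_k2_cut_separates_generator_groups(self, rng):
        """Two synthetic phenotype groups (responsive+spontaneous vs
        quiet+non-responsive) are split exactly by the k=2 cut."""
        profiles = []
        for i in range(6):
            profiles.append(_profile(
                f"rec{i}", spont=40 + rng.uniform(-5, 5), non=20.0, mono=20.0, multi=60.0,
                stim_pct={s: 50 + float(rng.uniform(-5, 5)) for s in SECRETAGOGUES},
            ))
        for i in range(7):
            profiles.append(_profile(
                f"non{i}", spont=rng.uniform(0, 3), non=90.0, mono=5.0, multi=5.0,
                stim_pct={s: 5 + float(rng.uniform(-2, 2)) for s in SECRETAGOGUES},
            ))
        features, _ = build_feature_table(profiles)
        _, labels = cluster_tumors(features)
        rec_labels = {labels[p.tumor_id] for p in profiles if p.tumor_id.startswith("rec")}
        non_labels = {labels[p.tumor_id] for p in profiles if p.tumor_id.startswith("non")}
        assert len(rec_labels) == 1 and len(non_labels) == 1 and rec_labels != non_labels

    def test_invariant_under_row_permutation(self, rng):
        profiles = _random_profiles(8, rng)
        features, _ = build_feature_table(profiles)
        _, labels = cluster_tumors(features)
        perm = features.iloc[rng.permutation(8)]
        _, labels_perm = cluster_tumors(perm)
        same = {t: labels[t] == labels["t1"] for t in labels}
        same_perm = {t: labels_perm[t] == labels_perm["t1"] for t in labels_perm}
        assert same == same_perm

    def test_more_clusters_than_tumors_rejected(self, rng):
        features, _ = build_feature_table(_random_profiles(3, rng))
        with pytest.raises(ValueError):
            cluster_tumors(features, k=4)


class TestRecurrenceRule:
    def test_anchored_profiles_reproduce_observed_recurrence(self):
        """The three worked-example tumors match their recorded recurrence
        status 3/3 under the default thresholds."""
        for name in ANCHORED_PROFILES:
            profile = anchored_profile(name)
            predicted, _ = predict_recurrence(profile)
            assert predicted == profile.recurrent_observed, name

    def test_clause_trace_reports_what_fired(self):
        predicted, clauses = predict_recurrence(anchored_profile("tumor8"))
        assert not predicted
        assert clauses["non_below_50"]
        assert not clauses["multi_above_20"]
        assert not clauses["spontaneous_present"]

    @given(
        spont=st.floats(0, 100), non=st.floats(0, 100),
        d_multi=st.floats(0, 30), d_spont=st.floats(0, 30), d_non=st.floats(0, 30),
    )
    @settings(max_examples=150, deadline=None)
    def test_rule_is_monotone(self, spont, non, d_multi, d_spont, d_non):
        """Raising multi or spontaneous, or lowering non, never flips a
        recurrent prediction back to non-recurrent."""
        non = min(non, 100.0)
        multi = (100.0 - non) * 0.6
        mono = 100.0 - non - multi
        base = TumorProfile("t", spont, non, mono, multi)
        pred0, _ = predict_recurrence(base)
        non2 = max(non - d_non, 0.0)
        multi2 = min(multi + d_multi, 100.0 - non2)
        mono2 = 100.0 - non2 - multi2
        better = TumorProfile("t", min(spont + d_spont, 100.0), non2, mono2, multi2)
        pred1, _ = predict_recurrence(better)
        assert pred1 or not pred0

    def test_thresholds_configurable(self):
        profile = anchored_profile("tumor8")
        relaxed = RecurrenceThresholds(min_spontaneous_pct=-1.0, min_multi_pct=0.1, max_non_pct=50.0)
        predicted, _ = predict_recurrence(profile, relaxed)
        assert predicted


class TestCohortSummary:
    def test_recurrence_and_deficiency_counts(self):
        s = summarize_cohort()
        assert s["n_patients"] == 13
        assert s["n_recurrent"] == 5
        assert s["pct_recurrent"] == 38.5
        assert s["deficiency_counts"]["TSH"] == 12
        assert s["deficiency_pct"]["TSH"] == 92.3
        assert s["deficiency_counts"]["ACTH"] == 7

    def test_lineage_marker_counts(self):
        s = summarize_cohort()
        assert s["lineage_marker_counts"]["NR5A1"] == 10
        assert round(s["lineage_marker_pct"]["NR5A1"]) == 77
        assert s["lineage_marker_counts"]["TBX19"] == 2
        assert s["lineage_marker_counts"]["POU1F1"] == 1

    def test_treatment_counts(self):
        s = summarize_cohort()
        assert s["treatment_counts"] == {"TSS": 11, "TC": 3, "XRT": 3, "CBG": 3, "TMZ": 1}

    def test_recomputed_cohort_moments(self):
        """Means recomputed from the packaged table (these are the table's
        own values, not any externally quoted summary)."""
        t = load_cohort_table()
        s = summarize_cohort(t)
        assert s["mean_age"] == round(float(t["age"].mean()), 1)
        assert s["mean_diameter_cm"] == round(float(t["max_diameter_cm"].mean()), 2)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(load_cohort_table().iloc[0:0])

    def test_unknown_token_rejected(self):
        t = load_cohort_table()
        t.loc[0, "deficiency"] = "XYZ"
        with pytest.raises(ValueError, match="XYZ"):
            summarize_cohort(t)


class TestProfileInvariants:
    def test_partition_must_sum_to_100(self):
        with pytest.raises(ValueError):
            TumorProfile("t", 10.0, 50.0, 30.0, 30.0)

    def test_percentages_bounded(self):
        with pytest.raises(ValueError):
            TumorProfile("t", 150.0, 50.0, 30.0, 20.0)
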