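"""PLS-DA, grouped cross-validation, y-scrambling, CVA, band ranking."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from gelbands.chemometrics import (
    CanonicalVariateAnalysis,
    PLSDAClassifier,
    cross_validate,
    cross_validated_cva,
    first_local_maximum,
    fit_cva,
    permutation_test,
    rank_discriminant_bands,
)


def _random_cohort(rng, n_samples=20, n_features=40, n_replicates=2, separation=0.0):
    """Random lanes with optional class separation along a feature block."""
    labels = np.array(["a", "b", "c"])[np.arange(n_samples) % 3]
    X, y, sid = [], [], []
    offsets = {"a": 0, "b": 1, "c": 2}
    for i in range(n_samples):
        base = rng.normal(0, 1, n_features)
        base[offsets[labels[i]] * 3 : offsets[labels[i]] * 3 + 3] += separation
        for r in range(n_replicates):
            X.append(base + rng.normal(0, 0.3, n_features))
            y.append(labels[i])
            sid.append(f"s{i}")
    return np.array(X), np.array(y), np.array(sid)


def _one_hot(y):
    classes = np.unique(y)
    return (y[:, None] == classes[None, :]).astype(float)


class TestPLSDAClassifier:
    def test_matches_sklearn_pls2_oracle(self):
        """NIPALS scores/weights/loadings agree with an independent PLS2
        implementation to 1e-6, up to per-component sign."""
        rng = np.random.default_rng(42)
        for shape in [(20, 10), (40, 731)]:
            X = rng.normal(size=shape)
            y = np.array(["a", "b", "c"])[np.arange(shape[0]) % 3]
            ours = PLSDAClassifier(n_components=5, tol=1e-13).fit(X, y)
            skl = PLSRegression(n_components=5, scale=False, tol=1e-22,
                                max_iter=5000).fit(X, _one_hot(y))
            for mine, theirs in [
                (ours.x_scores_, skl.x_scores_),
                (ours.x_weights_, skl.x_weights_),
                (ours.x_loadings_, skl.x_loadings_),
            ]:
                for a in range(5):
                    u, v = mine[:, a], theirs[:, a]
                    sign = np.sign(u @ v)
                    rel = np.max(np.abs(u - sign * v)) / np.linalg.norm(v)
                    assert rel < 1e-6, (shape, a)

    def test_scores_orthogonal_and_weights_unit_norm(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 50))
        y = np.array(["a", "b", "c"])[np.arange(30) % 3]
        m = PLSDAClassifier(n_components=6).fit(X, y)
        T = m.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) / np.max(np.diag(gram)) < 1e-8
        assert np.allclose(np.linalg.norm(m.x_weights_, axis=0), 1.0)

    def test_separable_classes_need_one_component(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.05, (20, 5))
        X[:10, 0] += 5.0
        y = np.array(["pos"] * 10 + ["neg"] * 10)
        m = PLSDAClassifier(n_components=1).fit(X, y)
        assert (m.predict(X) == y).all()

    def test_random_labels_train_near_chance_generalisation(self):
        """With no structure, held-out prediction sits near the 1/3 chance
        rate for three balanced groups."""
        rng = np.random.default_rng(7)
        X, y, sid = _random_cohort(rng, n_samples=30, separation=0.0)
        res = cross_validate(X, y, sid, max_components=3, keep_models=False)
        assert res.success_rates.max() < 0.65  # chance is 1/3

    def test_excessive_components_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 40))
        y = np.array(["a", "b"] * 4)
        with pytest.raises(ValueError, match="rank"):
            PLSDAClassifier(n_components=8).fit(X, y)

    def test_sklearn_param_interface(self):
        m = PLSDAClassifier(n_components=3)
        assert m.get_params()["n_components"] == 3
        m.set_params(n_components=2)
        assert m.n_components == 2


class TestCrossValidation:
    def test_separable_three_group_cohort_is_perfect_from_two_components(self):
        # three groups span a 2-D between-group subspace, so two latent
        # dimensions suffice for a perfect leave-sample-out assignment
        rng = np.random.default_rng(3)
        X, y, sid = _random_cohort(rng, separation=4.0)
        res = cross_validate(X, y, sid, max_components=4)
        assert res.success_rates[1] == 1.0
        assert res.best_k == 2
        assert (res.predictions.group == res.predictions.predicted).all()

    def test_success_invariant_to_lane_order_and_label_names(self):
        rng = np.random.default_rng(4)
        X, y, sid = _random_cohort(rng, separation=1.0)
        base = cross_validate(X, y, sid, max_components=3, keep_models=False)
        perm = rng.permutation(X.shape[0])
        shuffled = cross_validate(X[perm], y[perm], sid[perm], 3, keep_models=False)
        assert np.allclose(base.success_rates, shuffled.success_rates)
        y2 = np.array([{"a": "zz", "b": "qq", "c": "mm"}[v] for v in y])
        relabeled = cross_validate(X, y2, sid, 3, keep_models=False)
        assert np.allclose(base.success_rates, relabeled.success_rates)

    def test_replicates_always_grouped(self):
        rng = np.random.default_rng(5)
        X, y, sid = _random_cohort(rng, separation=1.0)
        res = cross_validate(X, y, sid, max_components=2, keep_models=False)
        for seg in res.segments:
            assert len({sid[i] for i in seg}) == 1

    def test_degenerate_segment_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 5))
        y = np.array(["a", "a", "a", "a", "b", "b"])
        sid = np.array(["s1", "s1", "s2", "s2", "s3", "s3"])
        with pytest.raises(ValueError, match="entire class"):
            cross_validate(X, y, sid, max_components=2)

    @pytest.mark.parametrize(
        "rates, expected",
        [
            ([0.4, 0.6, 0.7, 0.65, 0.8], 3),  # first peak, not global max
            ([0.7, 0.6, 0.9], 1),  # immediate decline
            ([0.5, 0.5, 0.6], 1),  # tie resolved toward fewer components
            ([0.3, 0.4, 0.5], 3),  # monotone rise ends at the last point
        ],
    )
    def test_first_local_maximum_rule(self, rates, expected):
        assert first_local_maximum(np.array(rates)) == expected


class TestPermutationTest:
    def test_null_centres_on_chance_and_signal_hits_floor(self):
        rng = np.random.default_rng(8)
        X, y, sid = _random_cohort(rng, n_samples=18, n_features=20, separation=4.0)
        res = permutation_test(X, y, sid, n_components=2, n_resamples=60, seed=0)
        assert res.p_empirical == pytest.approx(1.0 / (res.n_resamples + 1))
        # sample-level scrambling centres the null near the 1/3 chance rate
        # (leave-sample-out CV under the null is slightly pessimistic, so a
        # small downward bias is expected at this cohort size)
        assert abs(res.null_rates.mean() - 1 / 3) < 0.1
        assert res.observed_rate > res.null_rates.max()
        assert res.p_tail < res.p_empirical

    def test_observed_below_null_median_has_large_p(self):
        rng = np.random.default_rng(9)
        # anti-signal: replicates of a sample get conflicting noise so the
        # model generalises worse than scrambled labels on average
        X, y, sid = _random_cohort(rng, n_samples=18, n_features=10, separation=0.0)
        res = permutation_test(X, y, sid, n_components=2, n_resamples=40, seed=1)
        if res.observed_rate < np.median(res.null_rates):
            assert res.p_empirical > 0.5

    def test_minimum_resamples_enforced(self):
        rng = np.random.default_rng(10)
        X, y, sid = _random_cohort(rng, n_samples=9)
        with pytest.raises(ValueError, match="at least 20"):
            permutation_test(X, y, sid, 1, n_resamples=5)


class TestCVA:
    def test_three_groups_give_two_canonical_variates(self):
        rng = np.random.default_rng(11)
        S = rng.normal(size=(30, 4))
        y = np.array(["a", "b", "c"])[np.arange(30) % 3]
        proj = fit_cva(S, y)
        assert proj.scores.shape == (30, 2)
        assert proj.directions.shape == (4, 2)

    def test_identical_group_means_have_null_eigenvalues(self):
        rng = np.random.default_rng(12)
        S = rng.normal(size=(60, 4))
        y = np.array(["a", "b", "c"])[np.arange(60) % 3]
        cva = CanonicalVariateAnalysis().fit(S, y)
        # no real group structure: eigenvalues ~ O(g/n), far below 1
        assert np.all(cva.eigenvalues_ < 0.5)

    def test_separated_groups_order_eigenvalues(self):
        rng = np.random.default_rng(13)
        S = rng.normal(size=(60, 4))
        y = np.array(["a", "b", "c"])[np.arange(60) % 3]
        S[y == "a", 0] += 10.0
        S[y == "b", 1] += 5.0
        cva = CanonicalVariateAnalysis().fit(S, y)
        assert cva.eigenvalues_[0] >= cva.eigenvalues_[1] > 1.0

    def test_cross_validated_scores_shape(self):
        rng = np.random.default_rng(14)
        X, y, sid = _random_cohort(rng, n_samples=12, n_features=30, separation=2.0)
        scores, proj = cross_validated_cva(X, y, sid, n_pls_components=3)
        assert scores.shape == (X.shape[0], 2)
        assert set(proj.centroids.group) == {"a", "b", "c"}


class TestBandRanking:
    def _planted_cohort(self, rng, effect=1.0):
        """One discriminant band (feature 50) present only in group a."""
        n_feat = 200
        X, y, sid = [], [], []
        for i in range(24):
            grp = "a" if i < 12 else "b"
            base = np.zeros(n_feat)
            for p in (20, 80, 120, 160):  # shared bands
                base[p] = 0.5 + rng.uniform(-0.1, 0.1)
            if grp == "a":
                base[50] = effect
            for r in range(2):
                X.append(base + rng.normal(0, 0.02, n_feat))
                y.append(grp)
                sid.append(f"s{i}")
        return np.array(X), np.array(y), np.array(sid)

    def test_planted_band_ranks_first_and_is_consistent(self):
        rng = np.random.default_rng(15)
        X, y, sid = self._planted_cohort(rng)
        res = cross_validate(X, y, sid, max_components=2)
        rf_axis = 0.09 + np.arange(200) * 0.001
        ranking = rank_discriminant_bands(res.models, rf_axis, top_n=1)
        assert ranking.table.iloc[0]["rf"] == pytest.approx(rf_axis[50], abs=0.002)
        assert ranking.consistent

    def test_no_structure_is_not_flagged_consistent(self):
        rng = np.random.default_rng(16)
        X, y, sid = _random_cohort(rng, n_samples=16, n_features=200, separation=0.0)
        res = cross_validate(X, y, sid, max_components=2)
        ranking = rank_discriminant_bands(res.models, 0.09 + np.arange(200) * 0.001,
                                          top_n=4)
        assert not ranking.consistent

    def test_top_n_zero_returns_empty(self):
        rng = np.random.default_rng(17)
        X, y, sid = self._planted_cohort(rng)
        res = cross_validate(X, y, sid, max_components=2)
        ranking = rank_discriminant_bands(res.models, 0.09 + np.arange(200) * 0.001,
                                          top_n=0)
        assert ranking.table.empty
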