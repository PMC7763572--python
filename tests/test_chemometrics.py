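import numpy as np
import pytest
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression

from salimet.chemometrics import (
    MultilevelPLSDA,
    OPLSDAClassifier,
    PLSDAClassifier,
    fit_mpls_paired,
    multilevel_decompose,
    nipals_pls,
    within_between,
)
from salimet.containers import FeatureMatrix, SampleMetadata


class TestMultilevelDecompose:
    def test_identical_pair_gives_zero_within(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        within, between, grand, order = within_between(X, np.array(["s", "s"]))
        np.testing.assert_array_equal(within, 0.0)
        assert order == ["s"]

    def test_hand_example(self):
        X = np.array([[4.0, 0.0], [0.0, 2.0]])
        within, _, _, _ = within_between(X, np.array(["s", "s"]))
        np.testing.assert_allclose(within, [[2.0, -1.0], [-2.0, 1.0]])

    def test_reconstruction_identity(self, tiny_fm_md):
        fm, md = tiny_fm_md
        split = multilevel_decompose(fm, md)
        subj = md.subjects
        rebuilt = np.empty_like(fm.values)
        for i, s in enumerate(fm.sample_ids):
            k = split.subject_order.index(subj[s])
            rebuilt[i] = split.grand_mean + split.X_between[k] + split.X_within[i]
        np.testing.assert_allclose(rebuilt, fm.values, atol=1e-10)

    def test_within_rows_sum_to_zero_per_subject(self, tiny_fm_md):
        fm, md = tiny_fm_md
        split = multilevel_decompose(fm, md)
        subj = md.subjects
        for s in split.subject_order:
            rows = [i for i, sid in enumerate(fm.sample_ids) if subj[sid] == s]
            np.testing.assert_allclose(
                split.X_within[rows].sum(axis=0), 0.0, atol=1e-10
            )

    def test_single_sample_subject_errors(self):
        with pytest.raises(ValueError, match="single sample"):
            within_between(np.ones((3, 2)), np.array(["a", "a", "b"]))


class TestNipals:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(20)
        p = rng.standard_normal(6)
        X = np.outer(t, p)
        fit = nipals_pls(X, t, 1)
        # direction of p recovered up to sign; X fully deflated
        w = fit.P[:, 0]
        cos = abs(w @ p) / (np.linalg.norm(w) * np.linalg.norm(p))
        assert cos == pytest.approx(1.0, abs=1e-8)
        resid = (X - X.mean(0)) - np.outer(fit.T[:, 0], fit.P[:, 0])
        assert np.abs(resid).max() < 1e-8

    def test_score_orthogonality(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 10))
        Y = rng.standard_normal((20, 2))
        fit = nipals_pls(X, Y, 4)
        G = fit.T.T @ fit.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_agrees_with_sklearn_pls_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        for a in (1, 2, 3):
            fit = nipals_pls(X, y, a)
            yhat = (X - fit.x_mean) @ fit.coef + fit.y_mean
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                yhat.ravel(), ref.predict(X).ravel(), atol=1e-6
            )

    def test_too_many_components_errors(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError, match="rank"):
            nipals_pls(X, rng.standard_normal(5), 4)

    def test_deterministic_fit(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        a = nipals_pls(X, y, 2)
        b = nipals_pls(X, y, 2)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.T, b.T)


class TestPLSDAClassifier:
    def separable_toy(self):
        X = np.array([
            [1.0, 0.0, 0.2],
            [1.1, 0.1, 0.1],
            [-1.0, 0.0, -0.2],
            [-0.9, -0.1, -0.1],
        ])
        y = np.array(["pos", "pos", "neg", "neg"])
        return X, y

    def test_separable_toy_classified_perfectly(self):
        X, y = self.separable_toy()
        model = PLSDAClassifier(n_components=1).fit(X, y)
        assert list(model.predict(X)) == list(y)

    def test_boundary_tie_goes_to_first_class(self):
        X, y = self.separable_toy()
        model = PLSDAClassifier(n_components=1, class_order=["pos", "neg"]).fit(X, y)
        mid = np.zeros((1, 3)) + model.x_mean_  # decision exactly 0 at the mean
        assert model.decision_function(mid)[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert model.predict(mid)[0] == "pos"

    def test_feature_count_mismatch_errors(self):
        X, y = self.separable_toy()
        model = PLSDAClassifier(n_components=1).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((1, 5)))

    def test_three_class_dummy_encoding(self):
        rng = np.random.default_rng(5)
        centers = {"a": [4, 0], "b": [0, 4], "c": [-4, -4]}
        X = np.vstack([
            rng.normal(centers[c], 0.3, size=(10, 2)) for c in "abc"
        ])
        y = np.repeat(list("abc"), 10)
        model = PLSDAClassifier(n_components=2).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_sklearn_clone_compatible(self):
        model = PLSDAClassifier(n_components=3, scale=True)
        cl = clone(model)
        assert cl.get_params() == model.get_params()


class TestMultilevelPLSDA:
    def test_constant_shift_is_perfectly_separated(self):
        rng = np.random.default_rng(6)
        n_pairs, p = 6, 4
        base = rng.normal(50, 10, size=(n_pairs, p))
        shift = np.full(p, 3.0)
        X = np.vstack([base + shift, base])  # B rows then AT rows
        y = np.array(["B"] * n_pairs + ["AT"] * n_pairs)
        subjects = np.array([f"s{i}" for i in range(n_pairs)] * 2)
        model = MultilevelPLSDA(n_components=1).fit(X, y, subjects=subjects)
        scores = model.transform(X, subjects=subjects)[:, 0]
        assert np.all(scores[:n_pairs] * scores[n_pairs:] < 0)
        assert (model.predict(X, subjects=subjects) == y).all()

    def test_swapping_b_and_at_negates_scores(self):
        rng = np.random.default_rng(7)
        n_pairs, p = 5, 3
        Xb = rng.normal(10, 2, (n_pairs, p))
        Xat = rng.normal(8, 2, (n_pairs, p))
        subjects = np.array([f"s{i}" for i in range(n_pairs)] * 2)
        y = np.array(["B"] * n_pairs + ["AT"] * n_pairs)
        y_swapped = np.array(["AT"] * n_pairs + ["B"] * n_pairs)
        X = np.vstack([Xb, Xat])
        m1 = MultilevelPLSDA(1).fit(X, y, subjects=subjects)
        m2 = MultilevelPLSDA(1).fit(X, y_swapped, subjects=subjects)
        # scores are sign-fixed by the weight convention; the class encoding
        # flips, so the decision values negate and predictions swap
        np.testing.assert_allclose(
            m1.decision_function(X, subjects=subjects),
            -m2.decision_function(X, subjects=subjects),
            atol=1e-8,
        )
        assert (m1.predict(X, subjects=subjects)
                != m2.predict(X, subjects=subjects)).all()

    def test_subject_order_permutation_leaves_scores_unchanged(self, tiny_fm_md):
        fm, md = tiny_fm_md
        perm = [4, 5, 2, 3, 0, 1, 6, 7]  # reorder whole pairs
        fm2 = FeatureMatrix(
            fm.values[perm], [fm.sample_ids[i] for i in perm], fm.feature_ids
        )
        m1 = fit_mpls_paired(fm, md, n_components=1)
        m2 = fit_mpls_paired(fm2, md, n_components=1)
        subj = md.subjects
        subjects = np.asarray([subj[s] for s in fm.sample_ids], dtype=object)
        np.testing.assert_allclose(
            m1.transform(fm.values, subjects=subjects),
            m2.transform(fm.values, subjects=subjects),
            atol=1e-10,
        )

    def test_strong_signal_resubstitution_is_perfect(self, strong_dataset):
        ds = strong_dataset
        model = fit_mpls_paired(ds.features, ds.metadata, 2)
        groups = ds.metadata.group_of(ds.features.sample_ids)
        ids = [s for s, g in zip(ds.features.sample_ids, groups) if g in ("B", "AT")]
        sub = ds.features.subset(ids)
        subj = ds.metadata.subjects
        subjects = np.asarray([subj[s] for s in ids], dtype=object)
        pred = model.predict(sub.values, subjects=subjects)
        assert (pred == ds.metadata.group_of(ids)).all()

    def test_missing_subjects_argument_errors(self):
        with pytest.raises(ValueError, match="subjects"):
            MultilevelPLSDA(1).fit(np.ones((4, 2)), ["B", "B", "AT", "AT"])


class TestOPLSDA:
    def test_zero_orthogonal_reduces_to_plsda(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((24, 8))
        y = np.array(["A"] * 12 + ["B"] * 12)
        o = OPLSDAClassifier(2, 0).fit(X, y)
        p = PLSDAClassifier(2).fit(X, y)
        np.testing.assert_allclose(o.x_scores_, p.x_scores_, atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_classes(self, strong_dataset):
        ds = strong_dataset
        groups = ds.metadata.group_of(ds.features.sample_ids)
        model = OPLSDAClassifier(2, 1, class_order=["B", "AT", "HI"]).fit(
            ds.features.values, groups
        )
        for g in ("B", "AT", "HI"):
            enc = (groups == g).astype(float)
            r = np.corrcoef(model.orth_scores_[:, 0], enc)[0, 1]
            assert abs(r) < 1e-8

    def test_nuisance_direction_captured_in_orthogonal_loadings(self):
        rng = np.random.default_rng(9)
        n, p = 24, 8
        y = np.array(["A"] * 12 + ["B"] * 12)
        yenc = np.where(y == "A", 1.0, -1.0)
        t_sig = yenc + 0.05 * rng.standard_normal(n)
        t_nui = 4 * rng.standard_normal(n)
        t_nui -= t_nui.mean()
        t_nui -= (t_nui @ yenc) / (yenc @ yenc) * yenc
        p_sig = np.eye(p)[0]
        p_nui = np.eye(p)[1]
        X = np.outer(t_sig, p_sig) + np.outer(t_nui, p_nui) \
            + 0.01 * rng.standard_normal((n, p))
        model = OPLSDAClassifier(1, 1).fit(X, y)
        load = np.abs(model.orth_loadings_[:, 0])
        assert load[1] == pytest.approx(1.0, abs=0.01)  # nuisance direction
        assert abs(np.corrcoef(model.x_scores_[:, 0], yenc)[0, 1]) > 0.99

    def test_predictive_variance_nonincreasing_in_orthogonal_count(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((24, 8))
        y = np.array(["A"] * 12 + ["B"] * 12)
        variances = [
            OPLSDAClassifier(1, k).fit(X, y).x_scores_.var() for k in range(4)
        ]
        assert np.all(np.diff(variances) <= 1e-10)

    def test_predictions_invariant_to_added_orthogonal_component(self):
        rng = np.random.default_rng(11)
        n, p = 24, 8
        y = np.array(["A"] * 12 + ["B"] * 12)
        yenc = np.where(y == "A", 1.0, -1.0)
        t_sig = yenc + 0.1 * rng.standard_normal(n)
        t_sig -= t_sig.mean()
        raw = t_sig + rng.standard_normal(n)
        raw -= raw.mean()
        t_orth = raw - (raw @ yenc) / (yenc @ yenc) * yenc
        X1 = np.outer(t_sig, np.eye(p)[0])
        X2 = X1 + 3.0 * np.outer(t_orth, np.eye(p)[1])
        m1 = OPLSDAClassifier(1, 0).fit(X1, y)
        m2 = OPLSDAClassifier(1, 1).fit(X2, y)
        assert (m1.predict(X1) == m2.predict(X2)).all()
        np.testing.assert_allclose(
            m1.decision_function(X1), m2.decision_function(X2), atol=0.05
        )

    def test_rank_budget_exceeded_errors(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((6, 4))
        y = np.array(["A", "A", "A", "B", "B", "B"])
        with pytest.raises(ValueError, match="rank"):
            OPLSDAClassifier(3, 2).fit(X, y)

    def test_held_out_accuracy_on_strong_signal(self, strong_dataset):
        from salimet.validation import CVConfig, monte_carlo_cv

        ds = strong_dataset
        res = monte_carlo_cv(
            ds.features, ds.metadata,
            OPLSDAClassifier(2, 1, class_order=["B", "AT", "HI"]),
            CVConfig(n_runs=30, seed=3),
        )
        assert res.mean_accuracy > 0.75
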