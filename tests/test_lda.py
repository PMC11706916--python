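import numpy as np
import pandas as pd
import pytest

from cropsift.lda import (
    LdaModel,
    SingularCovarianceWarning,
    fit_lda,
    posterior,
    predict_class,
    project,
)


def make_groups(rng, G=4, p=6, n_per=12, spread=8.0):
    """Random well-conditioned grouped data with separated means."""
    means = rng.normal(0, spread, size=(G, p))
    X = np.vstack([rng.normal(means[g], 1.0, size=(n_per, p)) for g in range(G)])
    groups = np.repeat(np.arange(1, G + 1), n_per)
    return pd.DataFrame(X, columns=[f"v{j}" for j in range(p)]), groups


def full_dimensional_posterior_oracle(model: LdaModel, X) -> np.ndarray:
    """Shared-covariance Gaussian density evaluated in the original
    p-dimensional space — independent of the discriminant-space shortcut."""
    arr = np.asarray(X, dtype=float)
    Winv = np.linalg.inv(model.pooled_cov)
    logdens = np.empty((arr.shape[0], model.n_groups))
    for k in range(model.n_groups):
        d = arr - model.means[k]
        logdens[:, k] = np.log(model.priors[k]) - 0.5 * np.einsum(
            "ij,jk,ik->i", d, Winv, d
        )
    logdens -= logdens.max(axis=1, keepdims=True)
    dens = np.exp(logdens)
    return dens / dens.sum(axis=1, keepdims=True)


class TestFit:
    def test_two_groups_1d_separated(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 0.01, 20), rng.normal(10, 0.01, 20)])
        groups = [1] * 20 + [2] * 20
        model = fit_lda(X.reshape(-1, 1), groups)
        assert model.n_functions == 1
        assert (predict_class(model, X.reshape(-1, 1)).to_numpy()
                == np.array(groups)).all()

    @pytest.mark.parametrize("G,p,m", [(4, 6, 3), (5, 6, 4), (3, 2, 2), (7, 2, 2)])
    def test_function_count(self, G, p, m):
        rng = np.random.default_rng(1)
        X, groups = make_groups(rng, G=G, p=p)
        model = fit_lda(X, groups)
        assert model.n_functions == min(G - 1, p) == m

    def test_projected_within_group_cov_is_identity(self):
        rng = np.random.default_rng(2)
        X, groups = make_groups(rng, G=4, p=6, n_per=40)
        model = fit_lda(X, groups)
        Z = project(model, X).to_numpy()
        pooled = np.zeros((model.n_functions, model.n_functions))
        for g in np.unique(groups):
            zg = Z[groups == g]
            zg = zg - zg.mean(axis=0)
            pooled += zg.T @ zg
        pooled /= len(X) - 4
        np.testing.assert_allclose(pooled, np.eye(model.n_functions), atol=1e-8)

    def test_group_with_one_member_rejected(self):
        X = np.arange(6).reshape(3, 2)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(X, [1, 1, 2])

    def test_single_group_rejected(self):
        X = np.arange(8).reshape(4, 2)
        with pytest.raises(ValueError, match="two groups"):
            fit_lda(X, [1, 1, 1, 1])

    def test_priors_options(self):
        rng = np.random.default_rng(3)
        X, groups = make_groups(rng, G=3, p=4, n_per=10)
        prop = fit_lda(X, groups, priors="proportional")
        np.testing.assert_allclose(prop.priors, [1 / 3] * 3)
        uni = fit_lda(X, groups, priors="uniform")
        np.testing.assert_allclose(uni.priors, [1 / 3] * 3)
        expl = fit_lda(X, groups, priors=[0.5, 0.25, 0.25])
        np.testing.assert_allclose(expl.priors, [0.5, 0.25, 0.25])
        with pytest.raises(ValueError):
            fit_lda(X, groups, priors="bogus")

    def test_singular_covariance_ridge_warns_and_classifies(self):
        rng = np.random.default_rng(4)
        X, groups = make_groups(rng, G=3, p=3, n_per=10)
        X["zero"] = 0.0  # constant column -> singular pooled covariance
        with pytest.warns(SingularCovarianceWarning):
            model = fit_lda(X, groups)
        base = fit_lda(X.drop(columns="zero"), groups)
        assert (
            predict_class(model, X).to_numpy()
            == predict_class(base, X.drop(columns="zero")).to_numpy()
        ).all()

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        X, groups = make_groups(rng)
        model = fit_lda(X, groups)
        for j in range(model.n_functions):
            col = model.scalings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestProject:
    def test_grand_mean_projects_to_zero(self):
        rng = np.random.default_rng(6)
        X, groups = make_groups(rng)
        model = fit_lda(X, groups)
        z = project(model, model.xbar.reshape(1, -1)).to_numpy()
        np.testing.assert_allclose(z, 0.0, atol=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X, groups = make_groups(rng)
        model = fit_lda(X, groups)
        mean1 = model.means[[1]]
        np.testing.assert_array_equal(
            project(model, mean1).to_numpy(), project(model, mean1).to_numpy()
        )

    def test_hand_computed_2x2(self):
        model = LdaModel(
            group_labels=[1, 2],
            priors=np.array([0.5, 0.5]),
            means=np.array([[0.0, 0.0], [2.0, 2.0]]),
            pooled_cov=np.eye(2),
            scalings=np.array([[1.0], [2.0]]),
            xbar=np.array([1.0, 1.0]),
            training_sizes=np.array([2, 2]),
            feature_names=["a", "b"],
        )
        X = pd.DataFrame([[3.0, 5.0]], columns=["a", "b"])
        # (3-1)*1 + (5-1)*2 = 10
        assert project(model, X).iloc[0, 0] == pytest.approx(10.0)

    def test_column_mismatch_names_columns(self):
        rng = np.random.default_rng(8)
        X, groups = make_groups(rng, p=3)
        model = fit_lda(X, groups)
        bad = X.rename(columns={"v0": "other"})
        with pytest.raises(ValueError, match="v0"):
            project(model, bad)


class TestPosterior:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        X, groups = make_groups(rng)
        model = fit_lda(X, groups)
        post = posterior(model, X).to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_group_mean_has_top_posterior(self):
        rng = np.random.default_rng(10)
        X, groups = make_groups(rng, spread=12.0)
        model = fit_lda(X, groups, priors="uniform")
        post = posterior(model, model.means).to_numpy()
        assert (np.argmax(post, axis=1) == np.arange(model.n_groups)).all()

    def test_shortcut_matches_full_dimensional_oracle(self):
        rng = np.random.default_rng(11)
        X, groups = make_groups(rng, G=3, p=5, n_per=15, spread=3.0)
        model = fit_lda(X, groups)
        test = pd.DataFrame(
            rng.normal(0, 4, size=(25, 5)), columns=X.columns
        )
        post = posterior(model, test).to_numpy()
        oracle = full_dimensional_posterior_oracle(model, test)
        np.testing.assert_allclose(post, oracle, atol=1e-10)

    def test_non_finite_input_rejected(self):
        rng = np.random.default_rng(12)
        X, groups = make_groups(rng, p=2)
        model = fit_lda(X, groups)
        bad = X.iloc[:2].copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            posterior(model, bad)


class TestPredict:
    def test_exact_tie_goes_to_lowest_label(self):
        model = LdaModel(
            group_labels=[1, 3],
            priors=np.array([0.5, 0.5]),
            means=np.array([[0.0], [2.0]]),
            pooled_cov=np.eye(1),
            scalings=np.eye(1),
            xbar=np.array([1.0]),
            training_sizes=np.array([2, 2]),
            feature_names=["a"],
        )
        # x = 1.0 is equidistant from both means
        assert predict_class(model, np.array([[1.0]])).iloc[0] == 1

    def test_resubstitution_perfect_on_separated_groups(self):
        rng = np.random.default_rng(13)
        X, groups = make_groups(rng, spread=15.0)
        model = fit_lda(X, groups)
        assert (predict_class(model, X).to_numpy() == groups).all()

    def test_agreement_with_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(14)
        X, groups = make_groups(rng, G=4, p=6, n_per=20, spread=2.0)
        model = fit_lda(X, groups)
        sk = LinearDiscriminantAnalysis(solver="svd").fit(X, groups)
        test = pd.DataFrame(rng.normal(0, 3, size=(60, 6)), columns=X.columns)
        np.testing.assert_array_equal(
            predict_class(model, test).to_numpy(), sk.predict(test)
        )
        np.testing.assert_allclose(
            posterior(model, test).to_numpy(), sk.predict_proba(test), atol=1e-8
        )


class TestInvariances:
    def test_sign_flip_changes_nothing(self):
        rng = np.random.default_rng(15)
        X, groups = make_groups(rng)
        model = fit_lda(X, groups)
        flipped = LdaModel(
            **{
                **model.__dict__,
                "scalings": model.scalings * np.array([-1, 1, -1]),
            }
        )
        np.testing.assert_allclose(
            posterior(model, X).to_numpy(),
            posterior(flipped, X).to_numpy(),
            atol=1e-12,
        )
        assert (
            predict_class(model, X).to_numpy()
            == predict_class(flipped, X).to_numpy()
        ).all()

    def test_affine_shift_of_a_column(self):
        rng = np.random.default_rng(16)
        X, groups = make_groups(rng)
        test = pd.DataFrame(rng.normal(0, 5, size=(30, 6)), columns=X.columns)
        base = predict_class(fit_lda(X, groups), test)
        shifted_train = X.copy()
        shifted_train["v2"] += 100.0
        shifted_test = test.copy()
        shifted_test["v2"] += 100.0
        shifted = predict_class(fit_lda(shifted_train, groups), shifted_test)
        assert (base.to_numpy() == shifted.to_numpy()).all()

    def test_duplicating_training_set_preserves_predictions(self):
        # With the unbiased pooled divisor (n - G), duplication rescales the
        # covariance by 2(n-G)/(2n-G), so posteriors are only asymptotically
        # unchanged; classifications are stable and posteriors converge.
        rng = np.random.default_rng(17)
        X, groups = make_groups(rng, n_per=150)
        test = pd.DataFrame(rng.normal(0, 5, size=(10, 6)), columns=X.columns)
        base_model = fit_lda(X, groups)
        doubled = fit_lda(
            pd.concat([X, X], ignore_index=True), np.concatenate([groups, groups])
        )
        assert (
            predict_class(base_model, test).to_numpy()
            == predict_class(doubled, test).to_numpy()
        ).all()
        np.testing.assert_allclose(
            posterior(base_model, test).to_numpy(),
            posterior(doubled, test).to_numpy(),
            atol=5e-3,
        )
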