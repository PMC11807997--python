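import numpy as np
import pytest

from uromet.latent import (
    autoscale, encode_binary, fit_oplsda, fit_plsda, permutation_test,
    q2_cross_validate, vip_scores,
)


def _separable(n=30, p=12, delta=3.0, seed=0, sd=1.0):
    """Two well-separated groups on the raw-intensity scale."""
    rng = np.random.default_rng(seed)
    labels = np.array(["CN"] * (n // 2) + ["AD"] * (n - n // 2))
    X = np.exp(rng.normal(13.0, 0.4, size=(n, p)))
    shift = np.exp(rng.normal(0, sd, size=p // 3) + delta)
    X[labels == "AD", : p // 3] *= shift
    return X, labels


class TestAutoscale:
    def test_unit_variance_scaling_matches_hand_computation(self):
        out = autoscale(np.array([[1.0], [2.0], [3.0]]), log_transform=False)
        assert np.allclose(out.values[:, 0], [-1.0, 0.0, 1.0])  # sample sd = 1
        assert out.scale[0] == 1.0 and out.center[0] == 2.0

    def test_constant_feature_flagged_not_poisoned(self):
        out = autoscale(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]),
                        log_transform=False)
        assert out.constant_features.tolist() == [True, False]
        assert np.allclose(out.values[:, 0], 0.0)
        assert out.scale[0] == 1.0

    def test_round_trip_recovers_input(self):
        rng = np.random.default_rng(1)
        raw = np.exp(rng.normal(10, 1, size=(8, 5)))
        out = autoscale(raw, log_transform=True)
        assert np.allclose(out.inverse(), np.log10(raw + 1e-9))
        assert np.allclose(out.apply_to(raw), out.values)

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            autoscale(np.array([[1.0, np.nan]]))


class TestPLSDA:
    def test_single_predictive_column_gives_r2y_one(self):
        y = np.array(["CN"] * 10 + ["AD"] * 10)
        x = (y == "AD").astype(float).reshape(-1, 1)
        model = fit_plsda(autoscale(x, log_transform=False), y, 1)
        assert model.r2y[-1] == pytest.approx(1.0)

    def test_r2_cumulative_and_bounded(self):
        X, labels = _separable(n=40, p=10, seed=3)
        model = fit_plsda(autoscale(np.log10(X)), labels, 3)
        assert np.all(np.diff(model.r2x) >= -1e-12)
        assert np.all(np.diff(model.r2y) >= -1e-12)
        assert np.all((model.r2x >= 0) & (model.r2x <= 1))
        assert np.all(np.isclose(np.linalg.norm(model.weights, axis=0), 1.0))

    def test_components_beyond_rank_rejected(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # rank 1 centred
        y = np.array(["CN", "AD", "AD"])
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(autoscale(x, log_transform=False), y, 2)

    def test_three_class_response_and_group_separation(self, clean):
        table = clean["tables"]["negative"]
        meta = clean["metadata"]
        X = autoscale(table.data.T, log_transform=True)
        labels = meta.groups.loc[table.sample_ids].to_numpy()
        model = fit_plsda(X, labels, 2)
        assert model.y_loadings.shape[0] == 3
        # planted effects must pull the group centroids apart in score space
        centroids = {g: model.scores[labels == g].mean(axis=0)
                     for g in ("CN", "MCI", "AD")}
        for a, b in (("CN", "MCI"), ("CN", "AD"), ("MCI", "AD")):
            assert np.linalg.norm(centroids[a] - centroids[b]) > 1.0


class TestOPLSDA:
    def test_no_orthogonal_filtering_reduces_to_pls_first_component(self):
        X, labels = _separable(n=36, p=15, seed=4)
        Xs = autoscale(np.log10(X))
        opls = fit_oplsda(Xs, labels, n_ortho=0, case_group="AD")
        pls = fit_plsda(Xs, labels, 1)
        t_pls = pls.scores[:, 0]
        if np.sign(t_pls @ opls.t_pred) < 0:
            t_pls = -t_pls
        assert np.max(np.abs(t_pls - opls.t_pred)) < 1e-8

    def test_predictive_and_orthogonal_scores_uncorrelated(self, screens):
        for screen in screens.values():
            for model in screen.models.values():
                for comp in model.orthogonal:
                    denom = np.linalg.norm(model.t_pred) * np.linalg.norm(comp["t"])
                    assert abs(model.t_pred @ comp["t"]) / denom < 1e-8

    def test_constructed_orthogonal_variation_absorbed(self):
        """Features carry the response plus a structured nuisance signal z
        orthogonal to y: one orthogonal component absorbs z and the
        predictive scores align exactly with y."""
        rng = np.random.default_rng(5)
        n = 40
        labels = np.array(["CN"] * 20 + ["AD"] * 20)
        y_c, _ = encode_binary(labels, "AD")
        z = rng.normal(size=n)
        z -= z @ y_c / (y_c @ y_c) * y_c  # exactly orthogonal to y
        X = np.column_stack([y_c, y_c + z])
        Xs = autoscale(X, log_transform=False)
        model = fit_oplsda(Xs, labels, n_ortho=1, case_group="AD")
        corr = np.corrcoef(model.t_pred, y_c)[0, 1]
        assert corr > 1 - 1e-8
        assert model.r2y > 1 - 1e-8
        # the orthogonal scores carry the nuisance signal
        t_o = model.orthogonal[0]["t"]
        assert abs(np.corrcoef(t_o, z)[0, 1]) > 1 - 1e-6

    def test_strong_effect_regime_r2y_and_q2(self, screens, clean):
        """On the planted-effect cohort the fitted models reach the strong
        separation regime: R2Y above 0.9 and cross-validated Q2 above 0.7,
        with Q2 never exceeding R2Y."""
        for screen in screens.values():
            for model in screen.models.values():
                assert model.r2y > 0.9
                assert model.q2 > 0.7
                assert model.q2 <= model.r2y

    def test_case_group_scores_positive(self, screens):
        for name, screen in screens.items():
            case = name.split("-")[1]
            for model in screen.models.values():
                enc = model.class_encoding
                assert enc["case"] == case

    def test_constant_labels_rejected(self):
        X = autoscale(np.random.default_rng(0).normal(size=(10, 3)),
                      log_transform=False)
        with pytest.raises(ValueError):
            fit_oplsda(X, np.array(["CN"] * 10), 1)


class TestVIP:
    def test_closed_form_on_single_informative_feature(self):
        """Only feature 0 covaries with the response, so w -> (1, 0) and
        VIP -> (sqrt(2), 0)."""
        labels = np.array(["CN"] * 12 + ["AD"] * 12)
        y_c, _ = encode_binary(labels, "AD")
        X = np.column_stack([y_c, np.zeros(24)])
        X[:, 1] = np.tile([1e-9, -1e-9], 12)  # non-constant but y-orthogonal
        model = fit_oplsda(autoscale(X, log_transform=False), labels,
                           n_ortho=0, case_group="AD")
        vip = vip_scores(model)
        assert vip[0] == pytest.approx(np.sqrt(2), abs=1e-6)
        assert vip[1] == pytest.approx(0.0, abs=1e-6)

    def test_mean_square_vip_is_one_on_every_fit(self, screens):
        for screen in screens.values():
            for model in screen.models.values():
                assert np.mean(model.vip ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_equal_weights_give_unit_vip(self):
        labels = np.array(["CN"] * 8 + ["AD"] * 8)
        y_c, _ = encode_binary(labels, "AD")
        X = np.column_stack([y_c, y_c, y_c])
        model = fit_oplsda(autoscale(X, log_transform=False), labels,
                           n_ortho=0, case_group="AD")
        assert np.allclose(model.vip, 1.0)


class TestQ2:
    def test_separable_data_scores_high(self):
        X, labels = _separable(n=60, p=20, delta=3.0, seed=6)
        q2 = q2_cross_validate(X, labels, n_ortho=1, folds=7, seed=1)
        assert q2 > 0.9

    def test_permuted_labels_score_at_or_below_zero_on_average(self):
        rng = np.random.default_rng(7)
        X = np.exp(rng.normal(13, 0.4, size=(40, 15)))
        labels = np.array(["CN"] * 20 + ["AD"] * 20)
        q2s = [q2_cross_validate(X, rng.permutation(labels), n_ortho=1,
                                 folds=5, seed=i) for i in range(50)]
        assert np.mean(q2s) <= 0.0

    def test_class_smaller_than_fold_count_rejected(self):
        X, labels = _separable(n=10, p=5)
        with pytest.raises(ValueError, match="fold"):
            q2_cross_validate(X, labels, folds=7)


class TestPermutationTest:
    def test_separable_data_attains_minimum_p(self):
        """No permutation can beat the observed fit, so p = 1/(n_perm+1)."""
        X, labels = _separable(n=28, p=10, delta=4.0, seed=8)
        res = permutation_test(X, labels, n_ortho=1, n_perm=200, seed=3,
                               folds=5, case_group="AD")
        assert res.p_q2 == pytest.approx(1 / 201)
        assert res.p_r2 <= 5 / 201  # ties in R2Y are possible but rare

    def test_p_values_bounded(self):
        rng = np.random.default_rng(9)
        X = np.exp(rng.normal(13, 0.4, size=(24, 8)))
        labels = np.array(["CN"] * 12 + ["AD"] * 12)
        res = permutation_test(X, labels, n_ortho=1, n_perm=49, seed=4, folds=4)
        for p in (res.p_r2, res.p_q2):
            assert 1 / 50 <= p <= 1.0
        assert len(res.null_q2) == 49

    def test_zero_permutations_rejected(self):
        X, labels = _separable()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(X, labels, n_perm=0)
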