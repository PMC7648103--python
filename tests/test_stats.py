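"""Transforms, univariate tests, PLS-DA/VIP, O-PLS-DA, LOO-CV, PCA, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pulsedims import stats as st


def _df(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols if cols is not None else [f"f{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestGlog:
    def test_lambda_zero_is_log2(self):
        X = _df([[1.0, 4.0], [16.0, 2.0]])
        out = st.glog_transform(X, lam=0.0)
        np.testing.assert_allclose(out.values.to_numpy(), np.log2(X.to_numpy()))

    def test_x_equal_lambda_identity(self):
        lam = 3.7
        X = _df([[lam], [lam]])
        out = st.glog_transform(X, lam=lam)
        expected = math.log2(lam * (1 + math.sqrt(2)) / 2)
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_monotone(self):
        x = np.linspace(0.01, 100, 500).reshape(-1, 1)
        out = st.glog_transform(_df(x), lam="auto").values.to_numpy().ravel()
        assert np.all(np.diff(out) > 0)

    def test_auto_lambda_is_min_positive(self):
        X = _df([[0.5, 10.0], [2.0, 7.0]])
        assert st.glog_transform(X).glog_lambda == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            st.glog_transform(_df([[1.0], [0.0]]))


class TestAutoscale:
    def test_two_point_closed_form(self):
        out = st.autoscale(_df([[1.0], [3.0]])).values.to_numpy().ravel()
        np.testing.assert_allclose(out, [-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_column_moments(self):
        rng = np.random.default_rng(0)
        X = _df(rng.lognormal(0, 1, (20, 5)))
        out = st.autoscale(X).values.to_numpy()
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = _df(rng.normal(0, 1, (10, 4)))
        once = st.autoscale(X).values
        twice = st.autoscale(once).values
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.autoscale(_df([[1.0, 2.0], [1.0, 3.0]]))


class TestWelch:
    def test_identical_groups_p_one(self):
        assert st.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_huge_shift_tiny_p(self):
        a = [1.0, 2.0, 3.0]
        b = [101.0, 102.0, 103.0]
        assert st.welch_t_test(a, b) < 1e-3

    def test_closed_form_two_point_groups(self):
        """Hand-computed Welch on A=[1,2], B=[3,4]: |t| = 2*sqrt(2), df = 2.

        For df = 2 the t CDF has the closed form
        F(t) = 1/2 + t / (2*sqrt(2)*sqrt(1 + t^2/2)), giving p = 0.10557.
        """
        t = 2 * math.sqrt(2)
        cdf = 0.5 + t / (2 * math.sqrt(2) * math.sqrt(1 + t * t / 2))
        expected = 2 * (1 - cdf)
        assert st.welch_t_test([1.0, 2.0], [3.0, 4.0]) == pytest.approx(expected, rel=1e-10)

    def test_rank_agreement_with_permutation_test(self):
        """Welch p-values order instances like an exact permutation test."""
        rng = np.random.default_rng(2)
        welch_ps, perm_ps = [], []
        for _ in range(30):
            a = rng.normal(0, 1, 4)
            b = rng.normal(rng.uniform(0, 2), 1, 4)
            welch_ps.append(st.welch_t_test(a, b))
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = 0
            combos = list(itertools.combinations(range(8), 4))
            for idx in combos:
                mask = np.zeros(8, bool)
                mask[list(idx)] = True
                count += abs(pooled[mask].mean() - pooled[~mask].mean()) >= obs - 1e-12
            perm_ps.append(count / len(combos))
        from scipy.stats import spearmanr

        rho = spearmanr(welch_ps, perm_ps).statistic
        assert rho > 0.9


class TestFoldChangeVolcano:
    def test_simple_ratios(self):
        X = _df([[10.0], [10.0], [5.0], [5.0]])
        fc = st.fold_change(X, [2, 3], [0, 1])
        assert fc.iloc[0] == 2.0
        assert st.fold_change(X, [0, 1], [0, 1]).iloc[0] == 1.0

    def test_zero_group1_mean_rejected(self):
        X = _df([[0.0], [0.0], [1.0], [1.0]])
        with pytest.raises(ValueError):
            st.fold_change(X, [0, 1], [2, 3])

    def test_planted_fc_recovered_monte_carlo(self):
        """5x planted effect, 10% CV, n=10/group: estimate within [4, 6]."""
        rng = np.random.default_rng(3)
        n_feat = 200
        base = rng.lognormal(3, 0.5, n_feat)
        g1 = base * rng.lognormal(0, 0.0998, (10, n_feat))
        g2 = 5.0 * base * rng.lognormal(0, 0.0998, (10, n_feat))
        X = _df(np.vstack([g1, g2]))
        fc = st.fold_change(X, list(range(10)), list(range(10, 20)))
        assert (fc.between(4, 6)).mean() >= 0.95

    @pytest.mark.parametrize(
        "p,fc,expected",
        [(0.04, 3.0, True), (0.04, 1.5, False), (0.05, 3.0, False),
         (0.04, 2.0, False), (0.04, 0.4, True), (0.04, 0.5, False)],
    )
    def test_volcano_strict_boundaries(self, p, fc, expected):
        tab = pd.DataFrame({"fc": [fc], "p_value": [p], "passes": [False]}, index=["f"])
        res = st.VolcanoResult(tab, 0.05, 2.0, 0.5)
        assert (["f"] == st.volcano_select(res)) is expected


def _separable(n=10, p=20, shift=4.0, seed=0):
    """Two shifted Gaussian clusters over the first 5 features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n, p))
    X[n:, :5] += shift
    y = ["u"] * n + ["s"] * n
    return _df(X), y


class TestPlsda:
    def test_component1_separates_separable_classes(self):
        X, y = _separable()
        Xs = st.autoscale(X).values
        model = st.plsda_fit(Xs, y, 2)
        t1 = model.scores[:, 0]
        assert max(t1[:10]) < min(t1[10:]) or min(t1[:10]) > max(t1[10:])

    def test_scores_orthogonal(self):
        X, y = _separable(seed=1)
        model = st.plsda_fit(st.autoscale(X).values, y, 3)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_null_data_explains_little_y_variance(self):
        rng = np.random.default_rng(4)
        X = _df(rng.normal(0, 1, (30, 10)))
        y = ["a"] * 15 + ["b"] * 15
        model = st.plsda_fit(st.autoscale(X).values, y, 2)
        yc = np.where(np.array(y) == "b", 1.0, -1.0)
        ssy = (model.y_loadings**2 * (model.scores**2).sum(axis=0)).sum()
        assert ssy / (yc**2).sum() < 0.5

    def test_matches_sklearn_pls1(self):
        """Independent cross-check: NIPALS PLS1 equals sklearn PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _separable(seed=5)
        Xs = st.autoscale(X).values.to_numpy()
        yc = np.where(np.array(y) == "s", 1.0, -1.0)
        ours = st.plsda_fit(_df(Xs), y, 2, classes=("u", "s"))
        ref = PLSRegression(n_components=2, scale=False).fit(Xs, yc)
        for a in range(2):
            ours_t, ref_t = ours.scores[:, a], ref.x_scores_[:, a]
            sign = np.sign(ours_t @ ref_t)
            np.testing.assert_allclose(ours_t, sign * ref_t, atol=1e-8)
        # predicted y agrees
        np.testing.assert_allclose(
            ours.predict_value(Xs), ref.predict(Xs).ravel() + 0.0, atol=1e-8
        )

    def test_deterministic(self):
        X, y = _separable(seed=6)
        Xs = st.autoscale(X).values
        a = st.plsda_fit(Xs, y, 2)
        b = st.plsda_fit(Xs, y, 2)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestVip:
    def test_mean_square_is_one(self):
        X, y = _separable(seed=7)
        model = st.plsda_fit(st.autoscale(X).values, y, 2)
        vip = st.vip_scores(model)
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (20, 10))
        y = np.array(["a"] * 10 + ["b"] * 10)
        X[:, 3] = np.where(y == "b", 3.0, -3.0) + rng.normal(0, 0.1, 20)
        model = st.plsda_fit(st.autoscale(_df(X)).values, y, 2)
        vip = st.vip_scores(model)
        assert vip.idxmax() == "f3"

    def test_equal_weights_single_component_all_one(self):
        # y perfectly aligned with every feature equally -> w uniform -> VIP = 1
        n = 10
        y = ["a"] * n + ["b"] * n
        base = np.where(np.array(y) == "b", 1.0, -1.0)
        X = _df(np.outer(base, np.ones(4)) + 0.0)
        model = st.plsda_fit(X, y, 1)
        vip = st.vip_scores(model)
        np.testing.assert_allclose(vip.to_numpy(), 1.0, atol=1e-10)

    def test_selection_boundary_strict(self):
        vip = pd.Series({"a": 1.8, "b": 1.81})
        assert st.select_significant(["a", "b"], vip, 1.8) == ["b"]

    def test_empty_volcano_empty_selection(self):
        assert st.select_significant([], pd.Series({"a": 5.0}), 1.8) == []


class TestOplsda:
    def test_equals_pls_without_orthogonal_structure(self):
        """Rank-1 class-aligned X has zero y-orthogonal variation."""
        rng = np.random.default_rng(9)
        y = ["a"] * 8 + ["b"] * 8
        yc = np.where(np.array(y) == "b", 1.0, -1.0)
        X = _df(np.outer(yc, rng.normal(0, 1, 12)))
        pls = st.plsda_fit(X, y, 1)
        opls = st.oplsda_fit(X, y, 1)
        np.testing.assert_allclose(
            opls.predictive_scores, pls.scores[:, 0], atol=1e-10
        )
        np.testing.assert_allclose(opls.w_ortho, 0.0, atol=1e-12)

    def test_orthogonal_confounder_removed(self):
        """A y-orthogonal structured component does not move predictive scores."""
        rng = np.random.default_rng(10)
        n, p = 20, 15
        y = ["a"] * 10 + ["b"] * 10
        yc = np.where(np.array(y) == "b", 1.0, -1.0)
        signal = np.outer(yc, rng.normal(0, 1, p))
        noise = rng.normal(0, 0.05, (n, p))
        conf_scores = rng.normal(0, 1, n)
        conf_scores -= conf_scores @ yc / (yc @ yc) * yc  # orthogonalize to y
        confounder = np.outer(conf_scores, rng.normal(0, 1, p))
        clean = st.oplsda_fit(_df(signal + noise), y, 1)
        dirty = st.oplsda_fit(_df(signal + noise + 3 * confounder), y, 1)
        t_c, t_d = clean.predictive_scores, dirty.predictive_scores
        sign = np.sign(t_c @ t_d)
        r = np.corrcoef(t_c, sign * t_d)[0, 1]
        assert r > 0.999

    def test_prediction_tracks_class(self):
        X, y = _separable(seed=11)
        Xs = st.autoscale(X).values
        model = st.oplsda_fit(Xs, y, 1)
        yc = np.where(np.array(y) == "s", 1.0, -1.0)
        yhat = model.predict_value(Xs.to_numpy())
        assert np.corrcoef(yhat, yc)[0, 1] > 0.9


class TestLooCv:
    def test_perfectly_separable_accuracy_one(self):
        X, y = _separable(n=6, shift=6.0, seed=12)
        res = st.loo_cv(X, y)
        assert res.accuracy == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        X, _ = _separable(n=6, shift=6.0, seed=14)
        accs = []
        for _ in range(15):
            y = list(rng.permutation(["u"] * 6 + ["s"] * 6))
            try:
                accs.append(st.loo_cv(X, y).accuracy)
            except ValueError:
                continue
        assert 0.25 <= np.mean(accs) <= 0.75

    def test_refit_count(self):
        X, y = _separable(n=2, shift=6.0, seed=15)
        calls = []

        def fit(Xt, yt):
            calls.append(1)
            return st.oplsda_fit(Xt, yt, 1, classes=("u", "s"))

        st.loo_cv(X, y, fit=fit)
        assert len(calls) == 4

    def test_plsda_and_oplsda_agree_without_orthogonal_structure(self):
        X, y = _separable(n=6, shift=5.0, seed=16)
        pls_res = st.loo_cv(X, y, fit=lambda Xt, yt: st.plsda_fit(Xt, yt, 1, classes=("u", "s")))
        opls_res = st.loo_cv(X, y, fit=lambda Xt, yt: st.oplsda_fit(Xt, yt, 1, classes=("u", "s")))
        pd.testing.assert_series_equal(pls_res.predictions, opls_res.predictions)

    def test_single_class_fold_rejected(self):
        X = _df(np.random.default_rng(17).normal(0, 1, (3, 4)))
        with pytest.raises(ValueError):
            st.loo_cv(X, ["a", "a", "b"])


class TestPca:
    def test_collinear_data_pc1_explains_all(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, 2 * x])
        scores, loadings, var = st.pca(X)
        assert var[0] / var.sum() == pytest.approx(1.0)

    def test_variance_conservation(self):
        rng = np.random.default_rng(18)
        X = rng.normal(0, 2, (15, 6))
        _, _, var = st.pca(X)
        total = X.var(axis=0, ddof=1).sum()
        assert var.sum() == pytest.approx(total, rel=1e-10)

    def test_reconstruction_full_rank(self):
        rng = np.random.default_rng(19)
        X = rng.normal(0, 1, (8, 5))
        scores, loadings, _ = st.pca(X)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings.T, Xc, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(20)
        X = rng.normal(0, 1, (12, 4))
        _, loadings, _ = st.pca(X)
        for a in range(loadings.shape[1]):
            col = loadings[:, a]
            assert col[np.argmax(np.abs(col))] > 0


class TestCorrelations:
    def test_unit_diagonal_symmetric(self):
        rng = np.random.default_rng(21)
        X = _df(rng.normal(0, 1, (10, 4)))
        r = st.pearson_correlation_map(X)
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        assert np.all(np.abs(r.to_numpy()) <= 1 + 1e-12)

    def test_perfect_anticorrelation(self):
        x = np.arange(10, dtype=float)
        X = _df(np.column_stack([x, -x]))
        r = st.pearson_correlation_map(X)
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_anchor_family_recovered(self):
        """Negatively scaled copies + 10% noise keep |r| > 0.8 to the anchor."""
        rng = np.random.default_rng(22)
        anchor = rng.normal(0, 1, 30)
        cols = {"anchor": anchor}
        for j in range(5):
            scale = rng.uniform(0.5, 2.0)
            cols[f"d{j}"] = -scale * anchor + rng.normal(0, 0.1 * scale, 30)
        for j in range(10):
            cols[f"n{j}"] = rng.normal(0, 1, 30)
        X = _df(np.column_stack(list(cols.values())), cols=list(cols))
        r = st.correlation_to_anchor(X, "anchor")
        assert all(abs(r[f"d{j}"]) > 0.8 for j in range(5))
        assert all(r[f"d{j}"] < 0 for j in range(5))

    def test_constant_feature_rejected(self):
        X = _df([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError):
            st.pearson_correlation_map(X)
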