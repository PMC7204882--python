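import itertools

import numpy as np
import pandas as pd
import pytest

from traceorigin.discriminant import (classify, fit_canonical,
                                      loo_crossvalidate, press_q,
                                      stepwise_select, subset_wilks)
from traceorigin.manova import scatter_matrices, wilks_from_scatter

from conftest import three_site_zmatrix


def planted_signal_data(n_per=30, p=8, separation=5.0, seed=0):
    """Only column e1 carries between-group signal; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(3 * n_per, p))
    X[:, 0] += np.repeat([0.0, separation, 2 * separation], n_per)
    labels = np.repeat(["A", "B", "C"], n_per)
    return pd.DataFrame(X, columns=[f"e{j + 1}" for j in range(p)]), labels


class TestStepwiseSelect:
    @pytest.mark.parametrize("criterion", ["wilks", "mahalanobis_closest_pair"])
    def test_recovers_planted_signal_variable(self, criterion):
        df, labels = planted_signal_data()
        trace = stepwise_select(df, labels, criterion=criterion)
        # oracle: exhaustive single-variable Wilks scan
        lams = {c: subset_wilks(df, labels, [c]) for c in df.columns}
        assert min(lams, key=lams.get) == "e1"
        assert "e1" in trace.selected
        assert trace.selected[0] == "e1"

    def test_infinite_entry_threshold_gives_empty_flagged(self):
        df, labels = planted_signal_data()
        trace = stepwise_select(df, labels, f_enter=np.inf, f_remove=1.0)
        assert trace.selected == []
        assert trace.flagged_empty

    def test_greedy_matches_exhaustive_best_subset(self):
        """On a small instance with two orthogonal informative variables the
        greedy path is unique and must coincide with the best same-size
        subset found by exhaustive search."""
        rng = np.random.default_rng(3)
        n_per, p = 25, 5
        X = rng.normal(size=(3 * n_per, p))
        X[:, 0] += np.repeat([0.0, 4.0, 8.0], n_per)   # axis 1
        X[:, 1] += np.repeat([0.0, 4.0, 0.0], n_per)   # axis 2, orthogonal
        labels = np.repeat(["A", "B", "C"], n_per)
        df = pd.DataFrame(X, columns=[f"e{j}" for j in range(p)])
        trace = stepwise_select(df, labels, criterion="wilks")
        size = len(trace.selected)
        best = min(itertools.combinations(df.columns, size),
                   key=lambda cols: subset_wilks(df, labels, list(cols)))
        assert set(trace.selected) == set(best)

    def test_trace_actions_are_consistent(self):
        df, labels = planted_signal_data(seed=2)
        trace = stepwise_select(df, labels)
        in_model: set = set()
        for s in trace.steps:
            if s.action == "enter":
                assert s.element not in in_model
                in_model.add(s.element)
            else:
                in_model.remove(s.element)
        assert in_model == set(trace.selected)


class TestFitCanonical:
    def test_two_groups_one_variable_matches_regression(self):
        """k=2, p=1: rc^2 equals the squared point-biserial correlation
        between the canonical score and the group indicator."""
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 25)])
        labels = np.array(["a"] * 20 + ["b"] * 25)
        fit = fit_canonical(pd.DataFrame({"x": x}), labels)
        assert fit.n_functions == 1
        score = fit.transform(pd.DataFrame({"x": x}))[:, 0]
        r = np.corrcoef(score, (labels == "b").astype(float))[0, 1]
        assert fit.canonical_correlations[0] ** 2 == pytest.approx(r**2, abs=1e-10)

    def test_duplicated_groups_give_zero_eigenvalues(self):
        rng = np.random.default_rng(5)
        block = rng.normal(size=(20, 3))
        X = pd.DataFrame(np.vstack([block, block]), columns=list("xyz"))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        fit = fit_canonical(X, labels)
        assert np.all(np.abs(fit.eigenvalues) < 1e-10)
        assert fit.wilks_lambda == pytest.approx(1.0, abs=1e-8)

    def test_variance_shares_sum_to_one(self):
        df, labels = three_site_zmatrix(2.0, n_per=15, p=5, seed=6)
        fit = fit_canonical(df, labels)
        assert fit.variance_shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_within_score_covariance_is_identity(self):
        df, labels = three_site_zmatrix(3.0, n_per=20, p=5, seed=7)
        fit = fit_canonical(df, labels)
        scores = fit.transform(df)
        W, _ = scatter_matrices(scores, np.asarray(labels))
        cov = W / (len(df) - 3)
        np.testing.assert_allclose(cov, np.eye(fit.n_functions), atol=1e-8)

    def test_wilks_matches_det_ratio(self):
        df, labels = three_site_zmatrix(1.5, n_per=15, p=4, seed=8)
        fit = fit_canonical(df, labels)
        W, B = scatter_matrices(df.to_numpy(), np.asarray(labels))
        assert fit.wilks_lambda == pytest.approx(wilks_from_scatter(W, B), abs=1e-8)


class TestClassify:
    def test_bird_at_centroid_has_zero_distance(self):
        df, labels = three_site_zmatrix(8.0, n_per=15, p=4, seed=9)
        fit = fit_canonical(df, labels)
        # invert the affine map at centroid 0 is not needed: score row equal
        # to a centroid gives D^2 = 0 by definition of the distance
        scores = fit.centroids[1][None, :]
        d2 = ((scores[:, : fit.retained] - fit.centroids[:, : fit.retained])
              ** 2).sum(axis=1)
        assert d2[1] == pytest.approx(0.0, abs=1e-20)

    def test_well_separated_groups_fully_resubstituted(self):
        df, labels = three_site_zmatrix(10.0, n_per=20, p=5, seed=10)
        fit = fit_canonical(df, labels)
        pred, _ = classify(fit, df)
        assert (pred == labels).all()

    def test_matches_sklearn_lda_predictions(self):
        """Independent cross-check: equal-prior LDA with the same training
        data must make the same calls on moderately separated groups."""
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        df, labels = three_site_zmatrix(2.5, n_per=25, p=5, seed=11)
        fit = fit_canonical(df, labels)
        pred, _ = classify(fit, df, n_functions=fit.n_functions)
        lda = sklearn_da.LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        skl = lda.fit(df.to_numpy(), labels).predict(df.to_numpy())
        assert np.mean(pred == skl) > 0.99

    def test_tie_broken_by_site_order(self):
        """A bird exactly equidistant from two centroids goes to the site
        that comes first in library order."""
        from test_assignment import _manual_fit

        fit = _manual_fit([[1.0, 1.0], [-1.0, 1.0], [0.0, 9.0]])
        pred, d2 = classify(fit, np.array([[0.0, 1.0]]))
        assert d2.iloc[0, 0] == d2.iloc[0, 1] == pytest.approx(1.0)
        assert pred[0] == "S0"


class TestLooCrossvalidate:
    def test_perfect_at_large_separation(self):
        df, labels = three_site_zmatrix(10.0, n_per=12, p=5, seed=13)
        rep = loo_crossvalidate(df, labels)
        assert rep.overall_pct_loo == 100.0
        assert rep.confusion_loo.to_numpy().sum() == len(df)

    def test_chance_level_under_permuted_labels(self):
        """k=10 equal groups with permuted labels: accuracy within the 99%
        binomial band around 10%."""
        rng = np.random.default_rng(14)
        n_per, k, p = 20, 10, 5
        X = pd.DataFrame(rng.normal(size=(n_per * k, p)),
                         columns=[f"v{j}" for j in range(p)])
        labels = rng.permutation(np.repeat([f"S{g}" for g in range(k)], n_per))
        rep = loo_crossvalidate(X, labels)
        n = len(X)
        half = 2.576 * np.sqrt(0.1 * 0.9 / n) * 100
        assert abs(rep.overall_pct_loo - 10.0) < half + 1e-9

    def test_row_sums_match_group_sizes(self, default_zmatrix):
        z = default_zmatrix
        labels = z.meta["site"].to_numpy()
        rep = loo_crossvalidate(z.z, labels, selected=list(z.z.columns[:6]))
        sizes = pd.Series(labels).value_counts()
        for site in rep.site_order:
            assert rep.confusion_loo.loc[site].sum() == sizes[site]
        assert rep.overall_pct_loo == pytest.approx(
            100.0 * rep.n_correct_loo / rep.N)


class TestPressQ:
    def test_closed_form_examples(self):
        q, p = press_q(10, 2, 10)
        assert q == pytest.approx(10.0)
        q0, p0 = press_q(100, 4, 25)        # pure chance
        assert q0 == pytest.approx(0.0)
        assert p0 == pytest.approx(1.0)

    def test_study_size_value(self):
        q, p = press_q(105, 10, 83)
        assert q == pytest.approx(556.22, abs=0.005)
        assert p < 1e-100

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            press_q(10, 1, 5)
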