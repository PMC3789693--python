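"""Differential-expression screening, classifiers, LOOCV, and consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgsig import (
    consensus_signature,
    loocv_accuracy,
    multivariate_permutation_test,
    predict,
    random_variance_ttest,
    train_classifier,
)
from cgsig.signatures import CLASSIFIER_METHODS, fit_variance_prior


def _frame(X, genes=None, samples=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    samples = samples or [f"s{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, index=genes, columns=samples)


def _separated_cohort(n_per_class=8, n_genes=30, n_informative=6, delta=3.0, seed=0):
    """Two classes separated by a patterned (up/down) signature so that both
    location-based and correlation-distance classifiers can resolve them."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(0, 1, (n_genes, n))
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class, dtype=object)
    pattern = delta * np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    pattern *= 1 + np.arange(n_informative) / n_informative
    X[:n_informative][:, labels == "B"] += pattern[:, None] / 2
    X[:n_informative][:, labels == "A"] -= pattern[:, None] / 2
    return _frame(X), labels


class TestRandomVarianceTtest:
    def test_plain_t_hand_oracle(self):
        # x = (1,2,3) vs y = (2,3,4): pooled s² = 1, t = −1/√(2/3) = −1.2247
        df = _frame([[1, 2, 3, 2, 3, 4]])
        labels = ["x", "x", "x", "y", "y", "y"]
        res = random_variance_ttest(df, labels, mode="plain")
        assert res["t"].iloc[0] == pytest.approx(-1.2247, abs=1e-4)
        assert res["df"].iloc[0] == 4

    def test_identical_groups_give_t0_p1(self):
        df = _frame([[5.0, 6.0, 5.0, 6.0]])
        res = random_variance_ttest(df, ["a", "a", "b", "b"], mode="plain")
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_degenerate_zero_variance_gene_flagged(self):
        df = _frame([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        res = random_variance_ttest(df, ["a", "a", "b", "b"], mode="plain")
        assert bool(res["degenerate"].iloc[0])
        assert res["p"].iloc[0] == 1.0

    def test_vanishing_prior_weight_recovers_plain_t(self):
        rng = np.random.default_rng(1)
        df = _frame(rng.normal(0, 1, (40, 12)))
        labels = ["a"] * 6 + ["b"] * 6
        plain = random_variance_ttest(df, labels, mode="plain")
        limit = random_variance_ttest(df, labels, prior=(1e-12, 1.0))
        assert np.max(np.abs(plain["t"] - limit["t"])) < 1e-6

    def test_prior_recovery_on_f_distributed_variances(self):
        # variances generated from the model: s² = b·F(d, 2a)
        rng = np.random.default_rng(2)
        a_true, b_true, d = 3.0, 0.5, 10
        s2 = b_true * stats.f.rvs(d, 2 * a_true, size=4000, random_state=rng)
        a_hat, b_hat = fit_variance_prior(s2, d)
        assert a_hat == pytest.approx(a_true, rel=0.25)
        assert b_hat == pytest.approx(b_true, rel=0.15)

    def test_shrinkage_pulls_small_variances_up(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (200, 10))
        X[0] *= 0.01  # one nearly-constant gene
        df = _frame(X)
        labels = ["a"] * 5 + ["b"] * 5
        rv = random_variance_ttest(df, labels)
        plain = random_variance_ttest(df, labels, mode="plain")
        assert abs(rv["t"].iloc[0]) < abs(plain["t"].iloc[0])


class TestMultivariatePermutation:
    def test_exhaustive_2v2_matches_enumeration(self):
        df = _frame([[0.0, 0.1, 2.0, 2.1], [1.0, 0.9, 1.1, 1.0]])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        alpha = 0.05
        global_p, selected, obs = multivariate_permutation_test(
            df, labels, alpha=alpha, mode="plain"
        )
        # oracle: enumerate the 6 balanced relabelings directly
        counts = []
        for combo in itertools.combinations(range(4), 2):
            lab = np.array(["b"] * 4, dtype=object)
            lab[list(combo)] = "a"
            res = random_variance_ttest(df, lab, mode="plain")
            counts.append(int((res["p"] < alpha).sum()))
        expected = np.mean(np.asarray(counts) >= obs)
        assert global_p == pytest.approx(expected)

    def test_sampled_extreme_case_p_is_one_over_bplus1(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 14))
        labels = np.array(["a"] * 7 + ["b"] * 7, dtype=object)
        X[:5, labels == "b"] += 30.0  # five perfectly separating genes
        global_p, selected, obs = multivariate_permutation_test(
            _frame(X), labels, alpha=1e-3, n_perm=99, seed=0, mode="plain",
            exhaustive_limit=10,
        )
        assert "g0" in selected
        assert global_p == pytest.approx(1 / 100)

    def test_null_global_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(40):
            X = rng.normal(0, 1, (30, 12))
            labels = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
            p, _, _ = multivariate_permutation_test(
                _frame(X), labels, alpha=0.05, n_perm=60, seed=rep, mode="plain",
                exhaustive_limit=10,
            )
            pvals.append(p)
        # permutation p-values are super-uniform at worst; KS against uniform
        # should not reject wildly on null data
        stat = stats.kstest(pvals, "uniform").statistic
        assert stat < 0.35


class TestClassifiers:
    def test_ccp_scores_and_threshold_hand_oracle(self):
        df = _frame([[0.0, 1.0, 4.0, 5.0], [0.0, 1.0, 4.0, 5.0]])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        model = train_classifier(df, labels, "ccp", genes=["g0", "g1"], mode="plain")
        res = random_variance_ttest(df, labels, mode="plain")
        w = res["t"].to_numpy()
        scores = w @ df.to_numpy()
        np.testing.assert_allclose(model.params["train_scores"], scores)
        assert model.params["threshold"] == pytest.approx(
            0.5 * (scores[:2].mean() + scores[2:].mean())
        )
        assert list(predict(model, df)) == list(labels)

    @pytest.mark.parametrize("method", CLASSIFIER_METHODS)
    def test_separated_classes_fit_perfectly(self, method):
        df, labels = _separated_cohort(seed=10)
        model = train_classifier(df, labels, method, selection_alpha=1e-3)
        assert list(predict(model, df)) == list(labels)

    def test_single_gene_centroid_reduces_to_threshold(self):
        df = _frame([[0.0, 1.0, 5.0, 6.0]])
        labels = np.array(["lo", "lo", "hi", "hi"], dtype=object)
        model = train_classifier(df, labels, "centroid", genes=["g0"])
        test = _frame([[2.0, 3.5]], samples=["t1", "t2"])
        # centroids at 0.5 and 5.5; midpoint 3.0 is the implied threshold
        assert list(predict(model, test)) == ["lo", "hi"]

    def test_unknown_method_rejected(self):
        df, labels = _separated_cohort()
        with pytest.raises(ValueError, match="unknown method"):
            train_classifier(df, labels, "forest")


class TestLoocv:
    def test_separable_cohort_is_perfect(self):
        df, labels = _separated_cohort(seed=11)
        acc, preds = loocv_accuracy(df, labels, "dlda", selection_alpha=1e-3)
        assert acc == 1.0

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (40, 20))
        labels = np.array(["a", "b"] * 10, dtype=object)
        acc, _ = loocv_accuracy(_frame(X), labels, "dlda", selection_alpha=0.05, mode="plain")
        # binomial 95% band around 0.5 for n = 20
        assert 0.5 - 2 * np.sqrt(0.25 / 20) <= acc <= 0.5 + 2 * np.sqrt(0.25 / 20)

    def test_selection_leak_inflates_accuracy_on_null(self):
        # paired simulation: honest in-loop selection vs selection leaked from
        # the full data, on pure-noise cohorts
        rng = np.random.default_rng(13)
        honest_all, leaked_all = [], []
        for rep in range(8):
            X = rng.normal(0, 1, (150, 16))
            labels = np.array(["a", "b"] * 8, dtype=object)
            df = _frame(X)
            acc_honest, _ = loocv_accuracy(df, labels, "ccp", selection_alpha=0.1, mode="plain")
            # leaked: pick genes once on all samples, then LOOCV only the fit
            res = random_variance_ttest(df, labels, mode="plain")
            panel = list(res["p"].nsmallest(10).index)
            correct = 0
            for k in range(16):
                mask = np.ones(16, dtype=bool)
                mask[k] = False
                model = train_classifier(
                    df.iloc[:, mask], labels[mask], "ccp", genes=panel, mode="plain"
                )
                correct += predict(model, df.iloc[:, [k]])[0] == labels[k]
            honest_all.append(acc_honest)
            leaked_all.append(correct / 16)
        assert np.mean(honest_all) < np.mean(leaked_all)

    def test_predictions_independent_of_sample_order(self):
        df, labels = _separated_cohort(n_per_class=5, seed=14)
        acc1, preds1 = loocv_accuracy(df, labels, "knn3", selection_alpha=0.05)
        order = np.random.default_rng(0).permutation(df.shape[1])
        acc2, preds2 = loocv_accuracy(
            df.iloc[:, order], labels[order], "knn3", selection_alpha=0.05
        )
        assert preds1.sort_index().tolist() == preds2.sort_index().tolist()


class TestConsensus:
    def test_intersection_keeps_first_list_order(self):
        assert consensus_signature([["A", "B", "C"], ["B", "C", "D"]]) == ["B", "C"]

    def test_identical_lists_identity(self):
        assert consensus_signature([["X", "Y"], ["X", "Y"]]) == ["X", "Y"]

    def test_disjoint_lists_warn_and_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert consensus_signature([["A"], ["B"]]) == []
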