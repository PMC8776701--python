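import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ventdose import (
    SplitScheme,
    auc,
    compare_feature_sets,
    correlation_matrix,
    run_experiment,
    stratified_split,
    tune_svm,
    univariate_screen,
    zscore_fit_apply,
)


# ---------------------------------------------------------------------------
# Independent enumeration oracles


def brute_force_auc(scores, labels):
    """Pairwise positive-vs-negative comparison, ties counting 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exact_mannwhitney_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    observed = u_stat(x, y)
    mu = nx * len(y) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(xs, ys) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def exact_wilcoxon_p(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    diffs = [d for d in diffs if d != 0]
    ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
    w_plus = sum(r for d, r in zip(diffs, ranks) if d > 0)
    mu = ranks.sum() / 2.0
    count = total = 0
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_plus - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------


def make_table(n=20, n_pos=6, seed=0, informative=False):
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    x1 = rng.normal(size=n) + (3.0 * labels if informative else 0.0)
    x2 = rng.normal(size=n) + (3.0 * labels if informative else 0.0)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "f1": x1, "f2": x2, "rp": labels,
    })


class TestZscore:
    def test_population_sd_example(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0], "rp": [0, 1, 0]})
        test = pd.DataFrame({"f": [2.0], "rp": [1]})
        xtr, xte, params = zscore_fit_apply(train, test, ["f"])
        assert np.allclose(xtr[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        assert xte[0, 0] == 0.0  # test value equal to the train mean
        assert params["sd"][0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotence_on_standardized_column(self, rng):
        col = rng.normal(size=50)
        col = (col - col.mean()) / col.std()
        train = pd.DataFrame({"f": col, "rp": np.tile([0, 1], 25)})
        xtr, _, _ = zscore_fit_apply(train, train.iloc[:2], ["f"])
        assert np.allclose(xtr[:, 0], col, atol=1e-12)

    def test_constant_feature_dropped_with_warning(self):
        train = pd.DataFrame({"f": [1.0, 1.0, 1.0], "g": [1.0, 2.0, 3.0],
                              "rp": [0, 1, 0]})
        with pytest.warns(UserWarning, match="constant"):
            xtr, _, params = zscore_fit_apply(train, train, ["f", "g"])
        assert params["columns"] == ["g"]
        assert xtr.shape[1] == 1

    def test_scaler_depends_only_on_train(self, rng):
        train = make_table(seed=1)
        test_a = make_table(seed=2)
        test_b = test_a.sample(frac=1.0, random_state=3)  # permuted rows
        _, _, pa = zscore_fit_apply(train, test_a, ["f1", "f2"])
        _, _, pb = zscore_fit_apply(train, test_b, ["f1", "f2"])
        assert np.array_equal(pa["mean"], pb["mean"])
        assert np.array_equal(pa["sd"], pb["sd"])


class TestStratifiedSplit:
    def test_per_class_rounding_rule(self):
        table = make_table(n=10, n_pos=4, seed=0)
        scheme = SplitScheme(train_fraction=0.7, seed=5)
        train, test = stratified_split(table, scheme, repeat=0)
        # round(0.7 * 4) = 3 positives, round(0.7 * 6) = 4 negatives
        assert (train["rp"].sum(), len(train)) == (3, 7)
        assert (test["rp"].sum(), len(test)) == (1, 3)

    def test_deterministic_given_seed_and_repeat(self):
        table = make_table(n=30, n_pos=9, seed=1)
        scheme = SplitScheme(seed=7)
        a = stratified_split(table, scheme, repeat=4)
        b = stratified_split(table, scheme, repeat=4)
        pd.testing.assert_frame_equal(a[0], b[0])
        c = stratified_split(table, scheme, repeat=5)
        assert not a[0].index.equals(c[0].index)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitScheme(train_fraction=1.0)
        table = make_table(n=6, n_pos=2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            stratified_split(table, SplitScheme(train_fraction=0.95), repeat=0)


class TestAuc:
    def test_four_point_example(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.4, 0.35, 0.8]
        assert auc(scores, labels) == pytest.approx(0.75)
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_perfect_and_all_tied(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_matches_brute_force_and_sklearn_on_random_data(self, rng):
        for _ in range(10):
            scores = rng.normal(size=30).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            a = auc(scores, labels)
            assert a == pytest.approx(brute_force_auc(scores, labels))
            assert a == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_increasing_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(auc(np.exp(scores), labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 2], [1, 1])


class TestTuneSvm:
    def test_separable_data_reaches_high_inner_cv_auc(self, rng):
        n = 40
        y = np.tile([0, 1], n // 2)
        X = rng.normal(scale=0.3, size=(n, 2)) + 3.0 * y[:, None]
        scheme = SplitScheme(bo_calls=15, bo_initial=8)
        C, gamma, trace = tune_svm(X, y, scheme, np.random.default_rng(0))
        assert trace.best_value >= 0.95
        assert 1e-3 <= C <= 1e3 and 1e-4 <= gamma <= 10.0

    def test_budget_one_returns_single_evaluated_point(self, rng):
        y = np.tile([0, 1], 10)
        X = rng.normal(size=(20, 2))
        _, _, trace = tune_svm(X, y, SplitScheme(bo_calls=1, bo_initial=1),
                               np.random.default_rng(1))
        assert len(trace.values) == 1

    def test_permutation_null_band(self, rng):
        # with labels carrying no signal, the tuned inner-CV AUC stays in a
        # modest band (optimization bias alone cannot manufacture signal)
        n = 40
        X = rng.normal(size=(n, 2))
        y = np.tile([0, 1], n // 2)
        scheme = SplitScheme(bo_calls=8, bo_initial=5)
        best = []
        for i in range(10):
            yp = np.random.default_rng(i).permutation(y)
            _, _, trace = tune_svm(X, yp, scheme, np.random.default_rng(100 + i))
            best.append(trace.best_value)
        assert 0.4 <= np.mean(best) <= 0.7

    def test_too_few_class_members_for_folds_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 1])  # 2 positives < 5 folds
        with pytest.raises(ValueError, match="fewer members"):
            tune_svm(X, y, SplitScheme(), np.random.default_rng(0))


class TestRunExperiment:
    def test_perfect_signal_limit(self):
        table = make_table(n=30, n_pos=10, seed=2, informative=True)
        sets = {"one": ("f1",), "both": ("f1", "f2")}
        scheme = SplitScheme(n_repeats=3, bo_calls=8, bo_initial=5, seed=3)
        res = run_experiment(table, sets, scheme)
        assert np.median(res.test_aucs("both")) > 0.9

    def test_paired_design_shares_splits_across_sets(self):
        table = make_table(n=24, n_pos=8, seed=4)
        sets = {"a": ("f1",), "b": ("f2",)}
        scheme = SplitScheme(n_repeats=2, bo_calls=4, bo_initial=3, seed=5)
        res = run_experiment(table, sets, scheme)
        assert [r.repeat for r in res.runs["a"]] == [r.repeat for r in res.runs["b"]]
        # identical split => identical per-repeat test sizes and C/gamma box
        for ra, rb in zip(res.runs["a"], res.runs["b"]):
            assert ra.repeat == rb.repeat

    def test_summary_recomputable_from_runs(self):
        table = make_table(n=24, n_pos=8, seed=6)
        scheme = SplitScheme(n_repeats=4, bo_calls=4, bo_initial=3, seed=7)
        res = run_experiment(table, {"a": ("f1",)}, scheme)
        summ = res.summary()
        row = summ[(summ.feature_set == "a") & (summ.partition == "test")].iloc[0]
        assert row["median_auc"] == pytest.approx(float(np.median(res.test_aucs("a"))))
        assert row["n_models"] == 4

    def test_missing_columns_rejected(self):
        table = make_table()
        with pytest.raises(ValueError, match="lacks columns"):
            run_experiment(table, {"a": ("nope",)}, SplitScheme(n_repeats=1))


class TestWilcoxon:
    def test_five_uniform_signs_exact(self):
        a = [0.6, 0.7, 0.65, 0.8, 0.75]
        b = [0.5, 0.55, 0.6, 0.7, 0.62]
        expected = exact_wilcoxon_p([x - y for x, y in zip(a, b)])
        assert expected == pytest.approx(0.0625)  # 2 / 2^5
        assert compare_feature_sets(a, b) == pytest.approx(expected)

    def test_identical_inputs_warn_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            p = compare_feature_sets([0.5, 0.6], [0.5, 0.6])
        assert p == 1.0

    def test_sign_flip_symmetry(self, rng):
        a = rng.uniform(0.4, 0.9, size=12)
        b = rng.uniform(0.4, 0.9, size=12)
        assert compare_feature_sets(a, b) == pytest.approx(compare_feature_sets(b, a))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            compare_feature_sets([0.5], [0.5, 0.6])


class TestMannWhitney:
    def test_disjoint_groups_exact_p(self):
        table = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6],
                              "rp": [1, 1, 1, 0, 0, 0]})
        expected = exact_mannwhitney_p([1, 2, 3], [4, 5, 6])
        assert expected == pytest.approx(0.1)  # 2 / C(6,3)
        assert univariate_screen(table)["f"] == pytest.approx(expected)

    def test_label_swap_invariance(self, rng):
        vals = rng.normal(size=16)
        labels = np.tile([0, 1], 8)
        t1 = pd.DataFrame({"f": vals, "rp": labels})
        t2 = pd.DataFrame({"f": vals, "rp": 1 - labels})
        assert univariate_screen(t1)["f"] == pytest.approx(univariate_screen(t2)["f"])

    def test_identical_groups_p_near_one(self):
        table = pd.DataFrame({"f": [1.0, 2.0, 3.0] * 2, "rp": [0, 0, 0, 1, 1, 1]})
        assert univariate_screen(table)["f"] > 0.9

    def test_single_class_rejected(self):
        table = pd.DataFrame({"f": [1.0, 2.0], "rp": [1, 1]})
        with pytest.raises(ValueError, match="both classes"):
            univariate_screen(table)


class TestSpearman:
    def test_monotone_and_antitone(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [10.0, 20, 30, 40],
                          "z": [4.0, 3, 2, 1]})
        m = correlation_matrix(t, ["x", "y", "z"])
        assert m.loc["x", "y"] == pytest.approx(1.0)
        assert m.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_rank_difference_example(self):
        # rho = 1 - 6 * sum(d^2) / (n^3 - n) with d = rank differences
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))  # ranks equal values here
        expected = 1 - 6 * d2 / (5**3 - 5)
        t = pd.DataFrame({"x": x, "y": y})
        assert correlation_matrix(t, ["x", "y"]).loc["x", "y"] == pytest.approx(expected)
        assert expected == pytest.approx(0.8)

    def test_constant_column_flagged(self):
        t = pd.DataFrame({"x": [1.0, 2, 3], "y": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            m = correlation_matrix(t, ["x", "y"])
        assert np.isnan(m.loc["x", "y"])

    def test_too_few_rows_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2], "y": [2.0, 1]})
        with pytest.raises(ValueError, match="at least 3"):
            correlation_matrix(t, ["x", "y"])
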