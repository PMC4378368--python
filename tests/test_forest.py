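import itertools

import numpy as np
import pytest
from scipy.stats import norm, rankdata, spearmanr

import sensiperiod as sp
from sensiperiod.forest import _candidate_features


# --------------------------------------------------------------------------
# independent oracle: exhaustive split search under the stated criterion


def oracle_root_split(X, y, alpha, min_child, task):
    """Brute-force root decision: (feature, threshold) or None (leaf).

    Selection: per feature, Spearman-type z = corr(midranks(x), scores(y)) *
    sqrt(n-1) via scipy; winner = max |z| (ties -> lowest index); stop if the
    Bonferroni-adjusted two-sided normal p >= alpha.  Cutpoint: maximize the
    standardized left-group score sum over all admissible boundaries.
    """
    n, p = X.shape
    g = y.astype(float) if task == "classification" else rankdata(y)
    zs = np.zeros(p)
    for j in range(p):
        if np.unique(X[:, j]).size < 2 or np.unique(g).size < 2:
            continue
        rho = spearmanr(X[:, j], g).statistic if task == "regression" else np.corrcoef(rankdata(X[:, j]), g)[0, 1]
        if np.isnan(rho):
            continue
        zs[j] = np.clip(rho, -1, 1) * np.sqrt(n - 1)
    j_best = int(np.argmax(np.abs(zs)))
    p_adj = min(1.0, 2.0 * norm.sf(abs(zs[j_best])) * p)
    if p_adj >= alpha:
        return None
    x = X[:, j_best]
    gbar, g_ss = g.mean(), np.sum((g - g.mean()) ** 2)
    best = None
    for thr in sorted(set(x))[:-1]:
        nl = int(np.sum(x <= thr))
        if nl < min_child or n - nl < min_child:
            continue
        s_l = g[x <= thr].sum()
        var = nl * (n - nl) * g_ss / (n * (n - 1))
        zc = abs(s_l - nl * gbar) / np.sqrt(var)
        if best is None or zc > best[0] + 1e-12:
            best = (zc, thr)
    if best is None:
        return None
    return j_best, best[1]


class TestFitTree:
    def test_root_split_matches_exhaustive_search(self):
        """Criterion agreement on 100 random small regression tables."""
        rng = np.random.default_rng(42)
        cfg = sp.ForestConfig(mtry=100, alpha_split=0.95, min_node=4,
                              min_child=2, max_depth=1)
        n_split = 0
        for rep in range(100):
            n = int(rng.integers(6, 11))
            p = int(rng.integers(2, 5))
            X = rng.integers(0, 4, size=(n, p)).astype(float)
            y = rng.normal(size=n) + X[:, 0] * rng.uniform(0, 2)
            tree = sp.fit_tree(X, y, cfg, task="regression")
            expected = oracle_root_split(X, y, 0.95, 2, "regression")
            if expected is None:
                assert tree.feature[0] == -1
            else:
                n_split += 1
                assert (tree.feature[0], tree.threshold[0]) == expected
        assert n_split > 30  # the comparison must actually exercise splits

    def test_null_outcome_mostly_single_leaf(self):
        """Type-I stop rate: independent outcome -> leaf in >=80% of runs."""
        rng = np.random.default_rng(0)
        cfg = sp.ForestConfig(alpha_split=0.05, mtry=4)
        leaves = 0
        n_runs = 100
        for rep in range(n_runs):
            X = rng.normal(size=(200, 10))
            y = rng.normal(size=200)
            tree = sp.fit_tree(X, y, cfg, task="regression", tree_key=rep)
            leaves += tree.feature[0] == -1
        assert leaves >= 0.8 * n_runs

    def test_perfect_separator_gives_depth_one_tree(self):
        rng = np.random.default_rng(1)
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([y * 2 + 1, rng.normal(size=n)])
        cfg = sp.ForestConfig(mtry=2)
        tree = sp.fit_tree(X, y, cfg, task="classification")
        assert tree.feature[0] == 0
        assert tree.n_leaves == 2
        acc = np.mean((tree.predict(X) > 0.5) == (y > 0.5))
        assert acc == 1.0

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0], [np.nan], [2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            sp.fit_tree(X, np.zeros(3), sp.ForestConfig(), task="regression")


class TestFitForest:
    def test_single_tree_forest_equals_tree(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        y = X[:, 0] + 0.2 * rng.normal(size=80)
        model = sp.fit_forest(X, y, sp.ForestConfig(n_trees=1), seed=3)
        np.testing.assert_array_equal(
            sp.predict(model, X), model.trees[0].predict(X)
        )

    def test_same_seed_identical_subsamples_and_trees(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 6))
        y = rng.normal(size=100)
        m1 = sp.fit_forest(X, y, sp.ForestConfig(n_trees=10), seed=7)
        m2 = sp.fit_forest(X, y, sp.ForestConfig(n_trees=10), seed=7)
        for s1, s2 in zip(m1.subsample_indices, m2.subsample_indices):
            np.testing.assert_array_equal(s1, s2)
        for t1, t2 in zip(m1.trees, m2.trees):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_array_equal(t1.threshold, t2.threshold)

    def test_planted_signal_beats_mean_predictor(self):
        rng = np.random.default_rng(4)
        n = 560
        X = rng.integers(0, 4, size=(n, 20)).astype(float)
        sig = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
        y = np.sqrt(0.25) * sig + np.sqrt(0.75) * rng.normal(size=n)
        tr, te = np.arange(400), np.arange(400, n)
        model = sp.fit_forest(X[tr], y[tr], sp.ForestConfig(n_trees=100), seed=5)
        pred = sp.predict(model, X[te])
        ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
        r2_forest = 1 - np.sum((y[te] - pred) ** 2) / ss_tot
        r2_mean = 1 - np.sum((y[te] - y[tr].mean()) ** 2) / ss_tot
        assert r2_forest > r2_mean

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_forest(np.zeros((10, 2)), np.zeros(10), sp.ForestConfig(n_trees=0))

    def test_error_non_increasing_in_n_trees(self):
        """Averaging more trees reduces mean prediction error on fresh rows
        (nested tree prefixes, averaged over 20 seeds)."""
        sizes = (2, 10, 60)
        mses = {k: [] for k in sizes}
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.integers(0, 4, size=(250, 8)).astype(float)
            y = X[:, 0] + rng.normal(size=250)
            tr, te = np.arange(150), np.arange(150, 250)
            # high-variance trees (mtry 1, small subsamples, permissive
            # stopping) make the 1/k variance reduction visible over noise
            cfg = sp.ForestConfig(n_trees=max(sizes), mtry=1,
                                  alpha_split=0.999, subsample_fraction=0.4)
            full = sp.fit_forest(X[tr], y[tr], cfg, seed=seed)
            per_tree = np.array([t.predict(X[te]) for t in full.trees])
            for k in sizes:
                pred = per_tree[:k].mean(axis=0)
                mses[k].append(np.mean((y[te] - pred) ** 2))
        means = [np.mean(mses[k]) for k in sizes]
        assert means[0] >= means[1] >= means[2]


class TestPredict:
    def test_all_leaf_trees_average(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = np.full(30, 0.7)
        model = sp.fit_forest(X, y, sp.ForestConfig(n_trees=4), seed=6,
                              task="regression")
        np.testing.assert_allclose(sp.predict(model, X[:5]), 0.7)

    def test_two_tree_average(self):
        leaf = lambda v: sp.Tree(
            feature=np.array([-1]), threshold=np.array([np.nan]),
            left=np.array([-1]), right=np.array([-1]),
            value=np.array([v]), n_node=np.array([1]),
        )
        model = sp.ForestModel(
            trees=[leaf(0.2), leaf(0.6)], subsample_indices=[np.array([0]), np.array([0])],
            config=sp.ForestConfig(n_trees=2), task="regression", n_features=1, seed=0,
        )
        assert sp.predict(model, np.zeros((3, 1)))[0] == pytest.approx(0.4)

    def test_matches_per_tree_traversal(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 5, size=(60, 4)).astype(float)
        y = X[:, 1] + 0.3 * rng.normal(size=60)
        model = sp.fit_forest(X, y, sp.ForestConfig(n_trees=5), seed=8)
        rows = X[:10]

        def traverse(tree, row):
            i = 0
            while tree.feature[i] >= 0:
                i = tree.left[i] if row[tree.feature[i]] <= tree.threshold[i] else tree.right[i]
            return tree.value[i]

        expected = np.mean(
            [[traverse(t, r) for t in model.trees] for r in rows], axis=1
        )
        np.testing.assert_allclose(sp.predict(model, rows), expected)

    def test_feature_count_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        model = sp.fit_forest(X, X[:, 0], sp.ForestConfig(n_trees=2), seed=9)
        with pytest.raises(ValueError, match="mismatch"):
            sp.predict(model, np.zeros((2, 4)))


class TestPermutationImportance:
    def _signal_forest(self, n=200, p=5, n_trees=20, seed=10):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 4, size=(n, p)).astype(float)
        X[:, p - 1] = 1.0  # constant column
        y = X[:, 0] + 0.5 * rng.normal(size=n)
        model = sp.fit_forest(X, y, sp.ForestConfig(n_trees=n_trees), seed=seed)
        return X, y, model

    def test_constant_and_unused_features_zero(self):
        X, y, model = self._signal_forest()
        imp = sp.permutation_importance(model, X, y, seed=1)
        used = set()
        for t in model.trees:
            used |= set(t.used_features())
        for f in range(X.shape[1]):
            if f not in used:
                assert imp[f] == 0.0
        assert imp[X.shape[1] - 1] == 0.0  # constant feature can never split
        assert imp[0] > 0.0

    def test_exhaustive_permutation_oracle(self):
        """Single depth-1 tree, 6 eval rows: MC estimate vs all 720 perms."""
        rng = np.random.default_rng(11)
        n = 40
        y = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([y * 3, rng.normal(size=n)])
        model = sp.fit_forest(
            X, y, sp.ForestConfig(n_trees=1, mtry=2, subsample_fraction=1.0), seed=12,
            task="classification",
        )
        tree = model.trees[0]
        assert tree.n_leaves == 2 and tree.feature[0] == 0
        Xe = np.column_stack([np.array([0, 3, 0, 3, 3, 0]), np.zeros(6)]).astype(float)
        ye = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        base = np.mean((tree.predict(Xe) > 0.5) == (ye > 0.5))
        degr = []
        for perm in itertools.permutations(range(6)):
            Xp = Xe.copy()
            Xp[:, 0] = Xe[list(perm), 0]
            degr.append(base - np.mean((tree.predict(Xp) > 0.5) == (ye > 0.5)))
        exact = np.mean(degr)
        se = np.std(degr) / np.sqrt(240)
        imp = sp.permutation_importance(
            model, X, y, seed=13, n_permutations=240, eval_rows=np.arange(6)
        )
        # model importance uses its own eval rows; emulate the same 6 rows
        Xs = X.copy()
        Xs[:6] = Xe
        ys = y.copy()
        ys[:6] = ye
        imp = sp.permutation_importance(
            model, Xs, ys, seed=13, n_permutations=240, eval_rows=np.arange(6)
        )
        assert abs(imp[0] - exact) <= 3 * se + 1e-12


class TestCandidateSampling:
    def test_appending_feature_preserves_existing_priorities(self):
        """Candidate draws over the original features are unchanged by a new
        feature except where the new feature itself displaces one."""
        key, path = 12345, 999
        for p in (10, 50, 200):
            mtry = 5
            old = set(_candidate_features(key, path, p, mtry))
            new = set(_candidate_features(key, path, p + 1, mtry))
            if p not in new:
                assert new == old
            else:
                assert new - {p} <= old and len(old - new) == 1

    def test_candidate_sets_deterministic(self):
        a = _candidate_features(7, 8, 100, 10)
        b = _candidate_features(7, 8, 100, 10)
        np.testing.assert_array_equal(a, b)


class TestSerialization:
    def test_json_round_trip(self):
        rng = np.random.default_rng(14)
        X = rng.integers(0, 4, size=(100, 6)).astype(float)
        y = X[:, 2] + rng.normal(size=100)
        model = sp.fit_forest(X, y, sp.ForestConfig(n_trees=5), seed=15)
        import json

        doc = json.loads(json.dumps(model.to_dict()))
        model2 = sp.ForestModel.from_dict(doc)
        np.testing.assert_allclose(sp.predict(model2, X), sp.predict(model, X))
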