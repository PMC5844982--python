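import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from oracles import brute_bh_adjust
from pgme.entropy import PGMETensor
from pgme.exceptions import DataError
from pgme.prediction import (CohortTable, aicc, aicc_compare, backward_select,
                             bootstrap_ci, confusion_rates, evaluate_holdouts,
                             fit_plsda, group_compare, make_holdouts,
                             nipals_pls, predict_plsda, tp_loadings)


def _paired_cohort(n_pairs, seed=0):
    ids = [f"s{i}" for i in range(2 * n_pairs)]
    pair = pd.Series(np.repeat(np.arange(n_pairs), 2), index=ids)
    labels = pd.Series(np.tile([1, 0], n_pairs), index=ids)
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(2 * n_pairs, 6)), index=ids,
                     columns=[f"f{i}" for i in range(6)])
    return X, labels, pair


class TestMakeHoldouts:
    def test_pair_counts_and_stratification(self):
        _, labels, pair = _paired_cohort(10)
        splits = make_holdouts(pair, n_reps=20, train_frac=0.8, seed=0)
        for train, test in splits:
            assert len(train) == 16 and len(test) == 4
            assert labels.loc[test].mean() == 0.5
            assert labels.loc[train].mean() == 0.5
            # pairs never straddle the split
            for p in pair.unique():
                members = pair.index[pair == p]
                assert (set(members) <= set(train)) or (set(members) <= set(test))

    def test_determinism_and_seed_sensitivity(self):
        _, _, pair = _paired_cohort(10)
        a = make_holdouts(pair, n_reps=10, seed=5)
        b = make_holdouts(pair, n_reps=10, seed=5)
        c = make_holdouts(pair, n_reps=10, seed=6)
        for (ta, _), (tb, _) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
        assert any(not np.array_equal(ta, tc)
                   for (ta, _), (tc, _) in zip(a, c))

    def test_too_small_cohort(self):
        _, _, pair = _paired_cohort(1)
        with pytest.raises(DataError):
            make_holdouts(pair, train_frac=0.8)


class TestNIPALS:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=50)
        p = rng.normal(size=8)
        X = np.outer(t, p)
        m = nipals_pls(X + 1e-12 * rng.normal(size=X.shape), t, 1)
        r = abs(np.corrcoef(m.scores[:, 0], t)[0, 1])
        assert r > 1 - 1e-8

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        m = nipals_pls(X, y, 6)
        G = m.scores.T @ m.scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_full_components_equal_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        m = nipals_pls(X, y, 5)
        fitted = (X - m.x_mean) @ m.coef + m.y_mean
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(fitted, Xc @ beta + y.mean(), atol=1e-6)

    def test_matches_sklearn_reference(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(35, 7))
        y = rng.normal(size=35)
        m = nipals_pls(X, y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, y)
        ours = (X - m.x_mean) @ m.coef + m.y_mean
        np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-10)

    def test_zero_variance_feature_named(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.raises(DataError, match="dead"):
            nipals_pls(X, rng.normal(size=20), 2,
                       feature_names=["alive", "dead", "kicking"])


class TestPLSDA:
    def test_separated_clouds_high_training_accuracy(self):
        rng = np.random.default_rng(6)
        y = np.tile([0, 1], 30)
        X = rng.normal(size=(60, 5))
        X[:, 0] += 6.0 * y
        model = fit_plsda(X, y, max_components=5, seed=0)
        _, pred = predict_plsda(model, X)
        assert (pred == y).mean() >= 0.99

    def test_permuted_labels_chance_level(self):
        # fresh permutation per repetition: the proper permutation null
        X, labels, pair = _paired_cohort(20, seed=7)
        X["f0"] += 3.0 * labels
        rng = np.random.default_rng(8)
        splits = make_holdouts(pair, n_reps=30, seed=1)
        accs = []
        for i, (tr, te) in enumerate(splits):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            model = fit_plsda(X.loc[tr], perm.loc[tr].to_numpy(),
                              max_components=4, seed=i)
            _, pred = predict_plsda(model, X.loc[te])
            accs.append(float((pred == perm.loc[te].to_numpy()).mean()))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_single_informative_feature_parsimonious_components(self):
        """With one informative feature among noise the one-standard-error
        rule must keep the latent space small: never more than two
        components, and a single component in at least half the seeds."""
        comps = []
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            y = np.tile([0, 1], 50)
            X = rng.normal(size=(100, 6))
            X[:, 0] += 3.0 * y
            comps.append(fit_plsda(X, y, max_components=5,
                                   seed=seed).n_components)
        assert np.mean([c <= 2 for c in comps]) >= 0.8
        assert np.mean([c == 1 for c in comps]) >= 0.5


class TestTPLoadings:
    def test_informative_feature_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            y = np.tile([0, 1], 25)
            X = pd.DataFrame(rng.normal(size=(50, 8)),
                             columns=[f"f{i}" for i in range(8)])
            X["f3"] += 3.0 * y
            model = fit_plsda(X, y, n_components=2, seed=seed)
            ranking = tp_loadings(model)
            hits += ranking.iloc[0]["feature"] == "f3"
        assert hits >= 9

    def test_duplicate_features_equal_loadings(self):
        rng = np.random.default_rng(9)
        y = np.tile([0, 1], 20)
        base = rng.normal(size=40) + 2.0 * y
        X = pd.DataFrame({
            "twin_a": base, "twin_b": base.copy(),
            "noise": rng.normal(size=40),
        })
        model = fit_plsda(X, y, n_components=1, seed=0)
        ranking = tp_loadings(model).set_index("feature")
        delta = abs(ranking.loc["twin_a", "tp_loading"]
                    - ranking.loc["twin_b", "tp_loading"])
        assert delta < 1e-10
        # deterministic tie-break by name
        assert (ranking.loc["twin_a", "rank"]
                < ranking.loc["twin_b", "rank"])


class TestBackwardSelect:
    def test_informative_features_survive(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(300 + seed)
            y = np.tile([0, 1], 25)
            X = pd.DataFrame(rng.normal(size=(50, 10)),
                             columns=[f"g{i}" for i in range(10)])
            X["g0"] += 2.0 * y
            X["g1"] -= 2.0 * y
            sel, trace = backward_select(X, y, max_components=5, seed=seed)
            hits += ("g0" in sel) and ("g1" in sel)
        assert hits >= 6  # >= 80% of seeds

    def test_trace_bookkeeping(self):
        rng = np.random.default_rng(10)
        y = np.tile([0, 1], 15)
        X = pd.DataFrame(rng.normal(size=(30, 4)),
                         columns=list("abcd"))
        X["a"] += 3.0 * y
        sel, trace = backward_select(X, y, max_components=3, seed=0)
        assert trace["n_features"].tolist() == [4, 3, 2, 1]
        assert trace["removed"].iloc[0] is None
        # selected subset is the global-minimum row of the trace
        best = trace.loc[trace["error"].idxmin()]
        assert set(sel) == set(best["subset"])

    def test_single_feature_passthrough(self):
        X = pd.DataFrame({"only": np.r_[np.zeros(10), np.ones(10)]
                          + 0.1 * np.random.default_rng(0).normal(size=20)})
        y = np.r_[np.zeros(10), np.ones(10)]
        sel, trace = backward_select(X, y, seed=0)
        assert sel == ["only"]
        assert len(trace) == 1


class TestEvaluation:
    def test_confusion_arithmetic(self):
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 1])
        rates = confusion_rates(y, p)
        assert rates["sensitivity"] == 0.6
        assert rates["specificity"] == 0.8
        assert rates["ppv"] == 0.75
        assert rates["npv"] == pytest.approx(2 / 3)
        assert rates["accuracy"] == 0.7

    def test_perfect_classifier(self):
        y = np.array([1, 0, 1, 0])
        rates = confusion_rates(y, y)
        assert all(v == 1.0 for v in rates.values())
        lo, hi = bootstrap_ci(np.ones(50))
        assert lo == hi == 1.0

    def test_bootstrap_ci_contains_point(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.6, 0.9, size=100)
        lo, hi = bootstrap_ci(vals, seed=1)
        assert lo <= vals.mean() <= hi


class TestAICc:
    def test_closed_form(self):
        assert aicc(-10.0, 2, 20) == pytest.approx(24.7058823529, abs=1e-9)

    def test_identical_models_rl_one(self):
        table = aicc_compare({"a": 30.0, "b": 30.0})
        assert np.allclose(table["delta_aicc"], 0.0)
        assert np.allclose(table["rel_likelihood"], 1.0)

    def test_better_likelihood_lower_aicc(self):
        assert aicc(-5.0, 3, 25) < aicc(-9.0, 3, 25)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(DataError):
            aicc(-1.0, 5, 6)


def _tensor_from(values):
    v = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return PGMETensor(values=v, scales=(1,), phases=(0,),
                      q_grid=np.linspace(-1, 1, v.shape[2]), level="subject")


class TestGroupCompare:
    def test_bh_adjustment_matches_hand_stepup(self):
        from statsmodels.stats.multitest import multipletests
        raw = [0.01, 0.03, 0.04]
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        np.testing.assert_allclose(adj, brute_bh_adjust(raw), atol=1e-12)
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04], atol=1e-12)

    def test_null_false_discovery_proportion(self):
        """Identical populations: across 200 simulated null datasets the
        overall discovery proportion stays at or below the FDR level."""
        rng = np.random.default_rng(12)
        total_cells = 0
        discoveries = 0
        for _ in range(200):
            A = [_tensor_from(rng.normal(size=6)) for _ in range(10)]
            B = [_tensor_from(rng.normal(size=6)) for _ in range(10)]
            df = group_compare(A, B)
            total_cells += len(df)
            discoveries += int(df["significant"].sum())
        assert discoveries / total_cells <= 0.05

    def test_shifted_cell_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            A = [_tensor_from(rng.normal(size=6)) for _ in range(20)]
            B = [_tensor_from(rng.normal(size=6)) for _ in range(20)]
            for t in A:
                t.values[0, 0, 2] += 2.0  # 2-pooled-SD shift in one cell
            df = group_compare(A, B)
            row = df[(df["q"] == df["q"].unique()[2])]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 19  # >= 95% of seeds

    def test_missing_cells_skipped(self):
        rng = np.random.default_rng(13)
        A = [_tensor_from(rng.normal(size=6)) for _ in range(5)]
        B = [_tensor_from(rng.normal(size=6)) for _ in range(5)]
        for t in A + B:
            t.values[0, 0, 0] = np.nan
        df = group_compare(A, B)
        assert len(df) == 5  # the all-missing cell is excluded from m


class TestCohortTable:
    def test_pairing_invariant(self):
        X, labels, pair = _paired_cohort(5)
        CohortTable(features=X, labels=labels, pair_id=pair)
        bad = labels.copy()
        bad.iloc[1] = 1  # pair 0 now has two fallers
        with pytest.raises(DataError):
            CohortTable(features=X, labels=bad, pair_id=pair)
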