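"""Cross-validation machinery: folds, LHS, up-sampling, elastic net, AUROC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from panelfrag import evaluate as ev
from panelfrag.fragments import ConfigError
from panelfrag.metrics import FeatureTable


def auroc_oracle(scores, positives):
    """All-pairs Mann-Whitney statistic with ties counting one half."""
    scores = np.asarray(scores, float)
    pos = np.asarray(positives, bool)
    total = 0.0
    for sp in scores[pos]:
        for sn in scores[~pos]:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (pos.sum() * (~pos).sum())


def table_from(X, y, metric="depth_all_exons"):
    idx = pd.Index([f"s{i}" for i in range(len(y))], name="sample_id")
    return FeatureTable(metric, pd.DataFrame(np.asarray(X, float), index=idx),
                        pd.Series(np.asarray(y), index=idx))


class TestFolds:
    def test_balanced_stratification(self):
        y = ["a"] * 50 + ["b"] * 50
        folds = ev.make_folds(y, 10, seed=0)
        y = np.array(y)
        for f in range(10):
            mask = folds == f
            assert mask.sum() == 10
            assert (y[mask] == "a").sum() == 5

    def test_deterministic(self):
        y = ["a", "b"] * 30
        assert (ev.make_folds(y, 5, 3) == ev.make_folds(y, 5, 3)).all()
        assert (ev.make_folds(y, 5, 3) != ev.make_folds(y, 5, 4)).any()

    def test_k_bounds(self):
        with pytest.raises(ConfigError):
            ev.make_folds(["a", "b"], 1, 0)
        with pytest.raises(ConfigError):
            ev.make_folds(["a", "b"], 3, 0)


class TestLatinHypercube:
    def test_one_point_per_stratum_on_both_axes(self):
        n = 10
        pts = ev.latin_hypercube_hyperparams(n, (0, 1), (1e-4, 10), seed=5)
        alpha_strata = sorted(int(p.alpha * n) for p in pts)
        assert alpha_strata == list(range(n))
        lo, hi = np.log(1e-4), np.log(10)
        lam_strata = sorted(
            int((np.log(p.lambda_) - lo) / (hi - lo) * n) for p in pts
        )
        assert lam_strata == list(range(n))

    def test_single_point_inside_box(self):
        (p,) = ev.latin_hypercube_hyperparams(1, (0.2, 0.8), (0.1, 1.0), seed=1)
        assert 0.2 <= p.alpha <= 0.8
        assert 0.1 <= p.lambda_ <= 1.0

    def test_deterministic(self):
        a = ev.latin_hypercube_hyperparams(5, seed=9)
        b = ev.latin_hypercube_hyperparams(5, seed=9)
        assert a == b


class TestUpsampling:
    def test_minority_resampled_to_majority(self):
        X = np.arange(13)[:, None].astype(float)
        y = np.array(["big"] * 10 + ["small"] * 3)
        X2, y2 = ev.upsample_classes(X, y, seed=0)
        assert (y2 == "big").sum() == 10
        assert (y2 == "small").sum() == 10
        # resampled small rows are copies of original small rows
        assert set(X2[y2 == "small"].ravel()) <= {10.0, 11.0, 12.0}

    def test_balanced_unchanged_up_to_order(self):
        X = np.arange(8)[:, None].astype(float)
        y = np.array(["a", "b"] * 4)
        X2, y2 = ev.upsample_classes(X, y, seed=0)
        assert sorted(X2.ravel()) == sorted(X.ravel())


class TestElasticNetFit:
    def _separable(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
        y = np.array(["neg"] * 10 + ["pos"] * 10)
        Z = (X - X.mean(0)) / X.std(0)
        return Z, y

    def test_large_lambda_nulls_coefficients(self):
        # lambda far above lambda_max: every coefficient is exactly zero and
        # predictions collapse to a constant favouring the majority class
        # (saga leaves the unpenalized intercept short of the exact class
        # log-odds in this degenerate regime, so the prior itself is not
        # asserted to printed precision)
        Z, y = self._separable()
        y = np.array(["neg"] * 15 + ["pos"] * 5)
        model = ev.fit_penalized_multinomial(
            Z, y, ev.HyperParams(1.0, 5.0), max_iter=5000, tol=1e-8
        )
        assert np.abs(model.coef_).max() == 0.0
        proba = model.predict_proba(Z)[:, list(model.classes_).index("pos")]
        assert np.ptp(proba) < 1e-9  # constant over samples
        assert proba[0] < 0.5  # minority class stays minority

    def test_separable_toy_reaches_training_auroc_one(self):
        Z, y = self._separable()
        model = ev.fit_penalized_multinomial(Z, y, ev.HyperParams(0.5, 1e-3))
        scores = model.predict_proba(Z)[:, list(model.classes_).index("pos")]
        assert ev.one_vs_rest_auroc(scores, y == "pos") == 1.0

    def test_lasso_at_least_as_sparse_as_ridge(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 12))
        y = np.where(X[:, 0] + 0.1 * rng.normal(size=60) > 0, "a", "b")
        Z = (X - X.mean(0)) / X.std(0)
        lam = 0.05
        ridge = ev.fit_penalized_multinomial(Z, y, ev.HyperParams(0.0, lam))
        lasso = ev.fit_penalized_multinomial(Z, y, ev.HyperParams(1.0, lam))
        n_zero = lambda m: int((np.abs(m.coef_) < 1e-10).sum())
        assert n_zero(lasso) >= n_zero(ridge)

    def test_input_validation(self):
        with pytest.raises(ConfigError):
            ev.fit_penalized_multinomial(
                np.array([[np.nan]]), np.array(["a", "b"])[:1], ev.HyperParams(0, 1)
            )
        with pytest.raises(ConfigError):
            ev.fit_penalized_multinomial(
                np.zeros((3, 1)), np.array(["a"] * 3), ev.HyperParams(0, 1)
            )
        with pytest.raises(ConfigError):
            ev.HyperParams(alpha=1.2, lambda_=1.0)


class TestNestedSelection:
    def test_single_candidate_returned(self):
        c = ev.HyperParams(0.3, 0.2)
        assert ev.nested_cv_select(np.zeros((4, 1)), np.array(["a"] * 4), [c]) == c

    def test_tie_break_smaller_lambda_then_alpha(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.array(["a", "b"] * 20)
        cands = [ev.HyperParams(0.5, 1e5), ev.HyperParams(0.2, 1e5),
                 ev.HyperParams(0.2, 9e4)]
        # all candidates are maximally shrunk -> identical (null) inner AUROCs
        best = ev.nested_cv_select(X, y, cands, inner_k=4, seed=2)
        assert best == ev.HyperParams(0.2, 9e4)

    def test_degenerate_candidate_loses(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-1, 0.2, (30, 2)), rng.normal(1, 0.2, (30, 2))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        good = ev.HyperParams(0.5, 1e-3)
        degenerate = ev.HyperParams(0.5, 1e7)
        best = ev.nested_cv_select(X, y, [degenerate, good], inner_k=5, seed=0)
        assert best == good


class TestAUROC:
    def test_perfect_separation(self):
        assert ev.one_vs_rest_auroc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_brute_force_hand_case(self):
        assert ev.one_vs_rest_auroc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert ev.one_vs_rest_auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_missing(self):
        assert np.isnan(ev.one_vs_rest_auroc([0.1, 0.2], [1, 1]))

    def test_matches_oracle_and_sklearn_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            pos = rng.random(n) < 0.5
            if pos.all() or not pos.any():
                continue
            got = ev.one_vs_rest_auroc(scores, pos)
            assert got == pytest.approx(auroc_oracle(scores, pos), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(pos, scores), abs=1e-12)


@pytest.fixture(scope="module")
def toy_tables():
    rng = np.random.default_rng(3)
    y = np.array(["healthy"] * 20 + ["cancer"] * 20)
    signal = np.where(y == "cancer", 1.0, -1.0)[:, None]
    X1 = signal + 0.4 * rng.normal(size=(40, 3))
    X2 = rng.normal(size=(40, 3))
    return {
        "depth_all_exons": table_from(X1, y, "depth_all_exons"),
        "entropy_all_exons": table_from(X2, y, "entropy_all_exons"),
    }


class TestRepeatedCV:

    def test_row_counting_rule(self, toy_tables):
        config = ev.CVConfig(outer_folds=5, inner_folds=3, n_hyper=2, n_repeats=3)
        res = ev.run_repeated_cv(toy_tables, config)
        # repeats x metrics x phenotypes
        assert len(res) == 3 * 2 * 2

    def test_signal_metric_beats_noise_metric(self, toy_tables):
        config = ev.CVConfig(outer_folds=5, inner_folds=3, n_hyper=3, n_repeats=3)
        res = ev.run_repeated_cv(toy_tables, config)
        med = res.groupby("metric")["auroc"].median()
        assert med["depth_all_exons"] > 0.95
        assert abs(med["entropy_all_exons"] - 0.5) < 0.25

    def test_fold_assignment_shared_across_metrics(self, toy_tables, monkeypatch):
        calls = []
        orig = ev.make_folds

        def spy(labels, k, seed):
            out = orig(labels, k, seed)
            calls.append((seed, out.tobytes()))
            return out

        monkeypatch.setattr(ev, "make_folds", spy)
        config = ev.CVConfig(outer_folds=4, inner_folds=3, n_hyper=1, n_repeats=2)
        ev.run_repeated_cv(toy_tables, config)
        outer_calls = [c for c in calls if len(c[1]) == 40 * 8]
        # one outer fold assignment per repeat, shared by both metrics
        assert len({c for c in outer_calls}) >= 2
        per_seed = {}
        for seed, blob in outer_calls:
            per_seed.setdefault(seed, set()).add(blob)
        assert all(len(v) == 1 for v in per_seed.values())

    def test_misaligned_tables_rejected(self, toy_tables):
        bad = dict(toy_tables)
        t = bad["entropy_all_exons"]
        flipped = pd.Series(
            np.where(t.labels.values == "cancer", "healthy", "cancer"),
            index=t.labels.index,
        )
        bad["entropy_all_exons"] = FeatureTable("entropy_all_exons", t.values, flipped)
        with pytest.raises(ConfigError, match="misaligned"):
            ev.run_repeated_cv(bad, ev.CVConfig(n_repeats=1))


class TestNoLeakage:
    def test_poisoning_heldout_rows_leaves_fit_unchanged(self):
        """Imputation, scaling, up-sampling and selection must never see
        held-out rows: corrupting them cannot change the fitted model."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))
        X[rng.random((60, 4)) < 0.1] = np.nan  # exercise imputation too
        y = np.array(["a", "b"] * 30)
        train = np.arange(60) % 3 != 0
        cands = ev.latin_hypercube_hyperparams(3, seed=1)
        config = ev.CVConfig(outer_folds=4, inner_folds=3, n_hyper=3)
        fm1 = ev._train_one_fold(X, y, train, cands, config, seed=7)
        X_poisoned = X.copy()
        X_poisoned[~train] = 1e9
        fm2 = ev._train_one_fold(X_poisoned, y, train, cands, config, seed=7)
        assert fm1.params == fm2.params
        np.testing.assert_array_equal(fm1.medians_, fm2.medians_)
        np.testing.assert_array_equal(fm1.means_, fm2.means_)
        np.testing.assert_array_equal(fm1.model_.coef_, fm2.model_.coef_)

    def test_heldout_class_proportions_untouched_by_upsampling(self):
        y = np.array(["a"] * 9 + ["b"] * 3)
        train = np.arange(12) < 8
        X = np.zeros((12, 1))
        X2, y2 = ev.upsample_classes(X[train], y[train], seed=0)
        # held-out labels unchanged by construction
        assert list(y[~train]) == ["a", "b", "b", "b"]


class TestSummaries:
    def test_median_and_delta_arithmetic(self):
        full = pd.DataFrame(
            {
                "metric": ["m"] * 3,
                "phenotype": ["p"] * 3,
                "repeat": [0, 1, 2],
                "auroc": [0.9, 0.92, 0.94],
            }
        )
        sub = full.copy()
        sub["auroc"] = [0.85, 0.9, 0.8]
        s = ev.summarize(full)
        assert s["median_auroc"].iloc[0] == pytest.approx(0.92)
        d = ev.median_delta(full, sub)
        assert d["delta"].iloc[0] == pytest.approx(0.85 - 0.92)

    def test_identical_sets_zero_delta(self):
        res = pd.DataFrame(
            {"metric": ["m"], "phenotype": ["p"], "repeat": [0], "auroc": [0.7]}
        )
        assert ev.median_delta(res, res)["delta"].iloc[0] == 0.0
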