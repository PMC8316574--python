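import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoprio.model import (
    BenchmarkSet,
    ConfusionCounts,
    bootstrap_auc_ci,
    build_benchmarks,
    cross_validate,
    fit_logistic,
    fit_normalizer,
    intersect_lirp,
    prioritize_top_fraction,
    roc_auc,
    select_final_model,
    sensitivity_specificity,
)


def feature_frame(rng, n, shift=0.0, prefix="s"):
    return pd.DataFrame(
        {"x": rng.normal(shift, 1.0, n)},
        index=[f"{prefix}{i}" for i in range(n)],
    )


class TestBenchmarks:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.pos = feature_frame(rng, 20, 1.0, "p")
        self.pool = feature_frame(rng, 300, 0.0, "n")

    def test_sizes_and_disjointness(self):
        sets = build_benchmarks(self.pos, self.pool, ratio=5, n_sets=10, seed=1)
        assert len(sets) == 10
        for b in sets:
            assert len(b.negatives) == 100
            assert not set(b.negatives.index) & set(b.positives.index)
            assert b.positives.equals(self.pos)

    def test_same_seed_reproduces(self):
        a = build_benchmarks(self.pos, self.pool, ratio=2, n_sets=3, seed=9)
        b = build_benchmarks(self.pos, self.pool, ratio=2, n_sets=3, seed=9)
        for x, y in zip(a, b):
            assert list(x.negatives.index) == list(y.negatives.index)

    def test_pool_too_small(self):
        with pytest.raises(ValueError, match="pool"):
            build_benchmarks(self.pos, self.pool.head(30), ratio=5, n_sets=1, seed=1)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BenchmarkSet(positives=self.pos, negatives=self.pos, ratio=1, seed=0)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        # with a constant feature the fit reduces to the base-rate log-odds
        X = pd.DataFrame({"c": np.ones(121 + 605)})
        y = np.array([1] * 121 + [0] * 605)
        m = fit_logistic(X, y)
        assert m.intercept == pytest.approx(np.log(121 / 605), abs=0.01)
        assert abs(m.weights[0]) < 1e-4

    def test_noise_feature_weight_vanishes(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"noise": rng.normal(size=20000)})
        y = rng.integers(0, 2, size=20000)
        m = fit_logistic(X, y)
        assert abs(m.weights[0]) < 0.05

    def test_separable_data_stays_finite(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fit_logistic(X, y)
        assert np.isfinite(m.weights).all() and np.isfinite(m.intercept)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1, 1]))


class TestAuc:
    def test_hand_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties(self):
        assert roc_auc(np.ones(10), np.array([0, 1] * 5)) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos, neg = scores[labels == 1], scores[labels == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            eq = (pos[:, None] == neg[None, :]).sum()
            oracle = (gt + 0.5 * eq) / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(oracle)


class TestSnSp:
    @pytest.mark.parametrize(
        "tp, fp, tn, fn, expected",
        [
            (9, 0, 5, 1, (0.9, 1.0)),
            (5, 10, 0, 5, (0.5, 0.0)),
            (5, 5, 5, 5, (0.5, 0.5)),
        ],
    )
    def test_ratios(self, tp, fp, tn, fn, expected):
        assert sensitivity_specificity(ConfusionCounts(tp, fp, tn, fn)) == expected

    def test_undefined_denominator(self):
        with pytest.raises(ValueError):
            sensitivity_specificity(ConfusionCounts(0, 1, 1, 0))


def make_benchmark(rng, shift, n_pos=50, n_neg=50, seed=0):
    return BenchmarkSet(
        positives=feature_frame(rng, n_pos, shift, "p"),
        negatives=feature_frame(rng, n_neg, 0.0, "n"),
        ratio=n_neg // n_pos,
        seed=seed,
    )


class TestCrossValidation:
    def test_separable_benchmark_auc_one(self):
        rng = np.random.default_rng(4)
        b = make_benchmark(rng, shift=50.0)
        assert cross_validate(b, k=10, seed=1).auc == 1.0

    def test_shuffled_labels_auc_half(self):
        rng = np.random.default_rng(5)
        b = make_benchmark(rng, shift=0.0, n_pos=300, n_neg=300)
        assert cross_validate(b, k=10, seed=1).auc == pytest.approx(0.5, abs=0.08)

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(6)
        b = make_benchmark(rng, shift=1.0)
        a = cross_validate(b, k=5, seed=3)
        c = cross_validate(b, k=5, seed=3)
        np.testing.assert_array_equal(a.oof_scores, c.oof_scores)

    def test_class_too_small_for_folds(self):
        rng = np.random.default_rng(7)
        b = make_benchmark(rng, shift=1.0, n_pos=5, n_neg=50)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(b, k=10)


class TestBootstrapCI:
    def test_perfectly_separated_ci_degenerate(self):
        scores = np.array([1, 2, 3, 10, 11, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert bootstrap_auc_ci(scores, labels, n_boot=200, seed=1) == (1.0, 1.0)

    def test_all_equal_scores_ci_at_half(self):
        scores = np.ones(20)
        labels = np.array([0, 1] * 10)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=200, seed=1)
        assert lo == pytest.approx(0.5) and hi == pytest.approx(0.5)

    def test_reproducible_by_seed(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert bootstrap_auc_ci(scores, labels, 500, seed=5) == bootstrap_auc_ci(
            scores, labels, 500, seed=5
        )


class TestModelSelection:
    def test_single_benchmark(self):
        rng = np.random.default_rng(9)
        b = make_benchmark(rng, shift=1.0)
        model, aucs = select_final_model([b], k=5, seed=1)
        assert model.benchmark_index == 0 and len(aucs) == 1

    def test_larger_separation_selected(self):
        rng = np.random.default_rng(10)
        weak = make_benchmark(rng, shift=0.3, n_pos=100, n_neg=100)
        strong = make_benchmark(rng, shift=3.0, n_pos=100, n_neg=100)
        model, aucs = select_final_model([weak, strong], k=5, seed=1)
        assert model.benchmark_index == 1
        assert aucs[1] > aucs[0]

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(11)
        b = make_benchmark(rng, shift=50.0)  # AUC exactly 1 both times
        model, aucs = select_final_model([b, b], k=5, seed=1)
        assert aucs[0] == aucs[1] == 1.0
        assert model.benchmark_index == 0


class TestNormalizer:
    def test_hand_example_with_outlier(self):
        nz = fit_normalizer(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert (nz.q1, nz.q3) == (2.0, 4.0)
        assert (nz.lower_fence, nz.upper_fence) == (-4.0, 10.0)
        assert (nz.s_min, nz.s_max) == (1.0, 4.0)
        assert nz.normalize(100.0) == 1.0
        assert nz.normalize(2.0) == pytest.approx(1 / 3)

    def test_endpoints(self):
        nz = fit_normalizer(np.array([1.0, 2.0, 3.0, 4.0]))
        assert nz.normalize(nz.s_min) == 0.0
        assert nz.normalize(nz.s_max) == 1.0

    def test_degenerate_all_equal(self):
        nz = fit_normalizer(np.ones(6))
        assert nz.normalize(1.0) == 0.5

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.array([1.0, 2.0, 3.0]))

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=40),
        st.floats(-60, 60),
        st.floats(-60, 60),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, raws, a, b):
        nz = fit_normalizer(np.array(raws))
        lo, hi = sorted((a, b))
        assert 0.0 <= nz.normalize(lo) <= nz.normalize(hi) <= 1.0


class TestPrioritization:
    def test_exact_fraction_distinct_scores(self):
        s = pd.Series(np.arange(100.0), index=[f"s{i}" for i in range(100)])
        assert len(prioritize_top_fraction(s, 0.05)) == 5

    def test_ties_at_cut_all_included(self):
        vals = [200.0, 199.0, 198.0, 197.0] + [196.0] * 3 + list(np.arange(93.0))
        s = pd.Series(vals, index=[f"s{i}" for i in range(100)])
        top = prioritize_top_fraction(s, 0.05)
        assert len(top) == 7  # ranks 1-4 distinct plus a 3-way tie at rank 5

    def test_fraction_one_returns_all(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        assert prioritize_top_fraction(s, 1.0) == {"a", "b"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            prioritize_top_fraction(pd.Series(dtype=float), 0.05)

    def test_no_excluded_site_outscores_included(self):
        rng = np.random.default_rng(12)
        s = pd.Series(rng.choice(10, 50) / 10.0, index=[f"s{i}" for i in range(50)])
        top = prioritize_top_fraction(s, 0.1)
        assert s[list(top)].min() >= s.drop(list(top)).max()


class TestLirpIntersection:
    regulated = pd.DataFrame(
        {
            "site_id": ["a", "b", "c"],
            "direction": ["hyper", "hypo", "hyper"],
            "log2fc": [1.0, -1.0, 0.8],
        }
    )

    def test_disjoint_sets_empty(self):
        assert intersect_lirp({"x", "y"}, self.regulated).empty

    def test_prioritized_subset_of_regulated(self):
        out = intersect_lirp({"a", "c"}, self.regulated)
        assert set(out.site_id) == {"a", "c"}

    def test_scores_attached_and_sorted(self):
        scores = pd.Series({"a": 0.2, "b": 0.9, "c": 0.5})
        out = intersect_lirp({"a", "b", "c"}, self.regulated, scores)
        assert list(out.site_id) == ["b", "c", "a"]
        assert list(out.score) == [0.9, 0.5, 0.2]
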