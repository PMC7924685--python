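"""Subset schedules, chains, error estimation and curve construction."""

import numpy as np
import pytest

import rankcurves as rc


@pytest.fixture
def tiny_data():
    """160 instances: a perfectly predictive feature plus five noise ones."""
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 160)
    X = np.column_stack([y] + [rng.integers(0, 2, 160) for _ in range(5)])
    return rc.LabeledDataset(
        X=X, y=y, feature_names=[f"f{i}" for i in range(6)]
    )


@pytest.fixture
def fast_cv():
    return rc.CVSpec(repeats=2, folds=3, seed=4)


TREE = rc.LearnerSpec("decision_tree")


class TestDeltaSchedule:
    @pytest.mark.parametrize(
        "i, n, expected", [(10, 100, 1), (50, 600, 1), (60, 600, 5), (501, 12_625, 631)]
    )
    def test_step_sizes(self, i, n, expected):
        assert rc.delta_schedule(i, n) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rc.delta_schedule(0, 10)
        with pytest.raises(ValueError):
            rc.delta_schedule(11, 10)


class TestScheduleSizes:
    def test_full(self):
        assert rc.schedule_sizes(4, "full") == [1, 2, 3, 4]

    def test_auto_switches_on_dimensionality(self):
        assert rc.schedule_sizes(100, "auto") == list(range(1, 101))
        assert len(rc.schedule_sizes(600, "auto")) < 600

    @pytest.mark.parametrize("n", [60, 600, 1_200])
    def test_delta_chain_ends_exactly_at_n(self, n):
        sizes = rc.schedule_sizes(n, "delta")
        assert sizes[0] == 1 and sizes[-1] == n
        assert all(b > a for a, b in zip(sizes, sizes[1:]))

    def test_explicit_sizes_get_n_appended(self):
        assert rc.schedule_sizes(10, [2, 5]) == [2, 5, 10]


class TestSubsetChain:
    def test_ffa_definition(self):
        r = rc.FeatureRanking(features=("A", "B", "C"), order=np.array([0, 1, 2]))
        assert rc.subset_chain(r, "FFA", "full") == [["A"], ["A", "B"], ["A", "B", "C"]]

    def test_rfa_definition(self):
        r = rc.FeatureRanking(features=("A", "B", "C"), order=np.array([0, 1, 2]))
        assert rc.subset_chain(r, "RFA", "full") == [["C"], ["C", "B"], ["C", "B", "A"]]

    def test_ffa_and_rfa_partition_the_features(self):
        r = rc.random_ranking(9, seed=1)
        ffa = rc.subset_chain(r, "FFA", "full")
        rfa = rc.subset_chain(r, "RFA", "full")
        n = 9
        for i in range(1, n):
            assert set(ffa[n - i - 1]) | set(rfa[i - 1]) == set(r.features)
            assert not set(ffa[n - i - 1]) & set(rfa[i - 1])

    def test_unknown_curve_type(self):
        with pytest.raises(ValueError):
            rc.subset_chain(rc.random_ranking(3, seed=0), "FFB")


class TestEstimateError:
    def test_perfect_feature_scores_one(self, tiny_data, fast_cv):
        acc, se = rc.estimate_error(tiny_data, ["f0"], TREE, fast_cv)
        assert acc == 1.0 and se == 0.0

    def test_noise_only_subset_is_chance_level(self, tiny_data, fast_cv):
        acc, se = rc.estimate_error(tiny_data, ["f3", "f4", "f5"], TREE, fast_cv)
        assert abs(acc - 0.5) < max(3 * se, 0.15)

    def test_deterministic(self, tiny_data, fast_cv):
        a = rc.estimate_error(tiny_data, ["f1", "f2"], TREE, fast_cv)
        b = rc.estimate_error(tiny_data, ["f1", "f2"], TREE, fast_cv)
        assert a == b

    def test_empty_subset_rejected(self, tiny_data, fast_cv):
        with pytest.raises(ValueError, match="empty"):
            rc.estimate_error(tiny_data, [], TREE, fast_cv)


class TestBuildCurve:
    def test_curves_share_their_last_point(self, tiny_data, fast_cv):
        """FFA and RFA both end on the full feature set: with shared folds
        the values agree exactly."""
        r = rc.random_ranking(6, seed=2, features=tuple(tiny_data.feature_names))
        ffa = rc.build_curve(tiny_data, r, "FFA", TREE, fast_cv, "full")
        rfa = rc.build_curve(tiny_data, r, "RFA", TREE, fast_cv, "full")
        assert ffa.values[-1] == rfa.values[-1]

    def test_point_count_matches_schedule(self, tiny_data, fast_cv):
        r = rc.random_ranking(6, seed=3, features=tuple(tiny_data.feature_names))
        curve = rc.build_curve(tiny_data, r, "FFA", TREE, fast_cv, [2, 4])
        assert list(curve.sizes) == [2, 4, 6]
        assert len(curve) == 3

    def test_error_rate_metric_is_complement(self, tiny_data, fast_cv):
        r = rc.random_ranking(6, seed=3, features=tuple(tiny_data.feature_names))
        acc = rc.build_curve(tiny_data, r, "FFA", TREE, fast_cv, [3])
        err = rc.build_curve(
            tiny_data, r, "FFA", TREE, fast_cv, [3], metric="error_rate"
        )
        assert np.allclose(acc.values + err.values, 1.0)

    def test_mismatched_features_rejected(self, tiny_data, fast_cv):
        r = rc.random_ranking(6, seed=0)  # default F1.. names
        with pytest.raises(ValueError, match="match"):
            rc.build_curve(tiny_data, r, "FFA", TREE, fast_cv)


class TestExpectedCurve:
    def test_m_one_reduces_to_a_single_random_ranking(self, tiny_data, fast_cv):
        seed = 17
        exp = rc.expected_curve(tiny_data, "FFA", TREE, fast_cv, "full", m=1, seed=seed)
        inner_seed = np.random.default_rng(seed).integers(2**31)
        r = rc.random_ranking(
            6, seed=inner_seed, features=tuple(tiny_data.feature_names)
        )
        direct = rc.build_curve(tiny_data, r, "FFA", TREE, fast_cv, "full")
        assert np.array_equal(exp.values, direct.values)

    def test_final_point_is_the_full_set_error(self, tiny_data, fast_cv):
        exp = rc.expected_curve(tiny_data, "FFA", TREE, fast_cv, "full", m=3, seed=5)
        full, _ = rc.estimate_error(
            tiny_data, tiny_data.feature_names, TREE, fast_cv
        )
        assert exp.values[-1] == pytest.approx(full)
        assert exp.std_errors[-1] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_m(self, tiny_data, fast_cv):
        with pytest.raises(ValueError):
            rc.expected_curve(tiny_data, "FFA", TREE, fast_cv, m=0)


def test_learner_and_cv_validation():
    with pytest.raises(ValueError):
        rc.LearnerSpec("perceptron")
    with pytest.raises(ValueError):
        rc.CVSpec(folds=1)
    curve = rc.ErrorCurve("FFA", [1, 2], [0.5, 0.6], [0.0, 0.0])
    with pytest.raises(ValueError):
        rc.ErrorCurve("FFA", [2, 2], [0.5, 0.6], [0.0, 0.0])
    assert np.allclose(curve.as_metric("error_rate"), [0.5, 0.4])
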