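"""The four baseline rankers: scores, orderings, method-separating behavior."""

import numpy as np
import pytest

import rankcurves as rc
from rankcurves.dataset import LabeledDataset

from conftest import relevant_features


def make_data(X, y, types=None):
    X = np.asarray(X)
    return LabeledDataset(
        X=X,
        y=np.asarray(y),
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        feature_types=types,
    )


class TestInfoGain:
    def test_perfect_feature_scores_one_bit(self):
        y = np.tile([0, 1], 50)
        rng = np.random.default_rng(0)
        data = make_data(np.column_stack([y, rng.integers(0, 2, 100)]), y)
        s = rc.info_gain(data)
        assert s["f0"] == pytest.approx(1.0)

    def test_contingency_table_value(self):
        # 2x2 table with counts (30,10 / 10,30): H(1/2) - H(1/4) bits
        f = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        s = rc.info_gain(make_data(f[:, None], y))
        expected = 1.0 - (-(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75)))
        assert s["f0"] == pytest.approx(expected, abs=1e-10)
        assert s["f0"] == pytest.approx(0.1887, abs=5e-4)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 1_000)
        data = make_data(rng.integers(0, 2, (1_000, 1)), y)
        assert rc.info_gain(data)["f0"] < 0.01

    def test_constant_target_warns_and_zeroes(self):
        data = make_data(np.eye(4), np.zeros(4))
        with pytest.warns(UserWarning, match="constant target"):
            s = rc.info_gain(data)
        assert np.all(s.values == 0)

    def test_numeric_feature_discretized(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 400)
        x = y + rng.normal(0, 0.3, 400)  # informative numeric feature
        data = make_data(x[:, None], y, types=["numeric"])
        assert rc.info_gain(data)["f0"] > 0.3


class TestReliefF:
    def test_perfect_feature_gets_top_weight(self, small_data):
        # small_data's first column agrees with y 90% of the time
        s = rc.relieff(small_data, seed=0)
        assert np.argmax(s.values) == 0

    def test_xor_members_positive_info_gain_blind(self, small_data):
        """The method-separating behavior: ReliefF credits both members of
        an XOR pair, univariate information gain sees noise."""
        rel = rc.relieff(small_data, seed=0)
        ig = rc.info_gain(small_data)
        noise = [f for f in small_data.feature_names if f.startswith("noise")]
        for member in ("g2c1a", "g2c1b"):
            assert rel[member] > 0
            assert rel[member] > max(rel[f] for f in noise)
            assert ig[member] < 0.01

    def test_duplicated_noise_columns_weighted_alike(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        noise = rng.integers(0, 2, 300)
        signal = np.where(rng.random(300) < 0.9, y, 1 - y)
        data = make_data(np.column_stack([signal, noise, noise]), y)
        s = rc.relieff(data, seed=0)
        assert s["f1"] == pytest.approx(s["f2"], abs=1e-9)

    def test_deterministic(self, small_data):
        a = rc.relieff(small_data, seed=5)
        b = rc.relieff(small_data, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_bad_neighbor_count(self, small_data):
        with pytest.raises(ValueError):
            rc.relieff(small_data, n_neighbors=0)


class TestRandomForest:
    def test_perfect_feature_on_top(self, small_data):
        s = rc.random_forest_importance(small_data, seed=0)
        assert np.argmax(s.values) == 0

    def test_pure_noise_importances_exchangeable(self):
        """On noise-only data no feature should be systematically favored."""
        from scipy.stats import kruskal

        per_seed = []
        for seed in range(20):
            rng = np.random.default_rng(1_000 + seed)
            y = rng.integers(0, 2, 200)
            data = make_data(rng.integers(0, 2, (200, 8)), y)
            per_seed.append(rc.random_forest_importance(data, seed=seed).values)
        per_feature = np.array(per_seed).T  # (features, seeds)
        assert kruskal(*per_feature).pvalue > 0.01

    def test_combined_spec_separation(self, combined_data, combined_gt):
        """Relevant features dominate the top of the forest ranking; the
        individually correlated ones are always recovered, most xor
        members too."""
        rel = relevant_features(combined_gt)
        singles = {f for f in rel if not f[-1].isalpha()}
        ranking = rc.ranking_from_scores(
            rc.random_forest_importance(combined_data, seed=0)
        )
        top27 = set(ranking.top(27))
        assert singles <= top27
        assert len(top27 & rel) >= 12

    def test_deterministic(self, small_data):
        a = rc.random_forest_importance(small_data, seed=2)
        b = rc.random_forest_importance(small_data, seed=2)
        assert np.array_equal(a.values, b.values)


class TestSVMRFE:
    def test_noise_eliminated_first(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        data = make_data(np.column_stack([y, rng.integers(0, 2, 200)]), y)
        ranking = rc.svm_rfe(data)
        assert ranking.ordered_features == ["f0", "f1"]

    def test_outputs_full_permutation(self, small_data):
        ranking = rc.svm_rfe(small_data)
        assert sorted(ranking.ordered_features) == sorted(small_data.feature_names)

    def test_chunked_elimination_still_a_permutation(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 120)
        X = rng.integers(0, 2, (120, 30)).astype(float)
        X[:, 0] = y
        est = rc.SVMRFERanker(chunk_threshold=10).fit(X, y)
        assert sorted(est.ranking_) == list(range(1, 31))
        assert est.ranking_[0] == 1  # the perfect feature survives longest


class TestSingleSpecRecovery:
    """Individually correlated features are easy: every ranker finds
    (nearly) all of them near the top."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_rankers_recover_singles(self, seed):
        spec = rc.standard_spec("single")
        data = rc.generate(spec, seed=seed)
        rel = relevant_features(rc.ground_truth_relevance(spec))
        rankings = {
            "info_gain": rc.ranking_from_scores(rc.info_gain(data)),
            "relieff": rc.ranking_from_scores(rc.relieff(data, seed=seed)),
            "random_forest": rc.ranking_from_scores(
                rc.random_forest_importance(data, seed=seed)
            ),
            "svm_rfe": rc.rank_dataset(data, "svm_rfe"),
        }
        for name, ranking in rankings.items():
            in_top9 = len(set(ranking.top(9)) & rel)
            in_top15 = len(set(ranking.top(15)) & rel)
            assert in_top9 >= 7, name
            assert in_top15 >= 8, name


def test_ranker_spec_validation():
    with pytest.raises(ValueError, match="unknown ranker"):
        rc.RankerSpec("chi2")
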