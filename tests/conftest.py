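"""Shared fixtures.

The heavyweight objects (the 1,000 x 100 combined benchmark and the
rankings computed on it) are session-scoped so the expensive rankers run
once for the whole suite.
"""

import numpy as np
import pytest

import rankcurves as rc


@pytest.fixture(scope="session")
def combined_spec():
    return rc.standard_spec("combined")


@pytest.fixture(scope="session")
def combined_data(combined_spec):
    return rc.generate(combined_spec, seed=1)


@pytest.fixture(scope="session")
def combined_gt(combined_spec):
    return rc.ground_truth_relevance(combined_spec)


@pytest.fixture(scope="session")
def combined_gt_ranking(combined_gt):
    return rc.ranking_from_scores(combined_gt)


@pytest.fixture(scope="session")
def relieff_ranking(combined_data):
    return rc.ranking_from_scores(rc.relieff(combined_data, seed=0))


@pytest.fixture(scope="session")
def info_gain_ranking(combined_data):
    return rc.ranking_from_scores(rc.info_gain(combined_data))


@pytest.fixture(scope="session")
def reduced_cv():
    """3x3 repeated stratified CV: the desk-scale evaluation setting."""
    return rc.CVSpec(repeats=3, folds=3, seed=0)


@pytest.fixture
def small_data():
    """A fast 240-instance dataset: one strong single feature, one xor
    pair, six noise features."""
    spec = rc.SyntheticSpec(
        groups=(
            (rc.InteractionGroup("single", 0.9), 1),
            (rc.InteractionGroup("xor", 0.9), 1),
        ),
        n_irrelevant=6,
        n_instances=240,
    )
    return rc.generate(spec, seed=7)


def relevant_features(scores):
    """Names of the features with strictly positive ground-truth relevance."""
    return set(np.array(scores.features)[scores.values > 0])
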