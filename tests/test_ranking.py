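import numpy as np
import pytest

from clopisig import (
    GenotypeMatrix,
    RankingConfig,
    aggregate_counts,
    bootstrap_splits,
    consensus_rank,
    rank_one,
)
from clopisig.io import MISSING
from clopisig.ranking import impute_mode


def labels_balanced(n):
    return np.arange(n) % 2


def test_split_sizes_and_disjointness():
    """100 subjects at 80% training -> 80/20 every iteration, disjoint."""
    y = labels_balanced(100)
    cfg = RankingConfig(n_iterations=25, seed=0)
    splits = bootstrap_splits(y, cfg)
    assert len(splits) == 25
    for train, val in splits:
        assert len(train) == 80 and len(val) == 20
        assert len(np.intersect1d(train, val)) == 0
        # stratified: label proportions in train within 1 subject of overall
        assert abs(y[train].sum() - 0.5 * len(train)) <= 1


def test_split_seed_determinism():
    y = labels_balanced(60)
    cfg = RankingConfig(n_iterations=10, seed=42)
    s1 = bootstrap_splits(y, cfg)
    s2 = bootstrap_splits(y, cfg)
    for (t1, v1), (t2, v2) in zip(s1, s2):
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(v1, v2)


def test_split_errors():
    with pytest.raises(ValueError, match="at least 10"):
        bootstrap_splits(np.array([0, 1, 0, 1]), RankingConfig())
    with pytest.raises(ValueError, match="2 subjects"):
        bootstrap_splits(np.array([0] * 11 + [1]), RankingConfig())


def test_with_replacement_mode():
    y = labels_balanced(50)
    cfg = RankingConfig(n_iterations=5, seed=1, with_replacement=True)
    saw_duplicate = False
    for train, val in bootstrap_splits(y, cfg):
        assert len(np.intersect1d(train, val)) == 0
        if len(np.unique(train)) < len(train):
            saw_duplicate = True
    assert saw_duplicate


def test_impute_mode_fills_with_majority_genotype():
    calls = np.array([[0, 1], [0, MISSING], [2, 1], [0, MISSING]], dtype=np.int8)
    X = impute_mode(calls)
    assert X[1, 1] == 1.0 and X[3, 1] == 1.0
    assert X[:, 0].tolist() == [0, 0, 2, 0]


@pytest.mark.parametrize("method", ["forest", "svm", "lasso"])
def test_perfect_separator_ranked_first(method):
    """A SNP that perfectly separates the labels outranks 50 null SNPs for
    every learner."""
    rng = np.random.default_rng(7)
    n = 60
    y = labels_balanced(n)
    X = rng.integers(0, 3, size=(n, 51)).astype(float)
    X[:, 17] = y * 2  # the separating SNP
    order = rank_one(X, y, method, random_state=0)
    assert order[0] == 17


def test_identical_features_tie_broken_by_index():
    X = np.ones((40, 5))
    y = labels_balanced(40)
    order = rank_one(X, y, "svm", random_state=0)
    assert order.tolist() == [0, 1, 2, 3, 4]


def test_null_planted_rank_is_central():
    """With shuffled labels the 'planted' SNP's mean normalized rank sits
    near the middle (no leakage through the ranking machinery)."""
    rng = np.random.default_rng(11)
    n, p = 40, 20
    ranks = []
    for _ in range(40):
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        y = rng.permutation(labels_balanced(n))
        order = rank_one(X, y, "forest", random_state=0)
        ranks.append(np.flatnonzero(order == 0)[0] / (p - 1))
    assert 0.3 < np.mean(ranks) < 0.7


def test_aggregate_counts_and_ties():
    snps = ["rsA", "rsB", "rsC"]
    top_sets = [
        {"forest": ["rsA", "rsB"], "svm": ["rsA", "rsC"]},
        {"forest": ["rsA", "rsC"], "svm": ["rsA", "rsB"]},
    ]
    ranking = aggregate_counts(top_sets, snps, ["forest", "svm"], top_k=2)
    assert ranking.counts["rsA"] == 4            # in every (iteration, method) set
    assert ranking.counts["rsB"] == 2 and ranking.counts["rsC"] == 2
    assert ranking.order == ["rsA", "rsB", "rsC"]  # tie broken by ascending id
    assert ranking.counts.sum() == 2 * 2 * 2


def test_consensus_rank_end_to_end(small_cohort):
    """Planted SNPs accumulate the top counts; the count total is conserved
    and identical seeds give identical rankings."""
    matrix, pheno, causal = small_cohort
    labels = pheno.df["case"].to_numpy(int)
    cfg = RankingConfig(n_iterations=10, top_k=10, seed=5)
    r1 = consensus_rank(matrix, labels, cfg)
    assert r1.counts.sum() == 10 * 3 * 10
    assert set(causal) <= set(r1.top(10))
    r2 = consensus_rank(matrix, labels, cfg)
    assert r1.counts.equals(r2.counts)


def test_config_validation():
    with pytest.raises(ValueError, match="train_fraction"):
        RankingConfig(train_fraction=1.0).validate()
    with pytest.raises(ValueError, match="methods"):
        RankingConfig(methods=()).validate()
    with pytest.raises(ValueError, match="top_k"):
        RankingConfig(top_k=50).validate(n_snps=20)
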