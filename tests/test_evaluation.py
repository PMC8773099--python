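import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from clopisig import (
    GenotypeMatrix,
    RankingConfig,
    bootstrap_splits,
    evaluate_curve,
    genotype_frequency_test,
    select_signature,
)
from clopisig.evaluation import EvalCurve
from clopisig.io import MISSING


def make_matrix(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        subject_ids=np.array([f"s{i}" for i in range(calls.shape[0])], dtype=object),
        snp_ids=np.array([f"rs{j}" for j in range(calls.shape[1])], dtype=object),
        calls=calls,
    )


def test_separable_signature_is_perfect():
    """With a perfectly separating SNP ranked first, AUC and accuracy are
    1.0 at every feature count."""
    rng = np.random.default_rng(0)
    n = 80
    y = np.arange(n) % 2
    calls = rng.integers(0, 3, size=(n, 5))
    calls[:, 0] = y * 2
    m = make_matrix(calls)
    splits = bootstrap_splits(y, RankingConfig(n_iterations=5, seed=1))
    curve = evaluate_curve(m, y, list(m.snp_ids), splits,
                           models=("forest", "tree"), max_features=3)
    assert (curve.table["auc"] == 1.0).all()
    assert (curve.table["accuracy"] == 1.0).all()
    assert curve.selected_feature_count == 1


def test_null_auc_is_central():
    """Labels independent of genotypes give AUC near 0.5."""
    rng = np.random.default_rng(3)
    aucs = []
    for seed in range(10):
        calls = rng.integers(0, 3, size=(200, 4))
        y = rng.permutation(np.arange(200) % 2)
        m = make_matrix(calls)
        splits = bootstrap_splits(y, RankingConfig(n_iterations=4, seed=seed))
        curve = evaluate_curve(m, y, list(m.snp_ids), splits,
                               models=("forest",), max_features=3)
        aucs.append(curve.table["auc"].mean())
    assert abs(np.mean(aucs) - 0.5) < 0.1


def curve_from(rows):
    return EvalCurve(table=pd.DataFrame(rows, columns=["model", "k", "auc", "accuracy"]))


def test_select_signature_rules():
    """Smallest k within tolerance of the best AUC; flat curves pick k=1,
    monotone curves pick the maximum k."""
    monotone = curve_from([("svm", k, 0.5 + 0.05 * k, 0.5) for k in range(1, 6)])
    assert select_signature(monotone)[1] == 5
    flat = curve_from([("svm", k, 0.9, 0.9) for k in range(1, 6)])
    assert select_signature(flat)[1] == 1
    plateau = curve_from(
        [("svm", 1, 0.70, 0.7), ("svm", 2, 0.85, 0.8), ("svm", 3, 0.96, 0.9),
         ("svm", 4, 0.962, 0.9), ("svm", 5, 0.958, 0.9)]
    )
    assert select_signature(plateau, tolerance=0.005)[1] == 3


def test_select_signature_model_tie_breaks_alphabetical():
    rows = [("svm", 1, 0.9, 0.9), ("forest", 1, 0.9, 0.9), ("tree", 1, 0.8, 0.8)]
    model, k, _ = select_signature(curve_from(rows))
    assert (model, k) == ("forest", 1)


def test_select_signature_deterministic():
    rows = [("svm", k, 0.8 + 0.01 * (k % 3), 0.8) for k in range(1, 8)]
    first = select_signature(curve_from(rows))
    assert all(select_signature(curve_from(rows)) == first for _ in range(3))


def test_max_features_exceeding_ranked_snps_errors():
    m = make_matrix(np.zeros((20, 2)))
    y = np.arange(20) % 2
    splits = bootstrap_splits(y, RankingConfig(n_iterations=2, seed=0))
    with pytest.raises(ValueError, match="max_features"):
        evaluate_curve(m, y, list(m.snp_ids), splits, max_features=5)


def test_annotation_filter_restricts_sweep():
    """Only SNPs with a gene symbol enter the sweep when annotation is given."""
    rng = np.random.default_rng(5)
    n = 60
    y = np.arange(n) % 2
    calls = rng.integers(0, 3, size=(n, 4))
    calls[:, 2] = y * 2
    m = make_matrix(calls)
    ann = pd.DataFrame({"gene": ["", "", "GENE1", "GENE2"]},
                       index=pd.Index(list(m.snp_ids), name="snp_id"))
    splits = bootstrap_splits(y, RankingConfig(n_iterations=3, seed=2))
    curve = evaluate_curve(m, y, list(m.snp_ids), splits, models=("tree",),
                           max_features=2, annotation=ann)
    assert curve.selected_snps == ["rs2"]


def test_genotype_frequency_known_tables():
    """Identical distributions give chi2=0/p=1; disjoint homozygote groups
    give chi2=40 on 1 df after the empty column is dropped."""
    same = np.array([0, 1, 2, 0, 1, 2])
    labels = np.array([True] * 3 + [False] * 3)
    table, chi2, p = genotype_frequency_test(same, labels)
    assert chi2 == 0.0 and p == 1.0

    calls = np.array([0] * 20 + [2] * 20)
    labels = np.array([True] * 20 + [False] * 20)
    table, chi2, p = genotype_frequency_test(calls, labels)
    np.testing.assert_array_equal(table, [[20, 0, 0], [0, 0, 20]])
    assert chi2 == pytest.approx(40.0)
    assert p < 0.005


def test_genotype_frequency_untestable_and_missing():
    calls = np.array([1, 1, MISSING, 1])
    labels = np.array([True, True, False, False])
    _, chi2, p = genotype_frequency_test(calls, labels)
    assert np.isnan(chi2) and np.isnan(p)
    with pytest.raises(ValueError, match="non-empty"):
        genotype_frequency_test(np.array([1, 1]), np.array([True, True]))


def test_auc_rank_statistic_equals_trapezoid():
    """The rank-based AUC equals trapezoidal ROC integration."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        y = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            continue
        s = rng.normal(size=50)
        # trapezoidal integration of the empirical ROC curve
        order = np.argsort(-s, kind="stable")
        tp = np.cumsum(y[order])
        fp = np.cumsum(1 - y[order])
        tpr = np.concatenate([[0], tp / y.sum()])
        fpr = np.concatenate([[0], fp / (len(y) - y.sum())])
        trap = np.trapezoid(tpr, fpr)
        assert roc_auc_score(y, s) == pytest.approx(trap, abs=1e-9)
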