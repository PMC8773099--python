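import numpy as np
import pytest
from scipy import stats

from clopisig import allele_table, associate, chi2_test, filter_associations, odds_ratio
from clopisig.io import MISSING


def test_allele_table_counts():
    """Alt-allele counts per arm are sums of additive codes; missing calls
    are excluded pairwise."""
    calls = np.array([2, 2, 1, 0, 0, 1])
    labels = np.array([True, True, True, False, False, False])
    np.testing.assert_array_equal(allele_table(calls, labels), [[5, 1], [1, 5]])

    het = np.array([1, 1, 1, 1])
    tab = allele_table(het, np.array([True, True, False, False]))
    np.testing.assert_array_equal(tab[0], tab[1])

    with_missing = np.array([2, MISSING, 0, 1])
    tab = allele_table(with_missing, np.array([True, True, False, False]))
    np.testing.assert_array_equal(tab, [[2, 0], [1, 3]])


def test_allele_table_untestable_arm():
    calls = np.array([MISSING, MISSING, 1, 2])
    assert allele_table(calls, np.array([True, True, False, False])) is None


def test_chi2_known_values():
    chi2, p = chi2_test([[10, 10], [10, 10]])
    assert chi2 == 0.0 and p == 1.0
    chi2, p = chi2_test([[30, 10], [10, 30]])
    assert chi2 == pytest.approx(20.0, abs=1e-12)   # 80 * 800^2 / 40^4
    assert p == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-12)
    assert p == pytest.approx(7.7e-6, rel=0.01)


def test_chi2_zero_margin_untestable():
    chi2, p = chi2_test([[0, 0], [5, 5]])
    assert np.isnan(chi2) and np.isnan(p)


def test_chi2_matches_pearson_oracle():
    """Formula agrees with the expected-count Pearson statistic from scipy
    on 1,000 random tables to 1e-10."""
    rng = np.random.default_rng(0)
    checked = 0
    while checked < 1000:
        t = rng.integers(0, 50, size=(2, 2))
        if t.sum(0).min() == 0 or t.sum(1).min() == 0:
            continue
        chi2, p = chi2_test(t)
        ref_chi2, ref_p, _, _ = stats.chi2_contingency(t, correction=False)
        assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)
        checked += 1


def test_label_swap_symmetry():
    """Swapping both row and column labels leaves chi2/p unchanged and maps
    the odds ratio to its reciprocal under a row swap."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        t = rng.integers(1, 40, size=(2, 2))
        swapped = t[::-1, ::-1]
        assert chi2_test(t) == pytest.approx(chi2_test(swapped))
        assert odds_ratio(t) == pytest.approx(odds_ratio(swapped))
        assert odds_ratio(t[::-1]) == pytest.approx(1.0 / odds_ratio(t))


def test_odds_ratio_values():
    assert odds_ratio([[30, 10], [10, 30]]) == pytest.approx(9.0)
    assert odds_ratio([[10, 10], [10, 10]]) == pytest.approx(1.0)
    # Haldane-Anscombe: zero cell pulls all cells up by 0.5
    assert odds_ratio([[5, 0], [5, 5]]) == pytest.approx(11.0)
    assert np.isfinite(odds_ratio([[5, 0], [0, 5]]))


def test_filter_strict_boundaries():
    import pandas as pd

    rec = pd.DataFrame(
        {
            "p": [0.04, 0.04, 0.05, 0.01],
            "odds_ratio": [12.0, 5.0, 12.0, 10.0],
            "untestable": [False, False, False, False],
        },
        index=["keep", "low_or", "boundary_p", "boundary_or"],
    )
    kept = filter_associations(rec, alpha=0.05, or_threshold=10.0)
    assert list(kept.index) == ["keep"]


def test_untestable_never_retained():
    import pandas as pd

    rec = pd.DataFrame(
        {"p": [np.nan], "odds_ratio": [np.nan], "untestable": [True]},
        index=["bad"],
    )
    assert len(filter_associations(rec)) == 0


def test_associate_full_cohort(small_cohort):
    """Planted SNPs dominate the case/control scan on the shared cohort."""
    matrix, pheno, causal = small_cohort
    rec = associate(matrix, pheno, contrast="case-control")
    assert len(rec) == matrix.n_snps
    assert set(rec["p"].nsmallest(3).index) == set(causal)
    # resistance contrast runs on the same cohort (labels known for everyone)
    rec_res = associate(matrix, pheno, contrast="resistance")
    assert rec_res["p"].notna().sum() > 0
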