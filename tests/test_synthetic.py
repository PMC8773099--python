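import numpy as np
import pytest

from clopisig import CohortSpec, associate, generate_cohort
from clopisig.synthetic import CohortSpecError, case_frequency


def test_seed_determinism():
    spec = CohortSpec(n_snps=200, seed=7)
    m1, p1, c1 = generate_cohort(spec)
    m2, p2, c2 = generate_cohort(spec)
    assert m1.equals(m2)
    assert p1.df.equals(p2.df)
    assert c1 == c2


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"n_cases": 0}, "n_cases"),
        ({"n_causal": 50, "n_snps": 10}, "n_causal"),
        ({"causal_or": 0.0}, "causal_or"),
        ({"maf_range": (0.4, 0.1)}, "maf_range"),
        ({"maf_range": (0.0, 0.3)}, "maf_range"),
        ({"missing_rate": 1.0}, "missing_rate"),
        ({"pru_sd": 0.0}, "pru_sd"),
    ],
)
def test_invalid_spec_names_field(kwargs, field):
    with pytest.raises(CohortSpecError, match=field):
        generate_cohort(CohortSpec(**kwargs))


def test_case_frequency_inversion():
    """The planted case frequency reproduces the target allelic odds ratio."""
    p = np.array([0.05, 0.2, 0.4])
    q = case_frequency(p, 15.0)
    odds_ratio = (q / (1 - q)) / (p / (1 - p))
    np.testing.assert_allclose(odds_ratio, 15.0, rtol=1e-12)
    np.testing.assert_allclose(case_frequency(p, 1.0), p)


def test_control_allele_frequencies_match_drawn_maf():
    """Null control-arm frequencies sit within binomial sampling error of the
    drawn MAF (at most ~1% of SNPs outside 3 SE)."""
    spec = CohortSpec(n_controls=500, n_snps=1000, n_causal=0, missing_rate=0.0, seed=3)
    m, ph, _ = generate_cohort(spec)
    ctrl = m.calls[~ph.df["case"].to_numpy(bool)]
    freq = ctrl.mean(axis=0) / 2.0
    # re-derive the drawn frequencies from the documented stream order
    rng = np.random.default_rng(spec.seed)
    p = rng.uniform(*spec.maf_range, size=spec.n_snps)
    se = np.sqrt(p * (1 - p) / (2 * spec.n_controls))
    outside = np.abs(freq - p) > 3 * se
    assert outside.mean() <= 0.01


def test_planted_or_converges():
    """Empirical case/control odds ratio of planted SNPs approaches the
    target at 5,000 subjects per arm (within 10%)."""
    # moderate MAFs keep the OR estimator's sampling error well inside 10%
    spec = CohortSpec(
        n_cases=5000, n_controls=5000, n_snps=40, n_causal=5, causal_or=15.0,
        maf_range=(0.2, 0.5), missing_rate=0.0, seed=5,
    )
    m, ph, causal = generate_cohort(spec)
    case = ph.df["case"].to_numpy(bool)
    for snp in causal:
        j = list(m.snp_ids).index(snp)
        alt_case = m.calls[case, j].sum()
        alt_ctrl = m.calls[~case, j].sum()
        ref_case = 2 * case.sum() - alt_case
        ref_ctrl = 2 * (~case).sum() - alt_ctrl
        emp_or = (alt_case * ref_ctrl) / (ref_case * alt_ctrl)
        assert emp_or == pytest.approx(15.0, rel=0.10)


def test_missingness_rate():
    spec = CohortSpec(n_snps=500, missing_rate=0.05, seed=9)
    m, _, _ = generate_cohort(spec)
    frac = m.missing_mask.mean()
    se = np.sqrt(0.05 * 0.95 / m.calls.size)
    assert abs(frac - 0.05) <= 3 * se


def test_pru_consistent_with_resistance():
    """Resistance labels are recomputed from PRU, never stored independently."""
    m, ph, _ = generate_cohort(CohortSpec(n_snps=50, seed=2))
    df = ph.df
    assert ((df["pru"] > 234) == df["resistance"].astype(bool)).all()
    assert (df["pru"] >= 0).all()


def test_planted_snps_have_smallest_association_p():
    """With a strong effect and 500/arm, the 3 planted SNPs carry the three
    smallest case/control association p-values."""
    spec = CohortSpec(
        n_cases=500, n_controls=500, n_snps=500, n_causal=3, causal_or=15.0, seed=13
    )
    m, ph, causal = generate_cohort(spec)
    rec = associate(m, ph, contrast="case-control")
    assert set(rec["p"].nsmallest(3).index) == set(causal)
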