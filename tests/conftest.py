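import numpy as np
import pandas as pd
import pytest

from clopisig import CohortSpec, GenotypeMatrix, PhenotypeTable, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """64/64 cohort with 3 strong planted SNPs; shared read-only across tests."""
    spec = CohortSpec(n_snps=300, n_causal=3, causal_or=15.0, seed=1)
    matrix, pheno, causal = generate_cohort(spec)
    return matrix, pheno, causal


def random_matrix(seed: int, n_subjects: int = 10, n_snps: int = 8) -> GenotypeMatrix:
    """Small random genotype matrix with some missing calls, for round-trips."""
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(n_subjects, n_snps)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.15] = -1
    return GenotypeMatrix(
        subject_ids=np.array([f"s{i}" for i in range(n_subjects)], dtype=object),
        snp_ids=np.array([f"rs{j}" for j in range(n_snps)], dtype=object),
        calls=calls,
    )


@pytest.fixture
def tiny_pheno():
    return PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": ["s0", "s1", "s2", "s3"],
                "group": ["I", "II", "IV", "IV"],
                "case": [True, True, False, False],
                "pru": [250.0, 200.0, np.nan, np.nan],
                "resistance": pd.array([True, False, pd.NA, pd.NA], dtype="boolean"),
            }
        )
    )
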