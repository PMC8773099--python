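"""Synthetic case/control genotype cohorts with planted resistance SNPs.

The generator emulates a pharmacogenomic case/control design: diabetic PAD
patients on clopidogrel (cases) versus age/sex-matched healthy controls,
genotyped on a large SNP array (emulated at a reduced SNP count).  Null SNPs
share one allele frequency in both arms; planted ("causal") SNPs get a case
allele frequency derived from the control frequency and a target allelic
odds ratio.  Each subject also receives a platelet-reactivity (PRU)
phenotype drawn from a resistant-mean component for cases and a
sensitive-mean component for controls, so that the PRU > 234 resistance
rule approximately recovers the case/control split.

Genotypes are Hardy-Weinberg (per-allele binomial) and independent across
SNPs; linkage disequilibrium and population structure are deliberately not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, PRU_RESISTANCE_THRESHOLD, GenotypeMatrix, PhenotypeTable

#: Gene symbols assigned to planted SNPs (cycled), chosen to overlap the
#: packaged synthetic PPI edge list so a full pipeline run can build a
#: connected subnetwork.
DEFAULT_CAUSAL_GENES = ("IQSEC1", "PSD3", "BTBD7", "GLIS3", "LRBA",
                        "WASHC3", "SLC37A2", "PRDM11", "CNR1")

#: Decoy symbols occasionally assigned to null SNPs.
DEFAULT_DECOY_GENES = ("ACTN4", "TP53", "EGFR", "MYC", "BRCA1", "KRAS")


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case/control cohort.

    Defaults reflect the study design being emulated: 64 patients and 64
    matched controls, array genotyping (SNP count reduced), strong planted
    allelic effects, and PRU phenotypes dichotomized at >234.
    """

    n_cases: int = 64
    n_controls: int = 64
    n_snps: int = 2000
    n_causal: int = 5
    causal_or: float = 15.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    pru_mean_resistant: float = 290.0
    pru_mean_sensitive: float = 170.0
    pru_sd: float = 45.0
    seed: int = 0
    annotated_fraction: float = 0.3
    causal_genes: Sequence[str] = field(default=DEFAULT_CAUSAL_GENES)

    def validate(self) -> None:
        if self.n_cases < 1:
            raise CohortSpecError("n_cases must be >= 1")
        if self.n_controls < 1:
            raise CohortSpecError("n_controls must be >= 1")
        if self.n_snps < 1:
            raise CohortSpecError("n_snps must be >= 1")
        if not 0 <= self.n_causal <= self.n_snps:
            raise CohortSpecError("n_causal must satisfy 0 <= n_causal <= n_snps")
        if self.causal_or <= 0:
            raise CohortSpecError("causal_or must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise CohortSpecError("maf_range must satisfy 0 < lower <= upper <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise CohortSpecError("missing_rate must lie in [0, 1)")
        if self.pru_sd <= 0:
            raise CohortSpecError("pru_sd must be positive")
        if not 0 <= self.annotated_fraction <= 1:
            raise CohortSpecError("annotated_fraction must lie in [0, 1]")


def case_frequency(p: float | np.ndarray, odds_ratio: float) -> float | np.ndarray:
    """Case-arm allele frequency for control frequency ``p`` at a target allelic OR.

    Inverts the allelic odds relation: q/(1-q) = OR * p/(1-p).
    """
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[GenotypeMatrix, PhenotypeTable, list[str]]:
    """Generate a cohort; returns (genotypes, phenotypes, causal SNP ids).

    Identical specs (including seed) give byte-identical outputs.  The
    random stream order is fixed: allele frequencies, causal-SNP choice,
    case genotypes, control genotypes, missingness mask, PRU values, gene
    annotation — stable across releases.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    p_control = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)
    causal_idx = np.sort(rng.choice(spec.n_snps, size=spec.n_causal, replace=False))
    p_case = p_control.copy()
    p_case[causal_idx] = case_frequency(p_control[causal_idx], spec.causal_or)

    case_calls = rng.binomial(2, p_case, size=(spec.n_cases, spec.n_snps))
    ctrl_calls = rng.binomial(2, p_control, size=(spec.n_controls, spec.n_snps))
    calls = np.concatenate([case_calls, ctrl_calls]).astype(np.int8)

    if spec.missing_rate > 0:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING

    n_total = spec.n_cases + spec.n_controls
    is_case = np.concatenate(
        [np.ones(spec.n_cases, dtype=bool), np.zeros(spec.n_controls, dtype=bool)]
    )
    pru_mean = np.where(is_case, spec.pru_mean_resistant, spec.pru_mean_sensitive)
    pru = np.clip(rng.normal(pru_mean, spec.pru_sd), 0.0, None)

    subject_ids = np.array(
        [f"case{i + 1:04d}" for i in range(spec.n_cases)]
        + [f"ctrl{i + 1:04d}" for i in range(spec.n_controls)],
        dtype=object,
    )
    snp_ids = np.array([f"rs{i + 1:06d}" for i in range(spec.n_snps)], dtype=object)

    genes = np.array([""] * spec.n_snps, dtype=object)
    if spec.annotated_fraction > 0:
        annotated = rng.random(spec.n_snps) < spec.annotated_fraction
        decoys = rng.choice(DEFAULT_DECOY_GENES, size=int(annotated.sum()))
        genes[annotated] = decoys
    for k, j in enumerate(causal_idx):
        genes[j] = spec.causal_genes[k % len(spec.causal_genes)]

    meta = pd.DataFrame(
        {
            "chrom": np.asarray((np.arange(spec.n_snps) % 22) + 1, dtype=object).astype(str),
            "pos": np.arange(1, spec.n_snps + 1, dtype=np.int64) * 1000,
            "ref": ["A"] * spec.n_snps,
            "alt": ["G"] * spec.n_snps,
            "gene": genes,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    matrix = GenotypeMatrix(
        subject_ids=subject_ids, snp_ids=snp_ids, calls=calls, snp_meta=meta
    )

    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                # patients split across study arms I-III; IV = healthy controls
                "group": np.where(
                    is_case,
                    np.take(["I", "II", "III"], np.arange(n_total) % 3),
                    "IV",
                ),
                "case": is_case,
                "pru": np.round(pru, 1),
                "resistance": pd.array(np.round(pru, 1) > PRU_RESISTANCE_THRESHOLD,
                                       dtype="boolean"),
            }
        )
    )
    causal_ids = [str(snp_ids[j]) for j in causal_idx]
    return matrix, pheno, causal_ids


def write_annotation(matrix: GenotypeMatrix, path) -> None:
    """Write the SNP annotation TSV (snp_id, chrom, pos, gene) for a cohort."""
    out = matrix.snp_meta[["chrom", "pos", "gene"]].copy()
    out.to_csv(path, sep="\t")
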