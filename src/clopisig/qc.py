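"""SNP-level quality control and platelet-reactivity resistance labeling.

Two filters are applied, in a fixed priority order, over non-missing calls
pooled across both study arms:

1. monomorphic SNPs (minor allele frequency exactly 0) are removed;
2. SNPs whose missing rate is strictly greater than the threshold
   (default 10%) are removed.

Resistance labeling applies the strict PRU > 234 rule to patients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PRU_RESISTANCE_THRESHOLD, GenotypeMatrix, PhenotypeTable


@dataclass
class QCReport:
    """Accounting of the SNP filters; removal reasons are disjoint.

    ``n_input == n_removed_maf0 + n_removed_missing + n_retained``.
    """

    n_input: int
    n_removed_maf0: int
    n_removed_missing: int
    n_retained: int
    per_snp: pd.DataFrame  # snp_id index; columns maf, missing_rate, status

    def __post_init__(self) -> None:
        total = self.n_removed_maf0 + self.n_removed_missing + self.n_retained
        if total != self.n_input:
            raise ValueError("QC report counts do not add up")

    def to_json(self, path: str | Path) -> None:
        summary = {
            "n_input": self.n_input,
            "n_removed_maf0": self.n_removed_maf0,
            "n_removed_missing": self.n_removed_missing,
            "n_retained": self.n_retained,
        }
        Path(path).write_text(json.dumps(summary, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        self.per_snp.to_csv(path, sep="\t")


def snp_statistics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP minor allele frequency and missing rate (pooled arms).

    MAF is computed over non-missing calls; an all-missing SNP gets NaN.
    """
    calls = matrix.calls.astype(float)
    miss = matrix.missing_mask
    calls[miss] = np.nan
    n_nonmiss = (~miss).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        alt_freq = np.nansum(calls, axis=0) / np.maximum(2 * n_nonmiss, 1)
    alt_freq = np.where(n_nonmiss == 0, np.nan, alt_freq)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    missing_rate = miss.mean(axis=0)
    return pd.DataFrame(
        {"maf": maf, "missing_rate": missing_rate},
        index=pd.Index(matrix.snp_ids, name="snp_id"),
    )


def filter_snps(
    matrix: GenotypeMatrix, missing_threshold: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the MAF-0 and missingness filters; order of retained SNPs preserved.

    A SNP with every call missing has no defined MAF and is removed under
    the missingness rule (its missing rate is 1) with a warning.
    """
    if matrix.n_snps == 0:
        raise ValueError("empty genotype matrix")
    stats = snp_statistics(matrix)
    all_missing = stats["maf"].isna()
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} SNP(s) with all calls missing removed",
            stacklevel=2,
        )
    removed_maf0 = (stats["maf"] == 0).fillna(False)
    removed_missing = ~removed_maf0 & (stats["missing_rate"] > missing_threshold)
    retained = ~removed_maf0 & ~removed_missing

    status = np.where(removed_maf0, "removed_maf0",
                      np.where(removed_missing, "removed_missing", "retained"))
    per_snp = stats.assign(status=status)
    report = QCReport(
        n_input=matrix.n_snps,
        n_removed_maf0=int(removed_maf0.sum()),
        n_removed_missing=int(removed_missing.sum()),
        n_retained=int(retained.sum()),
        per_snp=per_snp,
    )
    kept = [s for s, keep in zip(matrix.snp_ids, retained.to_numpy()) if keep]
    return matrix.subset_snps(kept), report


def label_resistance(
    pheno: PhenotypeTable, threshold: float = PRU_RESISTANCE_THRESHOLD
) -> PhenotypeTable:
    """Label patients as clopidogrel-resistant when PRU > threshold (strict).

    Controls are left unlabeled.  Raises if any patient lacks a PRU value.
    """
    df = pheno.df.copy()
    cases = df["case"]
    no_pru = cases & df["pru"].isna()
    if no_pru.any():
        subjects = df.loc[no_pru, "subject_id"].tolist()
        raise ValueError(f"patients with missing PRU: {subjects}")
    res = pd.array([pd.NA] * len(df), dtype="boolean")
    res[cases.to_numpy()] = (df.loc[cases, "pru"] > threshold).to_numpy()
    df["resistance"] = res
    return PhenotypeTable(df, pru_threshold=threshold)
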