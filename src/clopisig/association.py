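"""Per-SNP allelic case/control association: chi-square, odds ratio, filtering.

Each SNP is reduced to a 2x2 allele-count table (alternate/reference allele
by outcome group), tested with the uncorrected 1-df Pearson chi-square, and
summarized with the cross-product odds ratio (Haldane-Anscombe 0.5 added to
all cells when any cell is zero).  The selection filter keeps SNPs with
p < alpha AND odds ratio > or_threshold, both strict.

No multiple-testing correction is applied: the screening stage of this
pipeline deliberately filters on the raw per-SNP p-value (the ranking stage
downstream, not the p-value, determines the final signature).

Two outcome contrasts are supported:

* ``"resistance"`` — clopidogrel-resistant vs non-resistant subjects
  (subjects with an unknown resistance label are excluded);
* ``"case-control"`` — patients vs healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, PhenotypeTable

CONTRASTS = ("resistance", "case-control")


@dataclass
class AssociationRecord:
    """Allelic 2x2 association summary for one SNP.

    Table layout: rows = (positive group, negative group), columns =
    (alt alleles, ref alleles); ``a, b, c, d`` in reading order.
    """

    snp_id: str
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p: float
    odds_ratio: float
    untestable: bool = False
    passes_filter: bool = False


def allele_table(calls: np.ndarray, labels: np.ndarray) -> np.ndarray | None:
    """Allele-count 2x2 table [[alt+, ref+], [alt-, ref-]] for one SNP.

    ``labels`` is boolean (True = positive group).  Missing calls are
    excluded pairwise.  Returns None (untestable) when either group has no
    non-missing subjects.
    """
    calls = np.asarray(calls)
    labels = np.asarray(labels, dtype=bool)
    ok = calls != MISSING
    table = np.empty((2, 2), dtype=np.int64)
    for i, grp in enumerate((labels, ~labels)):
        sel = ok & grp
        n = int(sel.sum())
        if n == 0:
            return None
        alt = int(calls[sel].sum())
        table[i] = (alt, 2 * n - alt)
    return table


def chi2_test(table: np.ndarray) -> tuple[float, float]:
    """Uncorrected 1-df Pearson chi-square on a 2x2 table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p is the upper tail of
    the 1-df chi-square distribution.  A zero margin makes the table
    untestable and returns (nan, nan) rather than raising.
    """
    t = np.asarray(table, dtype=np.float64)
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return (float("nan"), float("nan"))
    chi2 = n * (a * d - b * c) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def odds_ratio(table: np.ndarray, correction: float = 0.5) -> float:
    """Cross-product odds ratio ad/(bc) with Haldane-Anscombe correction.

    When any cell is zero, ``correction`` is added to all four cells first,
    so infinity is never returned for a non-degenerate table.
    """
    t = np.asarray(table, dtype=np.float64)
    if (t == 0).any():
        t = t + correction
    a, b = t[0]
    c, d = t[1]
    return float((a * d) / (b * c))


def _contrast_labels(pheno: PhenotypeTable, contrast: str) -> np.ndarray:
    """Per-subject outcome labels: True/False, or NaN-coded -1 for excluded."""
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    if contrast == "case-control":
        return pheno.df["case"].to_numpy(dtype=np.int8)
    res = pheno.df["resistance"]
    out = np.full(len(res), -1, dtype=np.int8)
    known = res.notna().to_numpy()
    out[known] = res[known].astype(bool).to_numpy()
    return out


def associate(
    matrix: GenotypeMatrix,
    pheno: PhenotypeTable,
    contrast: str = "resistance",
) -> pd.DataFrame:
    """Allelic chi-square association for every SNP in the matrix.

    Returns a DataFrame indexed by SNP id with columns
    ``a, b, c, d, chi2, p, odds_ratio, untestable``.
    """
    pheno = pheno.aligned_to(matrix)
    labels = _contrast_labels(pheno, contrast)
    keep = labels >= 0
    if keep.sum() == 0 or len(set(labels[keep])) < 2:
        raise ValueError(f"contrast {contrast!r} has fewer than two outcome groups")
    calls = matrix.calls[keep]
    lab = labels[keep].astype(bool)

    rows = []
    for j, snp in enumerate(matrix.snp_ids):
        table = allele_table(calls[:, j], lab)
        if table is None:
            rows.append((snp, 0, 0, 0, 0, np.nan, np.nan, np.nan, True))
            continue
        chi2, p = chi2_test(table)
        untestable = np.isnan(chi2)
        orr = np.nan if untestable else odds_ratio(table)
        rows.append((snp, *table.ravel(), chi2, p, orr, untestable))
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "a", "b", "c", "d", "chi2", "p", "odds_ratio", "untestable"],
    ).set_index("snp_id")
    return df


def filter_associations(
    records: pd.DataFrame, alpha: float = 0.05, or_threshold: float = 10.0
) -> pd.DataFrame:
    """Keep SNPs with p < alpha and odds ratio > or_threshold (both strict).

    Untestable SNPs are never retained.  Adds a ``passes_filter`` column and
    returns the retained subset (original order preserved).
    """
    records = records.copy()
    records["passes_filter"] = (
        ~records["untestable"].astype(bool)
        & (records["p"] < alpha)
        & (records["odds_ratio"] > or_threshold)
    )
    return records[records["passes_filter"]]


def write_association_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", na_rep="NA")
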