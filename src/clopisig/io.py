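"""Readers and writers for genotype, phenotype, annotation, and PPI edge files.

Genotypes are held as an additive-coded subjects x SNPs matrix: each call is
the count of alternate alleles (0, 1, 2) with ``MISSING`` (-1) for no-calls.
Two on-disk dialects are supported:

* a minimal GT-only VCF v4.2 (one biallelic record per SNP, samples as
  columns), read through :mod:`cyvcf2`;
* a plain TSV with subjects as rows and SNPs as columns, ``NA`` for missing.

Phenotypes, SNP annotation and protein-interaction edge lists are tab-separated
tables read with :mod:`pandas`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the additive-coded matrix.
MISSING: int = -1

#: Platelet-reactivity threshold (PRU) above which a patient on clopidogrel
#: is classified as resistant (strict inequality).
PRU_RESISTANCE_THRESHOLD: float = 234.0

VALID_GROUPS = ("I", "II", "III", "IV")

META_COLUMNS = ("chrom", "pos", "ref", "alt", "gene")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive-coded genotype matrix with SNP metadata.

    Parameters
    ----------
    subject_ids : sequence of str
        Row labels, unique.
    snp_ids : sequence of str
        Column labels, unique.
    calls : ndarray of shape (n_subjects, n_snps), dtype int8
        Alternate-allele counts; ``MISSING`` (-1) marks a no-call.
    snp_meta : DataFrame indexed by SNP id
        Columns ``chrom, pos, ref, alt, gene`` (``gene`` may be empty).
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.snp_meta is None:
            self.snp_meta = default_snp_meta(self.snp_ids)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if self.calls.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2} or MISSING")
        if not self.snp_meta.index.equals(pd.Index(self.snp_ids)):
            raise ValueError("snp_meta index must match snp_ids")

    # -- conveniences ------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_snps(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``keep`` (order preserved)."""
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(
            subject_ids=self.subject_ids.copy(),
            snp_ids=np.asarray(keep, dtype=object),
            calls=self.calls[:, idx].copy(),
            snp_meta=self.snp_meta.iloc[idx].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            list(self.subject_ids) == list(other.subject_ids)
            and list(self.snp_ids) == list(other.snp_ids)
            and np.array_equal(self.calls, other.calls)
            and self.snp_meta.reset_index(drop=True).equals(
                other.snp_meta.reset_index(drop=True)
            )
        )


def default_snp_meta(snp_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(snp_ids)
    return pd.DataFrame(
        {
            "chrom": ["1"] * len(ids),
            "pos": np.arange(1, len(ids) + 1, dtype=np.int64),
            "ref": ["A"] * len(ids),
            "alt": ["G"] * len(ids),
            "gene": [""] * len(ids),
        },
        index=pd.Index(ids, name="snp_id"),
    )


@dataclass
class PhenotypeTable:
    """Per-subject phenotype table.

    Wraps a DataFrame with columns ``subject_id``, ``group`` (study arm
    I-IV; IV = healthy controls), ``case`` (bool, patient vs control),
    ``pru`` (platelet reactivity, NaN if unmeasured) and ``resistance``
    (nullable boolean, PRU > 234 when PRU is known).  Any further columns
    are treated as covariates.
    """

    df: pd.DataFrame
    #: PRU threshold the ``resistance`` column is consistent with.
    pru_threshold: float = PRU_RESISTANCE_THRESHOLD

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = ["subject_id", "group", "case", "pru"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        if "resistance" not in df.columns:
            df["resistance"] = pd.array([pd.NA] * len(df), dtype="boolean")
        df["subject_id"] = df["subject_id"].astype(str)
        df["case"] = df["case"].astype(bool)
        df["pru"] = pd.to_numeric(df["pru"], errors="coerce")
        df["resistance"] = df["resistance"].astype("boolean")
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dup}")
        unknown = set(df["group"]) - set(VALID_GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if (df["pru"].dropna() < 0).any():
            raise ValueError("negative PRU values")
        known = df["resistance"].notna() & df["pru"].notna()
        expect = df.loc[known, "pru"] > self.pru_threshold
        got = df.loc[known, "resistance"].astype(bool)
        if not (expect == got).all():
            raise ValueError(
                f"resistance labels inconsistent with PRU > {self.pru_threshold}"
            )

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy(dtype=object)

    def aligned_to(self, matrix: GenotypeMatrix) -> "PhenotypeTable":
        """Reorder rows to match the genotype matrix's subjects exactly."""
        df = self.df.set_index("subject_id")
        missing = [s for s in matrix.subject_ids if s not in df.index]
        if missing:
            raise ValueError(f"subjects absent from phenotype table: {missing[:5]}")
        out = df.loc[list(matrix.subject_ids)].reset_index()
        return PhenotypeTable(out, pru_threshold=self.pru_threshold)


# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"


def read_genotypes(
    path: str | Path,
    format: str | None = None,
    snp_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a minimal VCF or an additive-coded TSV."""
    fmt = _infer_format(path, format)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path, snp_meta=snp_meta)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a genotype matrix; round-trips with :func:`read_genotypes`."""
    fmt = _infer_format(path, format)
    if fmt == "vcf":
        _write_vcf(matrix, path)
    elif fmt == "tsv":
        _write_tsv(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _read_tsv(path: str | Path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=["NA"],
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise GenotypeParseError(f"ragged genotype TSV {path}: {exc}") from exc
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        vals = df[col]
        ok = vals.notna()
        try:
            calls[ok.to_numpy(), j] = vals[ok].astype(int).to_numpy()
        except ValueError as exc:
            raise GenotypeParseError(f"non-integer genotype in column {col!r}") from exc
    if snp_meta is not None:
        snp_meta = snp_meta.loc[list(df.columns)]
    return GenotypeMatrix(
        subject_ids=df.index.astype(str).to_numpy(dtype=object),
        snp_ids=df.columns.astype(str).to_numpy(dtype=object),
        calls=calls,
        snp_meta=snp_meta,
    )


def _write_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.calls, index=list(matrix.subject_ids), columns=list(matrix.snp_ids)
    ).astype(object)
    df[matrix.calls == MISSING] = pd.NA
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# minimal GT-only VCF v4.2
# ---------------------------------------------------------------------------

# cyvcf2 gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
_CYVCF2_TO_ADDITIVE = {0: 0, 1: 1, 3: 2, 2: MISSING}
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    subject_ids = np.asarray(vcf.samples, dtype=object)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"multi-allelic record {var.ID or f'{var.CHROM}:{var.POS}'} not supported"
            )
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(snp_id)
        rows.append(np.array([_CYVCF2_TO_ADDITIVE[g] for g in var.gt_types], dtype=np.int8))
        meta_rows.append((str(var.CHROM), int(var.POS), var.REF, var.ALT[0], ""))
    vcf.close()
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(subject_ids), 0), dtype=np.int8)
    )
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS),
                        index=pd.Index(snp_ids, name="snp_id"))
    return GenotypeMatrix(subject_ids=subject_ids, snp_ids=np.asarray(snp_ids, dtype=object),
                          calls=calls, snp_meta=meta)


def _write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    # GT-only v4.2; one biallelic record per SNP.
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.snp_meta["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(str(s) for s in matrix.subject_ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 + ("\t" + cols if matrix.n_subjects else "") + "\n")
        for j, snp in enumerate(matrix.snp_ids):
            m = matrix.snp_meta.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{snp}\t{m['ref']}\t{m['alt']}\t.\t.\t.\tGT"
                + ("\t" + gts if matrix.n_subjects else "") + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype / annotation / edge-list tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV (subject_id, group, case, pru, covariates...).

    A ``resistance`` column, if absent, is derived as PRU > 234 for every
    subject with a measured PRU.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "resistance" not in df.columns and "pru" in df.columns:
        pru = pd.to_numeric(df["pru"], errors="coerce")
        res = pd.array(pru > PRU_RESISTANCE_THRESHOLD, dtype="boolean")
        res[pru.isna()] = pd.NA
        df["resistance"] = res
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a SNP annotation TSV (snp_id, chrom, pos, gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str},
                     keep_default_na=False)
    if "snp_id" not in df.columns:
        raise ValueError("annotation TSV must have a snp_id column")
    return df.set_index("snp_id")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column symbol-pair edge TSV; self-loops are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list must have two symbol columns")
    a, b = df.columns[:2]
    edges = []
    n_loops = 0
    for x, y in zip(df[a], df[b]):
        if x == y:
            n_loops += 1
            continue
        edges.append((str(x), str(y)))
    if n_loops:
        logger.info("dropped %d self-loop edge(s)", n_loops)
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["symbol_a", "symbol_b"]).to_csv(
        path, sep="\t", index=False
    )
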