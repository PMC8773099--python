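"""Simulate a case/control pharmacogenomic cohort with planted SNPs.

Generates 64 patients and 64 matched controls genotyped at 1,000 SNPs, three
of which carry a strong planted allelic effect (odds ratio 15), then applies
the quality-control filters.  The printed counts show how many SNPs survive
the monomorphic and 10%-missingness rules; the PRU summary shows the platelet
reactivity phenotype whose >234 threshold defines clopidogrel resistance.
"""

from clopisig import CohortSpec, filter_snps, generate_cohort

spec = CohortSpec(n_snps=1000, n_causal=3, causal_or=15.0, seed=7)
matrix, pheno, causal = generate_cohort(spec)
print(f"cohort: {matrix.n_subjects} subjects x {matrix.n_snps} SNPs")
print(f"planted SNPs: {causal}")

filtered, report = filter_snps(matrix)
print(
    f"QC: {report.n_input} in, {report.n_removed_maf0} monomorphic, "
    f"{report.n_removed_missing} high-missingness, {report.n_retained} retained"
)

patients = pheno.df[pheno.df["case"]]
print(
    f"patients: mean PRU {patients['pru'].mean():.0f}, "
    f"{patients['resistance'].astype(bool).mean():.0%} resistant (PRU > 234)"
)
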