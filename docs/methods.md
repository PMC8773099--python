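# Methods

## Data model

Genotypes are additive-coded alternate-allele counts (0/1/2) in a
subjects × SNPs matrix with an explicit missing code; all sites are
biallelic (multi-allelic VCF records are rejected rather than split,
because every downstream statistic — the allelic 2×2 table, the odds
ratio, the 2×3 genotype table — presumes two alleles).  Coordinates are
1-based as in VCF; the TSV dialect stores subjects as rows so the matrix
doubles as a learner feature table.  Phenotypes carry the study arm
(groups I–III are patients, IV healthy controls), the VerifyNow platelet
reactivity in PRU, and a resistance flag that is always derived as
PRU > 234 (strict), never stored independently — one source of truth.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: n_cases =
n_controls = 64 by default, array genotyping emulated at a reduced SNP
count (default 2,000), per-SNP missingness (default 2%), and PRU
phenotypes.  Null SNPs draw one allele frequency per SNP uniformly from
`maf_range` (default 0.05–0.5) and sample genotypes as Binomial(2, p) in
both arms (Hardy–Weinberg); planted SNPs use the allelic-odds inversion
q = OR·p/(1 − p + OR·p) for the case arm.  Defaults plant 5 SNPs at
allelic OR 15, matching the effect-size regime the strict OR > 10 screen
is designed to catch.  PRU is drawn from a resistant-mean component for
cases (290 ± 45) and a sensitive-mean component for controls (170 ± 45),
clipped at 0; with the 234 threshold roughly 9% of labels flip relative
to case status, a deliberate source of label noise.  The uniform MAF
spectrum, the absence of linkage disequilibrium, population structure and
covariate confounding are declared simplifications: passing tests show the
machinery recovers planted single-SNP effects under ideal independence,
not that it would resolve correlated signals or stratified cohorts.
A single integer seed drives one generator with a documented stream order
(frequencies, causal choice, case genotypes, control genotypes,
missingness, PRU, annotation), so outputs are byte-stable.

## QC and association screen

MAF and missing rate are computed over non-missing calls pooled across
both arms (per-arm QC is not attempted; pooled is the standard array
practice).  Removal reasons are assigned with MAF-0 taking priority over
missingness so report counts are deterministic; both thresholds are
strict inequalities, taken literally from the stated rules.  An
all-missing SNP has no defined MAF and is removed under the missingness
rule with a warning.

The association screen is allelic: one 2×2 allele-count table per SNP,
uncorrected 1-df Pearson χ², odds ratio ad/bc with the Haldane–Anscombe
0.5 correction whenever a cell is zero (infinity is never returned).  An
allelic rather than genotypic test is used because the screen filters on
a single odds ratio per SNP, which only a 2×2 defines; the genotypic 2×3
comparison is provided separately for describing the final signature.
**No multiple-testing correction is applied at the screen** — this is a
deliberate property of the pipeline being reproduced, in which the raw
p < 0.05 filter is only the first of two stages and the resampled
consensus ranking, not the p-value, determines the signature.  Two outcome
contrasts are supported (resistant vs non-resistant; patients vs
controls); the screening odds-ratio threshold defaults to the strict 10
with the permissive > 1 variant one flag away.

The orchestrated pipeline defaults to the patients-vs-controls contrast:
the generator plants patient-vs-control allelic differences, and the ~9%
resistance-label noise otherwise attenuates an OR-15 SNP to an observed
OR of 6–9 at 64 subjects per arm, starving the strict screen.  Direct
library calls default to the resistance contrast.

## Consensus ranking

"Bootstrapping" here means repeated stratified random 80/20 re-splitting
without replacement (each stratum contributes its rounded share, never
emptying either side); a classical with-replacement bootstrap of the
training set is available behind a flag.  Learner hyperparameters are
fixed, not tuned: random forest with 100 trees on raw codes (100 rather
than a larger forest because per-fit importance noise averages out over
the 100 re-splits while fit cost scales linearly), linear-kernel SVM at
unit cost and LASSO with a 20-value internally cross-validated penalty
path, both on standardized codes.  Missing genotypes are imputed by
per-SNP training-set mode before fits.  Top-set size defaults to k = 20
per learner per iteration.  All rankings break ties by ascending SNP id,
so the consensus order is reproducible; the count total always equals
iterations × learners × k.

## Signature evaluation

The sweep fits each evaluation model on the training side of reused
stratified folds, restricted to the top-k consensus SNPs, and averages
AUC and accuracy (0.5 probability threshold; decision-function sign for
margin classifiers) over the held-out folds.  Imputation for the sweep is
computed once on the full matrix — with per-SNP mode imputation and the
default 2% missingness the train/validation leakage through a modal value
is negligible, and it keeps the k×model×fold loop cheap.  "Minimum needed
feature number" is formalized as: the smallest k whose best-model AUC is
within `tolerance` (default 0.005) of the global maximum, with ties going
to fewer features and then alphabetical model order — deterministic given
a curve.  When an annotation table is supplied, SNPs without a gene
symbol are dropped before the sweep (the annotated-signature variant).
The evaluation model set defaults to forest/SVM/tree/XGBoost; a
forest/SVM/LASSO/tree variant is available since both four-model sets are
plausible readings of the workflow being reproduced.

## Clinical statistics

Fisher's exact test enumerates the hypergeometric support conditional on
both margins; the two-sided p sums point probabilities ≤ the observed one
with a 1e-7 relative tie tolerance (the convention that reproduces the
published 0.034/0.036 medication contrasts).  Degenerate margins give
p = 1 with a warning.  When every support point is included the p-value
is returned as exactly 1.  Mann–Whitney U uses midranks, exact
enumeration for combined n ≤ 12 without ties, otherwise the
tie-corrected normal approximation with continuity correction.  The
two-proportion sample size uses the pooled-variance normal approximation
without continuity correction and rounds **to the nearest integer** per
group — 70% vs 30% at α 0.05/power 0.80 gives 23.3 → 23 per group, which
matches the published design, whereas the more common ceiling convention
would give 24; enrollment is floor(n_total/(1 − loss)).  Kaplan–Meier,
log-rank and Cox modeling are out of scope: they are off-the-shelf
survival fits with no recomputable inputs here.

## Interaction subnetwork

From an undirected symbol-pair edge list (self-loops and duplicates
dropped), the subnetwork keeps the signature genes plus every non-
signature node v with dist(s₁,v) + dist(v,s₂) ≤ L for two distinct
signature genes (default L = 2, i.e. shared direct interactors), with all
induced edges.  The length-≤2 rule is a declared reconstruction of
"bridge protein" — published figures of this kind show single
intermediates, and no formal rule exists.  Matching is case-insensitive
with an alias table (LRBA1 → LRBA).  Increasing L never removes nodes.
The packaged edge list is synthetic fixture data built to exercise this
topology, not curated interaction evidence.

## Problem sizes and numerical choices

Default test and acceptance problem sizes are chosen so the complete
suite runs on a single CPU in well under half an hour: 64–200 subjects
per arm, 300–2,000 SNPs, 100 ranking iterations, 20 evaluation folds.
Planted-recovery checks use 200/arm with 3 SNPs at OR 15 among 300 —
strong enough that recovery is expected in essentially every seeded run,
so a failure indicates a defect rather than sampling noise.  The OR
convergence check uses 5,000/arm at moderate MAFs (0.2–0.5), where the
estimator's sampling error is well inside the 10% test tolerance.
Exact-test agreement is asserted against a rational-arithmetic
enumeration oracle (|Δp| < 1e-12 over all 2×2 tables with total ≤ 40).
All stochastic components accept a single seed; the pipeline fans one
master seed out to stages through a SeedSequence, and repeated runs are
byte-identical.

## Known limitations

- No linkage disequilibrium or population structure in the generator, so
  stability-selection behavior under correlated predictors is untested.
- The screen's raw p < 0.05 rule is faithful to the reproduced pipeline
  but is not a recommendation; at array scale it admits thousands of
  false positives by design and relies entirely on stage 2 for control.
- The evaluation reuses one imputation of the full matrix (see above).
- Because the consensus ranking is computed on the same cohort that the
  evaluation folds resample, the best-ranked null SNPs carry
  selection-induced (winner's-curse) signal: the feature-number curve can
  keep rising slightly past the true signal size, so minimal-k selection
  tends to return a signature one or two SNPs larger than the planted
  count.  Only an external validation cohort removes this optimism.
- Real-cohort results of the original study (686k-SNP array, AUC 0.931)
  depend on undeposited data and are out of scope; the package
  demonstrates the machinery, not those numbers.
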