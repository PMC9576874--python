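# Methods

## Setting and data model

The unit of analysis is a mother–newborn pair with four aligned data
blocks: minor-allele dosages at a small candidate panel of SNPs (26 by
default), cord-blood array methylation at CpG probes expressed as
M-values (log2 methylated/unmethylated intensity, offset 1 so zero
intensities stay defined), a covariate table (newborn sex, gestational age
in weeks, ethnicity, birth weight in kg, maternal pregnancy complications,
pre-pregnancy BMI, parity, education, smoking, paternal age, plus seven
cord-blood cell-type proportions), and telomere length as the qPCR T/S
ratio. Coordinates are 1-based inclusive internally; BED manifests are the
only 0-based surface. Minor alleles are defined by observed sample
frequency, with an exact tie keeping the file's alternate allele — a
deterministic convention. The missing token is `NA` everywhere; floats are
written with 17 significant digits so files round-trip exactly.

## QC chains

**Genotypes** (fixed order): SNPs with call rate < 0.95 are dropped, then
samples with call rate < 0.90 over the retained SNPs; remaining missing
dosages are imputed by draws from each SNP's empirical genotype
distribution (deterministic under seed); finally SNPs with MAF < 0.01 or a
1-df Pearson Hardy–Weinberg chi-square p < 0.05 (no continuity correction;
monomorphic SNPs defined as chi² = 0, p = 1) are removed. All inequalities
are strict, so exactly-at-threshold features survive. LD-scaffold
imputation is not reproducible for a sparse candidate panel without
surrounding haplotypes, which is why the empirical-distribution scheme is
used; it is noted in the QC report. Pairwise LD is summarised as the
squared Pearson correlation of dosages (constant SNPs get missing
rows/columns).

**Methylation** (fixed order): a call fails when its detection p-value
exceeds `detection_p_max` (default 1e-16, the conventional EWAS reading of
the protocol's threshold; 1e-15 is selectable); probes with call rate
< 0.95 are dropped, then samples with call rate < 0.99, and surviving
failed calls become missing. Missing entries are filled by probe-wise KNN
imputation (K = 10): neighbours are the K nearest probe rows by Euclidean
distance with squared distance averaged over co-observed samples, ties
broken by row order; neighbours missing at the target sample are skipped
and the probe's row mean is the fallback. Technical batch and array
position are removed sequentially by parametric empirical-Bayes
location/scale adjustment (ComBat): per probe, standardise to the pooled
mean/variance, estimate per-level location γ and scale δ², shrink via
method-of-moments priors (normal on γ, inverse-gamma on δ²) with the
standard iterative posterior solution, remove, and restore the pooled
scale. The implementation agrees with Bioconductor `sva::ComBat` to ~1e-6
on fixtures (a test enforces this). Two consequences worth knowing: EB
shrinkage leaves per-probe residual batch deviations, so the adjustment is
only approximately idempotent and probe pooled means move by a small
fraction of the probe SD — identical behaviour to the reference
implementation; the batch-wide mean shift, however, is removed essentially
completely (>95% by construction of the prior mean). Outliers are then
trimmed per probe outside [Q1 − 3·IQR, Q3 + 3·IQR] (quartiles by linear
interpolation, single pass) and re-imputed; probes on chrX/chrY, at common
SNPs, or cross-reactive are removed by set semantics. Functional
normalisation is out of scope: it requires array control probes absent
from this data model, so the generator emits already-normalised
intensities.

**Cell deconvolution** is constrained projection against a reference
matrix of cell-type mean M-values at discriminating probes: per sample,
non-negative least squares then rescaling to sum 1 (within 1e-9). The
reference is study-supplied; the generator ships a synthetic one (100
probes, one discriminating cell type each) because the published cord
blood reference cannot be redistributed here — deconvolution is therefore
validated by mixture recovery, not by replicating a specific reference.

## Linear-model engine

All inference is OLS on a common design: intercept, binary covariates,
numeric covariates, dummy-coded categoricals (first declared level as
reference — the protocol's ordinal education codes are treated as
unordered for robustness), six of the seven cell proportions, and
analysis-specific terms. Granulocytes — the dominant cord-blood fraction —
are the dropped deconvolution component that breaks the sum-to-one
collinearity. Designs are checked to full column rank; dependent columns
are named left-to-right so the blame lands on the added term.

The mQTL scan moderates residual variances across pairs with the scaled
inverse-chi-square empirical-Bayes prior: s̃²g = (d0·s0² + d·s²g)/(d0 + d),
with (d0, s0²) fitted by the method of moments on log-variances (trigamma
inversion by Newton iteration, tolerance 1e-8) and moderated t referred to
d + d0 df. When the observed log-variance dispersion does not exceed
sampling noise (var ≤ trigamma(d/2)), the prior df is infinite and s0² is
the arithmetic mean of the variances, so constant variances moderate to
themselves and the moderated t equals the ordinary t. This matches
`limma::squeezeVar` in both branches (a test pins the agreement at 1e-4
relative). Moderation is applied only in the mQTL scan, mirroring the
protocol's use of array-style inference there and plain regression
elsewhere; with fewer than 10 tested pairs no prior can be fitted and the
scan falls back to ordinary t inference.

Family-wise control is Bonferroni at level α over the tested universe,
flagging p ≤ α/m (ties at the threshold significant).

## The four analysis steps

*Step 1* fits one covariate-adjusted regression of TL per SNP per coding
(dominant = carrier indicator; additive = allele count) and flags nominal
p < 0.05. *Step 2* enumerates cis pairs (same chromosome,
|CpG − SNP| ≤ 500 kb inclusive; distance signed CpG − SNP), fits all CpGs
sharing a SNP as one multi-response OLS, moderates, and Bonferroni-controls
over all tested pairs; the reported mQTL set requires significance under
*both* codings (configurable to the union) — the stricter reading of a
set "identified from both the dominant models and the additive models".
*Step 3* screens the CpGs of significant mQTLs for a nominal TL
association (marginal, covariate-adjusted, without the SNP; a flag can
condition on it), then runs the mediation decomposition with dominant
coding and percentile-bootstrap inference: individuals are resampled whole
(preserving the covariate joint), both models refitted per replicate,
CIs taken at the 2.5/97.5 percentiles (linear interpolation), and the
p-value is the symmetric two-sided form 2·min(P(≤0), P(≥0)). Replicates
with a degenerate resampled design are redrawn and counted; more than 10%
is an error. The proportion mediated and its interval come from the
same-sign replicates only. The product-of-coefficients IE coincides with
the causal ACME in this linear, no-interaction setting, and TE = DE + IE
holds exactly within every replicate. *Step 4* tests every cis pair
outside the significant mQTL set (genotype–methylation independence cannot
be assumed inside it) with the additive-coded interaction model; β12 is
Bonferroni-controlled over that universe and the SNP main effect over the
panel size (26 by default, config-exposed).

## Synthetic cohorts

The generator draws dosages i.i.d. Binomial(2, MAF) under HWE; default
MAFs are representative common-variant values in [0.05, 0.45] assigned
deterministically (golden-ratio spacing), since only frequency summaries
of the originating panel are public. Methylation is a cell-mixture model:
true proportions ~ Dirichlet(α) with α calibrated to typical cord-blood
composition (granulocytes dominant), probe-specific cell rows (reference
probes strongly discriminating, cis probes mildly cell-dependent around a
bimodal baseline-mean landscape), plus per-allele mQTL effects, dominant
mediation a-effects and N(0, 0.15²) residual noise; batch (4 levels) and
position (8 levels) add per-(level, probe) location/scale distortions on
top of the latent values, and detection failures and missingness are
masked independently. The phenotype follows the structural model with
every effect regressor centred at its realized mean, so the cohort mean
stays at the published 1.03 T/S whatever the effect sizes — centring moves
only the intercept, never the slopes the analyses recover. Mediation-path
effects enter with dominant coding and interaction/main effects with
additive coding, matching the estimand of the step that recovers them.
The residual SD defaults to the published marginal 0.20 T/S (an upper
bound on the post-covariate residual, which is not published); with the
default effects on, the marginal SD is slightly above 0.20. Covariates are
drawn from the published margins independently — the joint dependence is
not modelled — and the default interaction CpG sits at a methylated
baseline (mean M ≈ 3.3), which is what makes a large SNP main effect
(1.186 per allele) compatible with a realistic phenotype spread once the
negative interaction (−0.330 per allele per M-unit) is applied.

What passing recovery tests therefore shows: unbiased estimation, correct
error control and bootstrap calibration under the study's *structure*.
What they do not show: robustness to features the generator omits — LD
between panel SNPs, genome-scale probe counts, cell-reference
misspecification, non-Gaussian phenotype tails, or covariate dependence.

## Validation experiment sizes

The recovery experiments use 200 cohorts of n = 5,000 for the interaction
coefficients, 400 all-null scans of 2,000 pairs at n = 200 for family-wise
error, and 300 simulations at n = 500 with 500 bootstrap resamples for
mediation CI coverage and test size — sizes chosen so Monte-Carlo error is
small relative to the tolerances while the whole battery completes in a
few minutes on one CPU. Calibration checks use exact binomial tests at the
1% level rather than eyeballed bands.

## Known limitations

Trans effects, haplotype/phasing analyses, GWAS-scale panels,
multiple-mediator models and sensitivity analysis for sequential
ignorability are out of scope. The bootstrap percentile type, the marginal
TL~CpG screen, and the interaction-universe definition are interpretive
choices exposed in config/flags and documented above.
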