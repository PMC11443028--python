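# Methods

## The scientific question

Albinism is a rare hypopigmentation disorder whose ocular hallmarks are
infantile nystagmus and foveal hypoplasia. Two common missense variants —
TYR:c.1205G>A (p.Arg402Gln, rs1126809; non-Finnish European MAF ≈ 27%) and
OCA2:c.1327G>A (p.Val443Ile, rs74653330; MAF ≈ 0.3%) — are each
insufficient to cause disease in the heterozygous state, but their joint
occurrence ("dual heterozygosity") is hypothesised to act digenically.
This package implements the quantitative machinery for testing that
hypothesis in a case-control design, together with a synthetic cohort
generator that reproduces the statistical structure of the real
(controlled-access) cohorts so that every stage is testable end to end.

## Genotype groups and covariates

Individuals are classified by joint allele dosage at the two studied
variants: (0,0)→A (reference), (1,0)→B, (0,1)→C, (1,1)→D (dual
heterozygote), (2,0)→E, (2,1)→F. OCA2 homozygotes and missing-dosage
combinations are `unassigned` and excluded from model fitting; the
groups are a categorical coding (no allele-dosage trend term), matching
the recessive-style analysis of the source design.

Two further common TYR variants modify the effect of R402Q: the promoter
variant c.-301C>T (rs4547091), whose *reference* C allele is the
risk-associated one, and c.575C>A (p.Ser192Tyr, rs1042602), whose A
allele is risk-associated. The regression covariate `modifier_count`
(0–4) sums the risk-orientation alleles at these two loci: count of
-301C plus count of 575A. The alternate-allele orientation is available
via `FilterConfig(modifier_orientation="alt")` for sensitivity analyses.
When a modifier genotype is missing, the count is computed over the
observed loci and the individual is flagged, not dropped; individuals
are excluded from fitting only when a studied-variant dosage is missing.

## Genotype QC

Calls fail QC when genotype score < 20, read depth < 10, heterozygote
allele balance < 0.2 or > 0.8, homozygous-reference allele balance
> 0.1, or homozygous-alternate allele balance < 0.9. All comparisons are
strict, so boundary values pass. Calls without quality metadata (e.g.
simulated genotypes) pass by default. A failing studied-variant call is
an exclusion reason; failing calls elsewhere are masked to missing
before the exclusion rules run.

## Molecular-diagnosis exclusion

To isolate the effect of the studied pair, individuals whose genotypes
already explain albinism are removed: (i) homozygous P/LP HGMD-listed
variants in an autosomal albinism gene (TYR, OCA2, TYRP1, SLC45A2,
SLC24A5, C10ORF11, HPS1–10, LYST, SLC38A8; configurable); (ii) two or
more distinct heterozygous such variants in one autosomal gene (presumed
biallelic — phase is not assessable, so trans configuration is assumed);
(iii) hemizygous P/LP variants in GPR143 or FRMD7; (iv) the TYR risk
haplotype c.[-301C;575C>A;1205G>A] or c.[-301C;575C;1205G>A] (i.e.
-301C together with 1205A on one chromosome; the 575 allele is free) in
homozygous state; (v) one risk haplotype plus a heterozygous P/LP TYR
variant. Separately, heterozygous carriers of any other P/LP TYR or OCA2
variant are excluded, as are individuals outside the European-like
ancestry stratum (ancestry arrives as a label; no PCA inference is
done). The studied pair itself never counts as the qualifying P/LP
variant.

With unphased data the haplotype rules use only dosage-forced
configurations (pigeonhole: `max(0, C-alleles + A-alleles − 2)` risk
haplotypes are certain). Configurations where a risk haplotype is
possible but not forced are flagged `haplotype_ambiguous` and retained —
a conservative, reproducible choice that never excludes on guesswork.

## Firth bias-reduced logistic regression

The core estimator maximizes the Jeffreys-penalized binomial
log-likelihood

    l*(β) = l(β) + ½ log det I(β),   I(β) = Xᵀ diag(w·π(1−π)) X,

whose gradient is the modified score
U*ᵣ = Σᵢ (wᵢ(yᵢ−πᵢ) + hᵢ(½−πᵢ)) xᵢᵣ, with hᵢ the hat-matrix diagonal of
W^½X(XᵀWX)⁻¹XᵀW^½. The penalty removes the O(1/n) bias of maximum
likelihood and keeps estimates finite under complete and quasi-complete
separation — essential here because group D contains a handful of cases
in a cohort of twenty thousand.

Solver: Newton steps on the modified score with the expected information
as curvature, step-halving whenever a step would decrease l* (accepted
steps never decrease l* beyond a machine-precision slack of
1e-12·(1+|l*|)). Convergence requires max|U*| < 1e-6 or |Δl*| < 1e-9
(defaults; both configurable, and `tol_loglik = 0` disables the
likelihood-change criterion for score-only convergence). On very small
or degenerate designs the expected information is a poor Hessian of the
penalized objective and the main loop can creep; a local polish then
runs — Newton on U* = 0 with a finite-difference Jacobian, falling back
to BFGS ascent of l* with the exact gradient — which reaches
machine-precision stationarity (verified against the closed forms
below). Frequency weights allow grouped (e.g. 2×2 table) data.

Two exact identities anchor the implementation: the intercept-only model
has the closed form π̂ = (k+½)/(n+1), and in a saturated 2×2 design the
Firth estimate equals the Haldane–Anscombe log odds ratio (add ½ to each
cell). Both are enforced in the test suite at 1e-8.

Confidence intervals are profile penalized-likelihood intervals: the
endpoints solve 2(l*(β̂) − l*_profile(βᵣ)) = χ²₁(0.95) = 3.841 (a drop of
1.92073), with the profile re-maximized over the remaining coefficients
at each evaluation and the root bracketed outward from the estimate in
Wald-scaled steps before Brent refinement. A root not bracketed within
±20 log-odds units of the estimate is reported as an open bound with a
flag. p-values are penalized likelihood-ratio tests (the restricted
maximum pins the coefficient at zero; same solver); Wald quantities are
also reported (`se_wald`). These conventions follow the standard
reference implementation of Firth regression (R `logistf`).

The group model regresses case status on treatment-coded group
indicators (A = reference, odds ratio fixed at 1 by construction), sex
(male = 1) and `modifier_count`. Groups E/F are fitted jointly with B–D
in a single model when present; empty levels are dropped with a warning.

## Genomic-inflation factor

Confounding by population structure is quantified with λ_median: each of
35 presumed-neutral markers is tested with a single-marker Firth model
(case ~ dosage, no covariates by default; covariates optional) and the
penalized LRT statistic collected; λ = median(χ²)/0.4549364231 (the
χ²₁ median). λ ≈ 1 indicates limited stratification. Note the sampling
spread of a 35-marker median is large (SD ≈ 0.23 on the median, i.e.
≈ 0.5 on λ), so single-panel values well away from 1 are expected under
the null; calibration of the statistic itself is verified in the tests
by a Kolmogorov–Smirnov check against χ²₁ at m = 1000 markers. The
two-stratum confounded mode of the generator drives λ far above the null
envelope, confirming directional sensitivity.

## Endophenotype arm

LogMAR visual acuity (higher = worse) and central retinal subfield
thickness (µm; thicker = more foveal underdevelopment) are albinism
endophenotypes. Individuals carrying any ICD-10 eye-chapter code
(prefixes H0–H5, configurable) are excluded unless they also carry the
albinism code E70.3, so unrelated ophthalmic disease does not drive
trait differences. Groups A–D are compared with the tie-corrected
Kruskal–Wallis test (the trait distributions are non-normal); pairwise
comparisons use the two-group Kruskal–Wallis statistic (equivalent to a
Wilcoxon rank-sum without continuity correction — the specific pairwise
test was an open choice, and the rank test keeps the family consistent)
with Benjamini–Hochberg adjustment applied across the six pairs of one
trait, not across traits. A covariate-adjusted OLS model (group
indicators + sex + modifier count, t-based p-values) provides the
parametric companion. 2×2 susceptibility contrasts report the raw odds
ratio ad/bc, the Haldane-corrected OR (which the tests verify equals the
Firth saturated-2×2 estimate), and a two-sided Fisher exact p using the
point-probability rule (all tables with point probability ≤ observed).

## Synthetic cohort generator

The generator is the package's stand-in for the controlled-access
cohorts; its defaults encode the study conditions.

- **TYR haplotypes.** Three-site haplotypes over (-301, 575, 1205) are
  drawn from a frequency table. True haplotype frequencies are not
  published; the default table is constructed from the single-site
  frequencies (-301C 0.60, 575A 0.36, 1205A 0.27) by placing 575A
  exclusively on -301C backgrounds (the two travel together in real
  data) and leaving 1205A independent. The table is user-overridable and
  validated at load (sums to 1, implied single-site frequencies match
  the stated MAFs).
- **OCA2.** An independent allele pair, Binomial(2, 0.003) —
  Hardy–Weinberg, unlinked to TYR (different chromosomes).
- **Penetrance.** logit P(case) = logit(prevalence) + group effect +
  sex effect·male + modifier effect·count — the multiplicative model the
  analysis-side regression assumes. Default group odds ratios: B 1.5,
  C 4.0, D 12.8, E 3.5, F 15.0 (log scale internally). D is the
  headline dual-heterozygote effect; B/C/E/F are package choices on the
  ordering single-het < homozygote < dual-het, with C > B reflecting the
  much rarer, larger-effect OCA2 allele. Sex effect defaults to 0;
  modifier effect defaults to OR 1.2 per allele.
- **Prevalence.** Albinism's population prevalence (~1/17,000) would
  make 204 cases unreachable at simulation scale; the default baseline
  prevalence is raised to 0.01 over a population of 60,000. This is a
  deliberate, documented distortion that moves only the intercept: odds
  ratios are invariant to outcome-dependent sampling, so group-effect
  recovery is unaffected. A side effect is a small depletion of
  risk-allele frequency among non-cases (≈ 0.26 percentage points for
  R402Q), visible when control-side frequencies are compared with the
  generative values.
- **Sampling.** Exactly 204 cases and 20,350 controls (the filtered
  sizes of the real analysis) drawn uniformly without replacement.
- **Traits.** Group-shifted normals (defaults: group D +0.12 LogMAR and
  +10 µm over group A's 0.0 / 270 µm, SDs 0.18 / 22 µm — plausible
  UK-biobank-scale values) with a 5% contamination fraction drawn at 3×
  the SD to emulate the heavy tails of real acuity/OCT measurements.
  Setting the contamination to 0 recovers exact normality.
- **Neutral markers.** 35 markers (configurable), Hardy–Weinberg at
  frequencies uniform in [0.05, 0.5], identical in cases and controls;
  the stratified mode splits the cohort into two latent strata with
  case-enriched membership (P(stratum 1) = 0.9 for cases vs 0.3 for
  controls) and frequencies shifted ±0.15, inducing inflation.
- **Spiking.** Pathogenic-genotype spikes (homozygous, presumed
  biallelic, hemizygous-X, haplotype-homozygous, haplotype-plus-het,
  carrier het) with known ground truth exercise every exclusion reason.

All randomness flows from a single seed; identical seeds give bitwise
identical cohorts.

What the generator does *not* emulate: genome-wide background variation,
relatedness, genotyping/imputation error, ancestry admixture continua,
or real trait distributions beyond location/scale/contamination.
Passing tests therefore demonstrate that the statistical machinery is
correct and well calibrated under the assumed generative structure, not
that the scientific findings replicate on real data.

## Problem sizes and numerical choices

The replicated recovery experiment uses 50 cohorts of 20,554 (population
60,000 each); the calibration check uses 1,000 markers on a cohort of
~2,000; frequency fidelity uses n = 50,000. These sizes give
Monte-Carlo error comfortably below the asserted tolerances (e.g. the
mean log-OR over 50 replicates has SE ≈ 0.09 against a 25% band of
±0.64). Ties in rank tests use midranks with the standard correction
divisor; the even-length median is the midpoint mean; degenerate inputs
(monomorphic markers, empty groups, rank-deficient designs, zero 2×2
margins) raise or flag rather than silently propagate.

## Known limitations

- The exclusion engine assumes annotations cover all carried non-studied
  variants; unannotated variants are ignored rather than flagged.
- The per-marker λ tests are unadjusted for sex (the source design is
  silent); adding covariates is supported but untested at scale.
- Profile intervals assume a unimodal profile; with the Jeffreys penalty
  this holds in all exercised designs but is not proven globally.
- The record-level API is O(n) in Python objects and is not intended for
  cohorts beyond ~10⁵ individuals; the vectorized frame path covers the
  standard pipeline at scale.
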