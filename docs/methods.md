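# Methods

This note documents the models, estimators and design choices behind
`hybridzone`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Conventions

The two parental gene pools are `parent1` and `parent2`; the hybrid index
*h* ∈ [0, 1] of an individual is the proportion of its genome inherited
from parent1.  ALT-allele dosages are coded 0/1/2 with −1 for missing; any
genotype containing `.` (including half-calls) is missing, and no
imputation is performed.  All genomic coordinates are 1-based inclusive,
matching VCF; windows of width W tile each chromosome as
[start, start + W − 1].

## 2. Genomic cline model

The probability that a gene copy at locus *i* in hybrid *j* derives from
parent1 ancestry is the logit-logistic cline

    phi_ij = h_j^v_i / (h_j^v_i + (1 - h_j)^v_i * exp(u_i)),

computed internally in the stable form logit(phi) = v·logit(h) − u.  The
center c = inverse-logit(u/v) is the hybrid index at which phi = 0.5; v = 1,
u = 0 is the genome-average cline (the identity).  Genotypes are modelled
as g ~ Binomial(2, q) with q = phi·p1 + (1 − phi)·p2, where p1 and p2 are
parental ALT frequencies — this allele-frequency mixture handles non-fixed
loci without local-ancestry calls.  Loci with parental allele-frequency
difference (AFD) below a configurable floor (default 0.3) are excluded as
uninformative, since the mixture then barely depends on phi.  Individuals
whose hybrid-index point estimate is exactly 0 or 1 contribute no cline
information (phi is pinned at the boundary for every (v, u)) and are
excluded with a log entry.

### Estimation (two-stage)

Stage 1 (`GenomicClineModel.fit_sds`) runs a joint MCMC over per-locus
(log v, logit c) with hierarchical priors log v ~ N(0, σ_v),
logit c ~ N(0, σ_c) and half-Normal(0, 1) hyperpriors on both SDs, on a
subset of loci (default a few hundred).  The posterior-median SDs are then
fixed as plug-in point estimates for stage 2 (`fit`), which samples each
locus's (log v, logit c) independently — vectorised across loci — under
those Normal priors.  Hybrid indices are likewise plugged in as point
estimates.  This mirrors standard hierarchical-cline practice; full joint
propagation of hybrid-index and hyperparameter uncertainty is a documented
non-goal.

### Sampler

An adaptive random-walk Metropolis updates (log v, logit c) jointly per
locus (one bivariate isotropic proposal per locus per iteration, accepted
componentwise across loci).  Per-locus proposal scales adapt every 50
iterations during burn-in toward a 0.37 acceptance rate and are frozen
afterwards, preserving detailed balance.  Defaults are 4,000 iterations
with a 2,000-iteration burn-in and 2 chains.  The hierarchical SDs are
updated by an independence Metropolis step whose proposal is the
Inv-Gamma conditional implied by the current locus effects; the acceptance
ratio then reduces to the half-Normal prior factor, so mixing remains good
even when the posterior concentrates near σ = 0 (a regime where a log-scale
random walk funnels and stalls).  All randomness derives from a single
`SeedSequence`, so runs are bit-reproducible under a seed.

Diagnostics are split R-hat and bulk effective sample size (FFT
autocorrelation with Geyer initial-positive-sequence truncation), computed
batched over loci; a locus is flagged converged when both R-hats are below
1.1 and both ESS at least 100.  Non-convergence warns, never raises.

### Outlier classification and downstream tests

A locus is **steep** when the 95% equal-tail interval of v lies above 1,
**shallow** when it lies below 1, otherwise **neutral** — a partition.
Window summaries report the per-window fraction of each category (default
500 kb windows, 5-window centered rolling mean).  Per-chromosome enrichment
permutes category labels across all loci with chromosome sizes preserved
(the alternative — permuting positions — is equivalent here because only
the label-to-chromosome assignment matters); the empirical p-value is
(1 + #{perm ≥ obs}) / (n_perm + 1), which is slightly conservative by
construction.  Region-vs-background contrasts of posterior-median v and c
use the two-sided Mann-Whitney U with the tie-corrected normal
approximation.

### A calibration caveat that shaped the design

If the hybrid index is estimated from the *same* loci later fit for
clines, the estimate partially absorbs those loci's binomial sampling
noise, and fitted slopes are inflated (genotypes track the fitted h more
tightly than the true h).  The package's recovery tests therefore estimate
h from loci disjoint from the cline set; at realistic scales (a thousand
hybrid-index SNPs against tens of thousands of cline SNPs) the overlap is
negligible and the effect immaterial, but on small simulated zones it is
not.  Classical attenuation from noise in h is negligible in comparison
(error variance ≪ variance of h across a zone).

## 3. Hybrid index

Under the genome-average cline, each gene copy carries ALT with probability
q_i(h) = h·p1_i + (1 − h)·p2_i.  The per-sample log-likelihood
Σ_i [g_i ln q_i + (2 − g_i) ln(1 − q_i)] is one-dimensional and smooth, so
no MCMC is used: the likelihood is evaluated on a 1,001-point grid over
[0, 1], h-hat is the grid maximiser, and the 95% equal-tail interval comes
from the normalised grid posterior under a flat prior.  Boundary estimates
are reported as-is.  Loci are sampled without replacement (default 1,000)
from those above the AFD floor.  Swapping parent labels maps h-hat to
1 − h-hat exactly.

Diagnostic-marker ancestry ("triangle") summaries orient each AFD ≥
threshold (default 1.0) locus to the parent in which its allele is more
frequent and report the per-sample proportions of homozygous-parent1 /
heterozygous / homozygous-parent2 calls.  They ignore linkage — this is a
deliberate, documented deviation from HMM-based local-ancestry inference,
which is out of scope.  Parent designation labels samples parent1/parent2
when the supplied admixture proportion exceeds a threshold (default
0.99999) toward either end.

## 4. Divergence landscape and heterozygosity excess

π, d_xy and F_ST are ratio-of-sums within non-overlapping windows
(pixy-style): per-site mean pairwise differences among genotyped allele
copies (within or between groups) are summed and divided by the number of
sites genotyped in the relevant group(s), so genotyped invariant sites
contribute 0 to the numerator and 1 to the denominator.  Running the
estimators on a variant-only matrix warns that the denominators will be
biased upward.  F_ST is the Hudson estimator with the sample-size-corrected
numerator Σ[(p1 − p2)² − p1(1 − p1)/(n1 − 1) − p2(1 − p2)/(n2 − 1)] over
Σ[p1(1 − p2) + p2(1 − p1)]; windows with no usable site report missing, not
an error.  The rolling smoother is a centered mean over k windows within a
chromosome, shrinking to the available neighbours at edges and skipping
missing windows — chosen over a trailing mean for symmetric landscape
plots.

Heterozygosity excess is H_excess = P(Ho) − P(He) per SNP, computed among
hybrids with admixture in [0.25, 0.75] (bounds inclusive) at SNPs with AFD
at or above a threshold (default 1.0, i.e. fixed parental differences);
P(He) = 2q(1 − q) with q the ALT frequency in the retained hybrid subset.
H_excess is bounded by [−P(He), 1 − P(He)] sitewise.

## 5. Trait association

Traits are first screened with a Shapiro-Wilk test (α = 0.05); non-normal
traits are re-tested under the admissible transformations (log for strictly
positive values, square root for non-negative, Box-Cox with MLE λ for
strictly positive) and the transformation with the highest Shapiro-Wilk p
is kept only if it beats the untransformed p.

The scan is a per-SNP ordinary linear model with covariates (batched normal
equations with per-SNP missingness masks); the hybrid index serves as the
structure covariate, since in a two-population admixture setting it is the
leading structure axis.  A kinship random effect is a documented non-goal;
the permutation threshold absorbs residual miscalibration.  Monomorphic
SNPs and SNPs with fewer than 10 complete pairs are skipped.  The
genome-wide threshold pools the lowest 1% of p-values from each of
(default) 100 trait permutations and takes the 1e-6 empirical quantile
(type-7) of the pool — "0.0001%" is read as a fraction of 1e-6, a
configurable choice since the phrasing admits 1e-4.  A Bonferroni threshold
(0.05 / #SNPs) is computed alongside.  Peaks are per-(trait, chromosome)
sets of at least 5 significant SNPs, spanning [min pos, max pos], with the
percentage of peak SNPs at AFD = 1 reported; genes within 20 kb (inclusive
at exactly 20 kb) of the peak interval are listed in coordinate order.
Candidate-locus consensus genotyping orients each SNP to parental ancestry
and calls heterozygous at ≥ 50% heterozygous SNP calls, else a parent class
at > 50%, else missing.

## 6. Colour metrics and pollinator visual models

Segment classification splits 400–700 nm into four equal bands; brightness
is the trapezoidal area over the full range, relative signals S1..S4 are
band areas divided by brightness, chroma = sqrt((S4 − S2)² + (S3 − S1)²)
and hue = atan2(S4 − S2, S3 − S1) in [0, 360).  A zero-brightness spectrum
has chroma 0 and undefined (NaN) hue.  The modified hue subtracts 270° from
hues above 270° and adds 90° below, so redder flowers always score higher;
exactly 270° (the bluest value) maps to 0.

Receptor sensitivities are Govardovskii A1 visual-pigment templates
(alpha + beta band) generated from λmax and normalised to unit area —
not shipped lookup tables.  Default receptor sets are literature
conventions, configurable: honeybee UV/S/M at 344/436/544 nm with 1:2:1
densities; average violet-sensitive avian at 416/455/508/568 nm with
1:1:1:2.  Quantum catches are trapezoidal integrals of reflectance ×
sensitivity × illuminant over 300–700 nm on a common 1 nm grid (linear
resampling); the illuminant is flat ("ideal").  Von Kries correction
divides each catch by the background's catch; the hyperbolic transform is
E = Q/(Q + 1).  Chromatic contrast uses the receptor-noise-limited model
with density-based ("neural") noise e_i = w·sqrt(d_max/d_i), Weber fraction
w = 0.1 on the most abundant receptor class, and the standard closed forms
for 2, 3 and 4 receptor classes; achromatic contrast uses the
longest-wavelength receptor and is reported but not used for
classification.  Bee-hexagon coordinates are
x = (√3/2)(E_G − E_UV), y = E_B − (E_UV + E_G)/2, so the adapted background
maps to the origin.  Group comparisons of flower-vs-background JNDs use
one-way ANOVA with Tukey HSD post-hoc tests (off-the-shelf statistics).

## 7. Synthetic hybrid zone

The generator emulates the structure of an elevational two-species contact
zone.  Parental allele frequencies fall in three exact-count classes:
fixed differences (AFD = 1), diagnostic (AFD ~ Uniform[0.75, 1)) and
low-AFD (AFD ~ Uniform[0, 0.5), so no low-AFD locus reaches the diagnostic
threshold); midpoints are uniform over the feasible range and REF/ALT
orientation is random.  Class counts are round(fraction × n_loci).
Architecture blocks — contiguous locus runs with designated (v, c), e.g. a
steep "barrier" block, a shallow block, a forced-heterozygote block and a
major hue locus — are always fixed differences so their cline behaviour is
visible in genotypes.  The forced-heterozygote construction gives each
hybrid one parent1- and one parent2-derived copy, the idealised
heterozygosity-excess pattern.

Hybrid elevations are uniform over the configured range; the mean hybrid
index is logistic in scaled elevation (midpoint 3,000 m, range
2,600–3,400 m by default, echoing a Sierra Nevada-style gradient without
claiming fitted coefficients — no quantitative elevation-ancestry model is
available to copy) and individual h values are Beta-jittered around that
mean (concentration 30), keeping h in (0, 1) and mean h monotone in
elevation.  Each hybrid gene copy is parent1-derived with probability
phi(h; v, u) and then carries ALT at the corresponding parental frequency;
parents draw both copies from their own pool.  Copies are conditionally
independent given h: there is **no linkage or admixture-LD**, so cline
recovery tests treat loci as independent — a stated limitation relative to
real zones, where admixture LD broadens association peaks and couples
nearby clines.  There is also no sequencing-error or coverage model;
missingness is i.i.d. (default 1%).

Phenotypes: floral hue is the genotype-class mean at the major hue locus
(defaults 300/320/340° for 0/1/2 parent1 alleles, SD 4°) plus Normal noise;
polygenic traits are linear in h_true with Normal noise (defaults chosen as
plausible floral measurements in mm).  Reflectance spectra on a 300–800 nm
grid are baseline + amplitude × a hue-weighted mixture of a blue (450 nm)
and a red (650 nm) Gaussian band, so segment-classification hue of the
generated spectra is strictly monotone in the input hue — the property the
tests assert; absolute hue values are not meant to round-trip.  Everything
derives from one seeded generator in a documented draw order, so a fixed
seed reproduces the written bundle byte-for-byte.

Default sample sizes (40 + 30 parents, 200 hybrids, 5 × 200 loci) keep a
full pipeline run in tens of seconds while leaving every downstream filter
(admixture window, AFD thresholds, MAF floors) non-trivially exercised.
What passing tests on this generator show is that the estimators recover
the generating process they assume; they do not show robustness to
linkage, genotyping error or reference bias, which real resequencing data
carry.

## 8. Test and simulation scales

Recovery and calibration tests run at 150–250 hybrids and a few hundred
loci with 1,500–4,000 MCMC iterations; the headline cline-calibration check
uses 200 hybrids and 600 fixed-difference loci at v ∈ {0.5, 1, 2} with the
default 4,000-iteration, 2-chain settings, and estimates the hybrid index
from a disjoint background chromosome (§2).  The hierarchical-SD recovery
test uses 300 loci and 150 hybrids.  These sizes were chosen so the whole
suite completes in a few minutes while leaving the assertions
well-powered.
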