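# Methods

This note documents the models behind `duplexmut`, the calibration of the
synthetic-cohort generator, and the numerical choices made where the design
was genuinely open.

## Mutation frequency

The per-bp mutation frequency of any scope (sample, dose group, target,
region class, chromatin state, cohort) is

    MF = (number of unique somatic mutations) / (duplex bp sequenced),

with counts and depths **summed before dividing** (not a mean of per-sample
ratios), which is exact under unequal depths and makes the cohort MF the
depth-weighted mean of per-sample MFs. Uniqueness is per sample: the key is
(sample, chromosome, position, ref, alt). A call observed in *m* > 1 duplex
molecules of one sample is treated as one mutation plus *m* − 1 clonal
copies; the clone-inclusive MF sums multiplicities instead.

Dose (and stratum) contrasts use a binomial GLM with logit link on
per-animal aggregates — mutations out of duplex bp, dose as a factor — with
Wald z tests of each exposed dose against control. This is a fixed-effects
approximation to a mixed-effects binomial model; with per-animal aggregation
the animal *is* the experimental unit, so the approximation amounts to
ignoring extra-binomial dispersion between animals, which the generator does
not produce and which was minimal in the motivating data. The Holm–Šidák
step-down correction, adjᵢ = max over j ≤ i of 1 − (1 − p₍ⱼ₎)^(m−j+1), is
applied within each stratum independently (via
`statsmodels.stats.multitest`). A dose group with zero mutations gets a
0.5-mutation / 1-bp continuity correction (logged) to avoid separation.

The GC-content association test discretizes targets at a threshold (default:
panel mean GC) and reports the Wald χ² for the GC-group term of a binomial
GLM containing dose and GC group — a Type II test, since dose is retained
under the null. Note that in panels where GC correlates with region class or
chromatin (as in the default panel), this marginal test absorbs those
effects; that is a property of the design, not the test.

## Trinucleotide spectra

SNVs are assigned to one of 96 channels: six pyrimidine-referenced
substitution classes × 16 flank combinations, in canonical COSMIC order.
Purine-reference calls are reverse-complemented at assignment, so spectra
are strand-invariant by construction. Indels and MNVs are excluded from the
96-channel spectrum and tallied separately in the 6-class summary.
Normalizations: raw counts, proportions, per duplex bp, or per context
opportunity (each channel divided by the panel abundance of its trinucleotide
times the mean per-site depth).

Spectrum homogeneity between groups is tested with a fixed-row-margin Monte
Carlo Pearson χ²: each group's class vector is resampled from the pooled
class proportions at its observed total, and p = (1 + #{χ²_sim ≥ χ²_obs}) /
(B + 1). The Monte Carlo reference distribution was chosen over the
asymptotic χ² because mutation-class tables are routinely sparse (expected
counts below 5 in minor classes). Per-class follow-ups are 2×2 χ² tests
(class vs rest, group vs control), Holm–Šidák-adjusted across classes.
All-zero classes are dropped with a warning.

CpG analysis counts each CpG dinucleotide once (not per strand); a site is
mutated if any call hits its C or its G. The denominator is the panel's full
CpG inventory, derived from target sequences.

## Signature matching

Observed spectra are converted to proportions and compared with catalog
signatures by cosine similarity. Catalogs are read from a 96-row TSV
(channel label column plus one column per signature), reordered into
canonical channel order, and renormalized only if column sums are within
1e-3 of 1. Ties in the best match are broken by catalog order and reported.
The test suite uses a synthetic five-signature catalog built in code, so no
external catalog download is needed.

## Binomial distance, NMDS, Mantel

The binomial dissimilarity between two count vectors x, y is

    d(x, y) = Σᵢ [xᵢ ln(xᵢ/mᵢ) + yᵢ ln(yᵢ/mᵢ)] / nᵢ,   nᵢ = xᵢ + yᵢ, mᵢ = nᵢ/2,

summed over channels with nᵢ > 0 and with 0·ln 0 = 0. It is implemented
directly from this definition (and cross-checked against a naive loop) so no
external ecology package is required.

NMDS minimizes the stress

    stress = sqrt( Σ (f(xᵢ) − dᵢ)² / Σ dᵢ² )

where dᵢ are the configuration (embedded) distances and f the monotone
transform of the observed dissimilarities, realized as isotonic regression
(pool-adjacent-violators, via scikit-learn) of configuration distances on
the observed dissimilarity order — the standard NMDS choice. Optimization
alternates the isotonic fit with a Guttman majorization step; a step that
would increase stress terminates the restart, making the per-restart stress
sequence non-increasing by construction. Restart 1 starts from classical
metric scaling (principal coordinates); further restarts are seeded random
Gaussian configurations; the lowest-stress configuration wins. Defaults:
k = 2, 20 restarts, relative tolerance 1e-6, 300 iterations. Non-convergence
is reported in the result, not raised.

The Mantel test correlates the off-diagonal upper triangles of two distance
matrices (Pearson r) and permutes the sample labels of the second matrix;
the p-value is one-sided (greater), p = (1 + #{r_perm ≥ r_obs}) / (B + 1).

## Nearest shrunken centroids

Per-sample spectra enter as **percent** proportions (so that centroids are
on the same scale as the reported per-channel percentages). For channel i
and class k with class size n_k:

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = sqrt(1/n_k − 1/n),

where s_i is the pooled within-class SD and s0 the median of all s_i (the
usual guard against near-zero denominators). Soft thresholding
d′ = sign(d)·max(|d| − Δ, 0) shrinks the class centroids toward the overall
centroid; channels with d′ = 0 for every class are inactive and cancel out
of classification. The discriminant score of class k is the squared
(s_i + s0)-standardized distance to the shrunken centroid minus 2 ln π_k;
priors are equal by default (the closed-form probability below carries no
prior term). Class-membership probabilities are the softmax of −score/2.

Δ is selected from a grid (default 30 even steps from 0 to max |d|) by
stratified k-fold cross-validation (default 6 folds, deterministic given the
seed), ties broken toward the **largest** Δ — the most parsimonious model.
With cleanly separable training classes the zero-error plateau typically
extends almost to max |d|, so the selected model often retains only the
single strongest channel; this is a direct consequence of the parsimony rule
and is exercised as such in the tests.

The two-class Gaussian discriminant on named channels is

    ProbExposed = e^{−A/2} / (e^{−A/2} + e^{−B/2}),
    A = Σ ((xᵢ − exposedᵢ)/sᵢ)²,  B = Σ ((xᵢ − controlᵢ)/sᵢ)²,

evaluated in log space. `bap_reference_discriminant()` carries the reference
three-channel parameterization (C[C>A]A, C[C>A]C, G[C>A]C; exposed centroid
(4.23, 10.3, 4.00)%, control centroid (1.38, 1.64, 0.80)%, pooled SDs
(1.81, 4.11, 1.93)%), at which ProbExposed evaluates to ≈0.9921 at the
exposed centroid and ≈0.0079 at the control centroid.

## Benchmark-dose estimation

Responses are modeled as lognormal — the standard assumption for strictly
positive continuous endpoints — with the fitted function μ(d) describing the
group **median**. Arithmetic group summaries (mean, SD, n) are converted to
log-scale moments via σ_log² = ln(1 + CV²), m_log = ln(mean) − σ_log²/2.
With a shared log-scale residual variance profiled out analytically, maximum
likelihood reduces to n-weighted least squares of m_log on ln μ(d), and the
reported log-likelihood uses the profiled variance.

Six increasing families are fitted, each written as μ(d) = a·shape(d) with
shape(0) = 1:

| name       | shape(d)                               |
|------------|----------------------------------------|
| exp3       | exp(b·d^g)                             |
| exp5       | c − (c−1)·exp(−b·d^g)                  |
| hill3      | 1 + (c−1)·d/(b + d)                    |
| hill5      | 1 + (c−1)·d^g/(b^g + d^g)              |
| inv_exp    | 1 + (c−1)·exp(−b·d^(−g))               |
| log_normal | 1 + (c−1)·Φ((ln d − b)/g)              |

with a, b > 0, c > 1 and the power g restricted to [0.25, 4] — wide enough
for strongly sub- and supra-linear dose-responses while excluding step-like
degenerate fits. The background a is profiled analytically, which makes
every BMD exactly invariant to rescaling the response and reduces the
optimization to the shape parameters: a deterministic data-scaled multistart
grid polished with Nelder–Mead (the 5-parameter Hill additionally starts
from the fitted 3-parameter Hill at g = 1, guaranteeing the likelihood
nesting). The BMD at benchmark response `bmr` solves shape(d*) = 1 + bmr by
bracketing and Brent root-finding on (0, 10·d_max]; a response that never
reaches the target in that range is an error, and such models are excluded
from the average with a logged warning. The model-averaged BMD is the
unweighted arithmetic mean of the converged models' BMDs. Confidence
intervals (bootstrap BMDL/BMDU) are out of scope.

## Synthetic cohort generator

The generator emulates a dosed duplex-sequencing mutagenesis experiment at
the level of called variants. Defaults reproduce the conditions of a 28-day
oral benzo(a)pyrene study in MutaMouse bone marrow:

- **Design**: doses (0, 12.5, 25, 50) mg/kg/day, 6 animals per group,
  20-target panel (~2.4 kb each; 9 genic, 11 intergenic, 7 heterochromatic),
  8.5×10⁸ duplex bp per sample (lognormal across targets, CV 0.15).
- **Counts**: unique mutations per (sample, target) are Poisson with rate
  MF_target × depth. At MFs of order 10⁻⁷ the binomial site-thinning is
  indistinguishable from Poisson, and the Poisson form keeps the generator's
  moments analytic for recovery tests. Within a sample, duplicate
  (position, ref, alt) draws are rejected and only the position is redrawn
  (within the already-chosen channel), so deduplicated counts remain Poisson
  and the realized channel distribution is exactly the configured mixture.
- **Per-dose MF**: (1.3, 3.3, 6.8, 10.4) × 10⁻⁷. Genic targets are scaled
  down and heterochromatic ones up (multiplier 1.3), then the per-target
  vector is renormalized so the panel-wide mean equals the configured dose
  MF. The genic factor is solved from the panel layout so that the *mean
  observed* genic-vs-intergenic reduction is 23% at background and 42% under
  exposure, accounting for the partial confounding of chromatin with region.
- **Spectra**: each SNV's channel is drawn from
  (1 − w)·control + w·exposure. The control 6-class spectrum puts 32/22/16%
  on C>A/C>G/C>T (uniform across flanks). The exposure spectrum carries 75%
  C>A; the high-dose weight w₅₀ solves w·0.75 + (1 − w)·0.32 = 0.61, the
  observed high-dose C>A share, and the three discriminant channels receive
  exactly the exposure share that makes the mixture reproduce their observed
  high-dose frequencies (4.23, 10.3, 4.00% of SNVs). Lower-dose weights
  scale with the induced fraction (MF_d − MF₀)/MF_d — i.e. induced mutations
  carry the exposure spectrum, background mutations do not. Positions are
  drawn uniformly among the target's sites matching the channel's context,
  so simulated calls sit at real context-consistent reference sites.
- **Clonality**: a mutation is clonally expanded with dose-dependent
  probability (0.03, 0.06, 0.09, 0.18), adding 1 + Geometric extra molecules
  (mean 1.4). Geometric is the minimal one-parameter clone-size law; the
  probabilities were set so expected clonal extras rise with dose on the
  scale of the motivating study's reported totals.
- **Indels/MNVs**: 6% of events are non-SNV (55% single-bp deletions, 35%
  single-bp insertions, 10% dinucleotide MNVs), drawn without context
  structure.
- **Reproducibility**: one global seed; per-sample generators are spawned
  deterministically from it, so cohorts are byte-identical given the config.

**What the generator does not emulate.** Per-animal spectral noise is purely
multinomial; real animals show extra-binomial (biological) dispersion in
their channel proportions — the reference study's pooled per-channel SDs are
several times the binomial expectation. Consequently synthetic samples
separate more sharply in spectrum space than real ones, cross-validated NSC
models tend to retain fewer channels than they would on real data, and
passing recovery tests demonstrates correctness of the estimators under the
stated model, not robustness to biological overdispersion. There is no
sequencing-error model (duplex consensus error sits well below the target
MFs), no selection, no target-specific background variation beyond the
region/chromatin modifiers, and chromatin/region labels are inputs rather
than inferred quantities.

## Problem sizes in the test suite

Distributional tests run on full-size default cohorts (~11,000 calls each);
the end-to-end recovery suite uses 20 replicate cohorts, the law-of-large-
numbers spectrum test a ~100,000-mutation single-dose cohort, the MF oracle
tests deliberately shallow cohorts (≤100 mutations) where brute-force
recounting is transparent, and Monte Carlo calibration checks 200 Mantel
permutation tests at B = 99. The full suite completes in about a minute on
one CPU.
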