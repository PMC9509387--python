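# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `cortexmeth`.

## The synthetic cohort generator

The generator (`simcohort`) is first-class, tested code: it defines the
study conditions under which every downstream claim is verified.

**Cell-type profiles.** `make_reference_profiles` builds per-cell-type
mean beta profiles for NeuN+ (neuronal), SOX10+ (oligodendrocyte) and
NeuN−/SOX10− ("DN", microglia/astrocyte-enriched) populations. A chosen
number of discriminating CpGs per cell type is planted, half shifted up
and half down by `separation` (default 0.5 beta units) in that cell type
relative to a common background; backgrounds are drawn so shifted means
never leave [0, 1] (no clipping — impossible separations raise). All
other probes are identical across cell types. Within-type dispersion is
per-probe, on the logit scale (0.1–0.4), used when drawing labeled
reference samples.

**Pathology.** Five measures are generated per donor through a latent
Gaussian copula thresholded into each ordinal range: Braak NFT stage
(0–6), CERAD score (0–3), Thal phase (0–5), Braak Lewy-body stage (0–6)
and binary TDP-43 status. Marginals are binomial with means 3.72, 1.69,
3.09, 1.34 and rate 0.22 respectively — the composition of an aged
brain-bank population with substantial Alzheimer pathology. The default
latent correlation is 0.7 among the three AD measures and 0.2 elsewhere,
reproducing the strong mutual correlation of tau and amyloid staging.
The binomial marginal understates the zero-inflation of Lewy-body
staging seen in real cohorts (where most donors are stage 0); only the
mean and ordinal range are matched.

**Composition and its coupling to pathology.** Mean bulk composition is
NeuN+ 0.40, SOX10+ 0.35, DN 0.11, with the residual 0.14 treated as
debris that carries the per-probe background profile. Donor proportions
are Dirichlet draws (concentration 150) around a donor-specific mean: in
DLPFC only, the expected composition shifts linearly with Braak stage by
−2.74 (NeuN+), +1.60 (SOX10+) and −2.00 (DN) percentage points per stage,
centered at the realized cohort mean; the occipital region is uncoupled.
Two design points matter here:

* The three slopes do not sum to zero, so total labeled cell mass varies
  with pathology. The debris component absorbs this imbalance *and*
  contributes the background methylation profile, keeping total DNA mass
  at 1. Without that backing, every probe — discriminating or not —
  acquires a spurious pathology association through the mass term (we
  measured type-I error of 0.80 at non-discriminating probes before
  adopting this design).
* Shifting the Dirichlet *mean* (rather than adding shifts to a fixed
  draw) keeps every sample inside the simplex by construction; expected
  marginal slopes still equal the coupling values, which the
  `proportions_vs_pathology` recovery test confirms within 2 SE at 500
  donors.

**Differential methylation.** An `EffectSpec` confines effects to one
cell type: per-probe magnitudes (percentage points per unit of the
driving measure) default to |N(0.44, 0.17²)| — the scale of per-Braak-
stage bulk effects — with signs hyper or hypo per probe. The effect
enters only the target cell type's component of the mixture, so the bulk
effect is attenuated to mean(π_target) × cell-level effect. This
attenuation law is exact on noiseless data with fixed composition
(asserted to 1e-10) and is the mechanism behind the ~10× amplification
seen in purified-fraction comparisons.

**Noise.** Measurement noise and the donor random intercept are both
Gaussian on the logit scale and back-transformed, keeping betas in (0, 1)
without clipping and giving realistic heteroscedasticity (variance
shrinks near 0 and 1). Defaults: residual SD 0.1, donor SD 0.05 (logit
units). Detection p-values are Uniform(0, 0.01) with a configurable
failure rate (default 0.001) replaced by Uniform(0.95, 1).

**Sorted-fraction studies.** `make_sorted_fraction_study` emits four
matrices per donor — "total" (the mixture, analogous to bulk) and the
three purified fractions — for 15 low-pathology (Braak ≤ II) and 13
high-pathology (Braak ≥ V) donors by default. Purified fractions carry
cell-confined effects at full magnitude. Cell-level betas are clipped to
[0, 1] here (a saturation that large planted effects can reach at
extreme-methylation probes); experiments quantifying effect ratios
select target probes away from the boundary.

**What the generator does not emulate.** Probe-type (Infinium I/II)
chemistry, raw intensities, SNP structure, spatial/chromosomal
correlation among CpGs, and realistic cross-probe covariance of
measurement error. Passing tests therefore demonstrate the statistical
machinery under the stated mixture-and-noise model, not performance on
raw array data.

## Quality control and normalization

`pfilter` removes samples with strictly more than 1% of probes at
detection p > 0.05, then recomputes probe failure fractions on the
retained samples and removes probes failing in strictly more than 1% of
them; the sample-first order makes the result deterministic and the
operation idempotent. `pc_outlier_removal` scores samples on the first
three principal components (missing values mean-imputed per probe for the
decomposition only) and removes those beyond 3 robust SDs
(median/MAD-normal) on any PC, with one repeat pass and a hard guard at
50% of samples. The 3.0 cutoff is a configurable choice: on homogeneous
cohorts of a few dozen samples, ~0.3% of sample–PC scores exceed it by
chance, so occasional single-sample removals on clean data are expected.
`quantile_normalize` maps every sample onto the mean-of-sorted-samples
distribution via average ranks (ties receive the mean of their would-be
values; missing values are excluded from ranks and mapped through
interpolated quantiles). It is a generic between-sample normalization —
intensity- and probe-type-aware normalization is out of scope by design.
`compute_pc1` returns first-PC scores on the 10,000 most variable probes
(all probes if fewer), with the loading sign fixed so loadings sum to a
non-negative value.

## Deconvolution

Panel selection assigns each ANOVA-significant probe (p < 1e-8) to the
cell type with the largest |contrast| (mean in type − mean of others),
then takes the 50 largest positive and 50 most negative contrasts per
type, breaking ties by F statistic then probe ID — fully deterministic,
and no probe serves two cell types (which would duplicate collinear
columns). Proportions solve a non-negative least-squares problem; when
the unconstrained-sum NNLS solution already satisfies Σπ ≤ 1 it is the
optimum, otherwise the equality Σπ = 1 is enforced through a penalty row
of weight 1e6 (constraint violation ≪ 1e-9, the post-solve projection
tolerance). The solver matches a 0.01-step grid search over the simplex
within one grid step. Missing panel sites are tolerated down to 90%
coverage (array-version mismatch being the practical situation),
warning; below that, error. `joint_normalize_and_estimate` quantile-
normalizes the column-concatenated [reference | bulk] matrix — the whole
matrix, not panel sites only — before rebuilding the panel and
estimating; this compresses mixture columns toward the reference
distribution, so agreement with the unnormalized path is at the ~0.01
mean-absolute level, not per-entry.

Known limitation: with debris-backed mixtures, the constrained fit must
place total mass near 1 while the truth sums to ~0.86, and the
pathology-coupled debris trend is redistributed across the estimated
proportions. Recovered composition–pathology slopes from *estimated*
proportions are therefore attenuated/distorted relative to the generating
coupling (e.g. NeuN+ −1.7 vs −2.74 pp/stage at 250 donors); slope
recovery is exact in expectation only from true proportions. This
mirrors the real-data situation, where deconvolution against an
incomplete reference absorbs unmodeled cell types.

## The EWAS engine

The per-probe model is a linear model on untransformed betas (so
coefficients ×100 are percentage points, the scale on which methylation
effects are conventionally reported) with a donor random intercept. The
engine is a profiled-likelihood fitter written for this grouped
single-random-intercept structure: for a variance ratio λ = σ²_u/σ²_e,
GLS reduces to OLS on group-mean-shrunken data (shrinkage factor
1 − 1/√(1 + m_g λ) per group), and both the coefficients and σ²_e profile
out, leaving a 1-D bounded optimization over log₁₀ λ (xatol 1e-6,
λ ∈ [1e-8, 1e4]). This is exact ML — coefficients and log-likelihoods
match a general mixed-model optimizer to ~1e-5 in the test suite — at
roughly 50× less cost per probe, which is what makes array-scale
calibration studies feasible. Fits landing on the λ = 0 boundary are
flagged and reported with OLS small-sample inference (unbiased variance,
t tests); interior fits use Wald normal inference with the ML variance.

The joint pathology test compares the full model (Braak + CERAD + Thal)
to the null without them, both by ML, referring 2Δll to χ²(3). Like all
fixed-effect LRTs in mixed models it is mildly anticonservative at small
donor counts (size ~0.08 at 150 donors); calibration studies in this
package use 500 donors, where the measured size is 0.05–0.065 at nominal
0.05. Single-measure models report the Wald test of that coefficient.
The region-interaction test adds a region main effect and
predictor × region terms. Single-region analyses are plain OLS (one
sample per donor), vectorized across probes sharing the design, and
match the mixed model's boundary path exactly. Missing betas are handled
probe-wise complete-case; samples missing covariates are dropped
globally. The experiment-wide threshold defaults to 9e-8.

Cell-proportion covariates: two of the three proportions (NeuN+ and DN)
enter the model; including all three would be collinear (they nearly sum
to a constant), and `ModelSpec` enforces the limit. Proportion-versus-
pathology regressions control age and sex and flag significance at
0.05/6 (three cell types × two regions per measure).

An optional `standardize_predictors` flag rescales each measure to unit
SD for per-SD effect reporting; the default is per-unit (per-stage)
effects, and meta-analysis assumes cohorts harmonized on that scale.

## Empirical-null adjustment

Observed z-scores are fit with a three-component normal mixture — a
central null N(bias, inflation²) plus left and right signal components —
by EM with point estimation (deterministic given the data; the cited
approach in this literature uses a Gibbs sampler for the same model).
Initialization is median/MAD; convergence is a 1e-8 relative
log-likelihood tolerance with the EM monotonicity asserted in tests.
Identifiability: signal components are constrained to be at least as wide
as the null and centered at least 1.5 null-SDs from it. The constraint
is deliberately stronger than a fixed 0.5 z-unit offset: with the weaker
guard, the signal components absorb ordinary Gaussian tail mass and the
null scale is underestimated by ~5% on pure-null data; with it, (bias,
inflation) = (0.3, 1.5) is recovered within 0.05 at n = 10,000 while a
5%-contaminated N(0, 1.2) mixture still yields inflation ≈ 1.17.
`adjust_statistics` rescales z, recomputes two-sided normal p, and
propagates se_adj = |effect/z_adj| with effects left untouched, so
printed effect sizes keep their meaning; a `method="robust"` shortcut
returns median/MAD directly, and EM non-convergence falls back to it
with a warning.

## Meta-analysis

Fixed-effects IVW: pooled effect Σw_i e_i / Σw_i, pooled SE (Σw_i)^(−1/2),
w_i = 1/se_i², probes restricted to those with usable statistics in at
least two cohorts. Cochran's Q and I² are computed and reported per probe
but play no role in inference. Bonferroni thresholds are applied at full
precision; the 3-significant-digit display value (rounded half-up, the
convention for printed thresholds) is carried separately.

## Concordance and amplification

Sign tests are exact one-sided binomial upper tails computed in integer
arithmetic, so full concordance is exactly 0.5ⁿ at any n (no underflow
at n in the hundreds). One-sided is the calibrated choice: the
full-concordance values it produces (e.g. 1.53e-5 at 16/16, 6.78e-21 at
67/67) are the printed convention in this literature, which a two-sided
test would double. Fold-change between a purified fraction and bulk is
the mean of per-site ratios |effect_fraction|/|effect_bulk| (sites with
a bulk effect of exactly 0 excluded and counted); a ratio-of-means
variant is available behind a flag. Per-site ratios are heavy-tailed
when the bulk denominator is noisy — and at discriminating sites the
high/low groups' sampled composition difference is a confounder *shared
across sites* — so the experiment demonstrating the 1/π law uses tight
composition dispersion (Dirichlet concentration 2000), a 4 %/stage
cell-level effect, 0.02 logit-SD noise, and target probes with means in
(0.15, 0.70); under those conditions the 20-seed mean fold-change is
10.2 against the theoretical 10.

## Problem sizes

Test and acceptance runs use: 500–2000 probes; 120–500 donors (two
regions each) for mixed-model studies; 12 reference samples per nuclei
population; 200 mixtures for deconvolution recovery; 15 + 13 donors per
sorted-fraction study with 20 replicate seeds; 10,000 z-scores for
empirical-null recovery. These sizes give each check comfortable
statistical resolution (binomial SE ~0.005 on a 2000-probe type-I rate;
~1% SE on the 20-seed fold-change mean) while keeping the full suite in
tens of seconds.

## Known limitations

* The generator's independence of probes (given composition) understates
  the correlation of real array data; genome-wide significance counts on
  synthetic data are not predictive of real-data yields.
* The LRT's small-sample anticonservatism is not Bartlett-corrected;
  interpret calibration at a few hundred donors or more.
* Deconvolution slope distortion under unmodeled mass (above).
* dasen-style intensity normalization, probe filtering requiring
  manifests, sex checks and SNP fingerprinting are out of scope;
  quantile normalization stands in as a documented simplification.
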