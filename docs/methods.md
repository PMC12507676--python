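# Methods

This note documents the models implemented in `dielniche`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a user should know about.

## Behavioural measures

**Tracking.** The image pipeline assumes a single dark animal on a
brighter, slowly changing background. The background is the per-pixel
95th percentile of the previous window of frames (default 60 min;
shorter windows — 30/20/10 min — track sand displacement better and are
a config switch). Detection takes the largest connected component of
|frame − background| above an intensity threshold, with an inclusive
minimum area of 100 px; the centroid is intensity-weighted by default
(binary centroid is a config option — the choice matters only at the
sub-pixel level). Frames without a detection are linearly interpolated
between flanking detections; leading/trailing gaps take the nearest
detection. Despiking treats any frame-to-frame displacement above
200 px as a tracking artifact (background subtraction latching onto
bubbles or a neighbour) and replaces the frame's position with the mean
over ±5 frames excluding itself; the pass iterates to a fixed point with
a cap of 10 passes so that runs of consecutive artifacts resolve.
Smoothing is a centred 0.5-s boxcar. A known limitation, visible in the
synthetic renders: an animal that stays still longer than the background
window is absorbed into the background and lost until it moves — the
motivation for the shorter background windows.

**Speed, movement, rest.** Speed is the Euclidean displacement of
consecutive positions divided by Δt, assigned to the later frame (the
first frame gets 0 so series lengths match). Movement is speed
*strictly greater* than 15 mm s⁻¹; below that, apparent motion is mostly
tracking noise and fin undulation. Rest is *strictly less* than 5%
movement in a centred sliding 60-s window. Both boundaries are strict
and configurable. The centred window avoids phase bias at bout edges
but erodes up to ~60 s from each end of a genuine rest bout; the
detector is therefore exact against a window-counting oracle while
under-counting total rest by roughly (bouts/day) × 1 min relative to the
underlying two-state process. Days with less than 95% sample coverage
are excluded from daily averages.

**Binning and profiles.** Series are averaged in 48 midnight-anchored
30-min bins per day (partial bins use the available samples and are
flagged through their counts). A species profile is the mean across
complete days, then across individuals; the per-bin SD is reported both
across individuals (default) and across pooled days, since either
reading of "variability" is defensible — the cathemeral rule below can
use either.

**Rhythmicity.** The periodogram is a Fisher g-test on the detrended
binned series: FFT power at the Fourier frequencies, the largest
remaining component tested against the exact Fisher g null
(P(G > g) = Σₖ (−1)ᵏ⁻¹ C(m,k)(1−kg)^(m−1)), iterating until the first
non-significant peak at the 0.05 threshold. This controls the
family-wise error of "any rhythm" at the threshold (verified by
simulation) and detects superposed 24-h and 12-h components.

## Diel-niche classification

Species profiles are z-scored per species over their 48 bins and
decomposed by PCA with **bins as observations and species as features**
(10 components by default), so time bins separate in score space by
light state and species loadings measure diel preference. Component
signs are fixed deterministically: night bins score positive on PC1
(nocturnal = positive loading) and dawn/dusk ramp bins score positive on
PC2 (crepuscular = positive loading). Guilds come from Ward clustering
of the (PC1, PC2) loadings cut at exactly k = 3, with clusters named by
centroid PC1 (most negative → diurnal, most positive → nocturnal,
middle → crepuscular). The cathemeral override fires when
max − min of the species mean profile < 2 × mean per-bin SD (strict
inequality); species order is made irrelevant by sorting on the species
code before linkage.

The bridge-shaped relation between the two loadings is quantified by
regressing PC2 on PC1 + PC1², by OLS and by pGLS; a negative quadratic
coefficient with the ridge near PC1 = 0 is the continuous signature of
the crepuscular bridge.

## Phylogenetic comparative models

All continuous-trait machinery is Gaussian on the Brownian covariance
C[i,j] = depth of the most recent common ancestor of tips i and j.

* **Pagel's λ** multiplies the off-diagonal of C; the ML value over
  [0, λ_max] (λ_max = largest value keeping C(λ) positive-definite,
  found by bisection) is computed with the root state and rate profiled
  out, on a 21-point grid followed by bounded scalar polish — the
  profile likelihood can be flat or bimodal on small trees.
* **Blomberg's K** is (MSE₀/MSE)_observed over its Brownian expectation
  (tr C − n/Σ C⁻¹)/(n−1), with MSE₀ the raw and MSE the C⁻¹-weighted
  mean squared deviation from the GLS mean. The multivariate K for
  profile matrices sums squared deviations across trait columns.
  Permutation p-values shuffle tip rows.
* **pGLS** whitens y and the design by the lower Cholesky factor of C
  and runs OLS on the whitened data; R² is taken against the GLS
  mean-only model. With λ-transformed C this interpolates between OLS
  (λ = 0) and Brownian pGLS (λ = 1). Under Brownian nulls the slope
  test is exact (verified: 5% rejection within the binomial CI over
  2,000 replicates, while OLS on the same structured data over-rejects).
* **Phylogenetic ANOVA** keeps the classical F statistic and draws its
  null from Brownian simulations on the tree (rate from the data; F is
  scale- and location-invariant so the plug-in rate is exact);
  p = (1 + #{F_sim ≥ F_obs})/(n_sim + 1).
* **Two-block PLS** whitens both blocks by C, centres on the GLS mean,
  and SVDs the cross-covariance; r-PLS is the correlation of the paired
  first singular scores, adjusted R² is reported in both regression
  directions (the direction is genuinely ambiguous for a summary
  statistic, so both are emitted), and the permutation p shuffles the
  tip assignment of the second block.
* **BM / OU / EB fits** transform C: OU (root-conditioned, suitable for
  ultrametric trees) takes C → e^{−α d_ij}(1 − e^{−2α t_ij})/(2α); EB
  takes t → (e^{rt} − 1)/r with r ≤ 0. The root state and σ² are
  profiled analytically, leaving one-dimensional searches in α or r
  (log-grid plus bounded polish; a fit at the boundary collapses to the
  exact BM solution). Comparison uses AICc with k = 2 (BM) or 3
  (OU, EB): AICc = −2logL + 2k + 2k(k+1)/(n−k−1).
* **OU ancestral states** are the conditional means of the internal
  nodes given the tips under the fitted model (for a Gaussian model
  these are also the joint ML states; verified against brute-force
  likelihood maximization on a 4-tip tree). When α̂ sits at the zero
  boundary the reconstruction falls back to Brownian motion with a
  warning.
* **Mk models** use Felsenstein pruning with per-branch transition
  matrices from one eigendecomposition of Q per likelihood evaluation
  (falling back to `expm` when Q is ill-conditioned), partials rescaled
  per node against underflow. Rate patterns: ER (1 free rate), SYM
  (k(k−1)/2), ARD (k(k−1)), and the bridge variants which remove the
  diurnal↔nocturnal pair (5 and 10 free rates on four states). The
  root prior is flat by default (stationary and FitzJohn are options).
  Optimization is bounded L-BFGS-B on log rates with 5 seeded random
  restarts by default — ARD-class likelihoods are multimodal on small
  trees. Discrete models are compared by AIC (= −2logL + 2k), the
  continuous ones by AICc, mirroring common practice for each family.

## Synthetic data

Every generator is a pure function of its parameters and a seed.

* **Tracks.** A diel intensity template (day/night square wave following
  the light ramps plus Gaussian bumps centred on dawn and dusk) sets the
  expected active swim speed; a two-state semi-Markov process with
  phase-dependent bout rates inserts contiguous rest bouts, during which
  speed is sub-threshold jitter. Active speed keeps a floor of 1.5× the
  movement threshold so the rest detector sees exactly the generated
  bout structure; a template with base speed 0 is fully at rest. The
  four guild templates are calibrated qualitatively (there is no
  quantitative published speed profile per guild): contrast 0.8 for
  diurnal/nocturnal, a crepuscular gain of 1.2 with contrast 0.1 for
  crepuscular, and zero contrast and gain for cathemeral, with rest-bout
  rates placing most rest in the inactive phase. Artifacts are opt-in:
  missing-detection runs and single-frame spikes > 200 px.
* **Cohorts.** For whole-study runs (60 species × 8 individuals ×
  6 days) the generator emits per-individual 48-bin day matrices
  directly from the same template arithmetic (expected bin speed =
  active fraction × active speed + rest fraction × jitter mean), with
  individual- and day-level Gaussian noise (2 and 3 mm s⁻¹ SD).
  Simulating 10 Hz positions for 480 individuals would cost ~2.5 × 10⁸
  samples and add nothing at 30-min resolution; full tracks remain
  available for the tracking/rest stages at any fps. Cathemeral species
  get per-individual random sinusoidal phase preferences (swing 0.6), so
  their species mean is flat while the across-individual SD is large —
  the signature the cathemeral rule keys on.
* **Trees, traits, histories.** Pure-birth trees rescaled to unit
  depth; BM/OU/EB traits as multivariate-normal draws from the model
  covariance; discrete histories by Gillespie simulation along branches
  with the full transition list retained (so bridge-constrained
  simulations can be checked for the absence of direct day↔night
  jumps).
* **Genotype panels.** Null allele frequencies evolve by Brownian
  motion on the logit scale along the tree (σ = 1.5), keeping f in
  (0, 1) with the phylogenetic correlation the pGLS must absorb.
  Planted sites draw x = 2f − 1 = ρ·trait + √(1−ρ²)·(structured noise)
  with ρ = β/√(1+β²), consistent with trait = β·x + unit noise (β = 2
  by default, a signal-to-noise ratio of two). Two diploid individuals
  per species receive Hardy–Weinberg genotypes, Poisson depth (mean 10),
  binomial allele sampling with per-read error 0.01, and exact
  GATK-style diploid PLs. INFO annotations are drawn with labelled
  failures (8% quality, 5% forced depth failures, plus indel /
  multiallelic / unplaced / singleton contamination) so the filter
  stage can be scored exactly. With 120 individuals at depth 10 the
  summed DP lands inside the 900–1900 gate by construction; small test
  panels must raise the per-individual depth accordingly.

What the generators do **not** emulate: multi-fish occlusion,
photorealistic video, read-level alignment artifacts, linkage
disequilibrium between sites, within-species trait variance in the
comparative models, and temperature or feeding effects on activity. A
green suite therefore shows the chain is correct under its stated model,
not that the model captures every property of real recordings.

## Allele-frequency posterior

For one species, the EM iteration maximizes Σ_ind log Σ_g L(g)·HW(g|f)
with HW(g|f) = {(1−f)², 2f(1−f), f²}; at the fixed point f̂ equals the
posterior-mean allele dosage over individuals divided by the chromosome
count, which is the reported frequency (the MAP-genotype count is also
emitted). Ref/alt-swap equivariance (f → 1 − f) is made exact in
floating point by evaluating each PL block in a canonical orientation
and flipping the result; the identity is bitwise in the canonical
direction, and a palindromic PL block converges to ½ within one ulp.
The estimate tracks the *realized* genotype frequency (mean absolute
error ~0.01 at depth 10); its deviation from the latent population
frequency is dominated by drawing only four chromosomes per species and
is irreducible at the estimation stage. Likewise x = 2f − 1 is exact
arithmetic for f = 0 and f ≥ ½ and correct to half an ulp elsewhere —
IEEE subtraction forbids more.

## GWAS and HAV calling

The GLM test is per-SNP OLS of the trait on x; the pGLS test whitens
the trait and every SNP column by the Cholesky factor of C once,
projects out the whitened intercept and runs mass simple regression —
algebraically identical to per-SNP `pgls` and equal to the GLM on a
star tree. Default HAV cutoffs are the smallest 1% of pGLS p-values
AND GLM p < 10⁻³, both configurable; the quantile is scaled to the
desk-sized panels generated here (a panel of tens of millions of SNPs
would use a far smaller quantile, e.g. 0.01%). Recall/precision against
planted sites are computed over the sites that survive selection, since
a site removed by the (correct) filters is invisible to the caller.

## Problem sizes

The test suite and the acceptance script run the studies at sizes chosen
for a single CPU: bridge-model recovery on a 200-tip tree × 100
replicates (tests) and 150 tips × 40 replicates (script); type-I
calibration at 2,000 replicates; K under BM at 1,000 replicates; λ
recovery at 100 replicates of 200 tips; GWAS on 6,000 sites × 60
species with 30 planted associations; tracking on 1,500–2,000 rendered
120×160 frames. These sizes give Monte-Carlo errors comfortably inside
the asserted tolerances.
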