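# Methods

`traitscan` implements a complete analysis chain linking a continuous
autistic-trait score (ASQ, 0–50) to task-fMRI responses: per-subject
first-level GLMs on an event-related emotional-face paradigm, spherical
searchlight support-vector-regression (SVR) decoding of the trait from
emotion>neutral contrast maps, generalized psychophysiological
interaction (gPPI) seed connectivity, and a group-level OXTR-genotype ×
trait moderation analysis.  Because raw fMRI of this kind is rarely
shareable, the package ships a synthetic cohort generator with known
ground truth; every downstream stage is validated by parameter recovery
and calibration experiments on that generator.

## Synthetic cohort model

**Paradigm.** Five expression conditions (angry, fear, happy, neutral,
sad), ten grayscale face stimuli each, presented once per run in a
pseudorandom order over two runs of 173 volumes (TR 2.0 s).  Inter-trial
intervals are uniform on 2–6 s (jitter is configurable; the first onset
is at 10 s and the schedule builder verifies that the run covers the last
event plus 32 s of HRF support).  Stimulus duration defaults to 1 s in
the event tables; the GLM models events as impulses by default.

**Trait scores.** A two-parameter-logistic item model generates the 50
binary questionnaire items: subject i endorses item j with probability
`logistic(a (theta_i - b_j))`, with common discrimination `a = 0.35` per
score point and equally spaced difficulties `b_j = j - 0.5`.  Equal
spacing makes the expected total approximately equal to the latent trait
away from the floor/ceiling, so the latent scale is the score scale.
The latent normal defaults to mean 21.4 and SD 5.34; binary-item noise
adds roughly `1/a` to the total-score variance, yielding totals with
mean ≈ 21.4 and SD ≈ 5.6 — the distribution reported for large
neurotypical samples on this instrument.

**Genotypes.** Four OXTR SNPs (rs2254298, rs2268491, rs2268498, rs53576)
are drawn as two independent alleles per subject, i.e. exact
Hardy–Weinberg proportions p², 2pq, q².  Default risk-allele frequencies
(0.50, 0.25, 0.45, 0.60) approximate East-Asian population values.
Subjects are dichotomized by dominant carrier grouping (≥1 risk allele:
A+/T+ vs A−/T−), the convention used for these SNPs.

**BOLD.** Per voxel and scan,
`BOLD = baseline + Σ_c amp_c · (HRF ⊛ sticks_c) + noise` with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6, unit peak) and
i.i.d. Gaussian scan noise (SD 1.0; AR(1) optional, off by default so
that OLS oracles are exact).  Three disjoint ground-truth regions are
embedded in an ellipsoidal grey-matter mask:

- **Pattern region** (default: radius-4 ball, 257 voxels).  The
  angry-condition amplitude of subject i at voxel v is
  `w_v (s z_i + g_i) + e_iv`, where `z_i` is the standardized trait,
  `w_v ~ N(1, 0.25)` are fixed pattern weights, `g_i ~ N(0, 0.3)` is a
  shared (global-gain) amplitude perturbation and `e_iv` is a spatially
  smooth field (marginal SD 0.5, Gaussian correlation σ = 1.5 voxels)
  covering the whole mask.  The slope `s` is calibrated in closed form so
  that the correlation between the trait and the regional-mean true
  amplitude equals a target (default 0.5); the calibration accounts for
  the smooth field's average pairwise autocorrelation
  `exp(-d²/4σ²)`.  The decomposition into a shared gain plus a smooth
  local field mirrors two robust properties of real beta maps —
  between-subject amplitude variability is dominated by global
  vascular/arousal factors, and preprocessed maps are spatially smooth.
  Both properties are *load-bearing* for multivariate decoding: with
  purely independent voxel noise, a C = 1 linear SVR given ~120 features
  and ~50 training subjects interpolates the noise and decodes nothing,
  regardless of the regional-mean signal.
- **Coupling seed** (radius-1 ball).  Seed voxels carry a common neural
  series: the all-condition stick train plus a smooth spontaneous
  fluctuation (SD 1.0), convolved with the HRF.  The fluctuation is what
  makes the PPI regressors identifiable (a purely task-locked seed would
  be collinear with the psychological regressors).
- **Coupling target** (radius-2 ball).  Target voxels additionally
  receive `Σ_c gain_ic · (HRF ⊛ (seed neural × indicator_c))`, with
  `gain_ic = base + slope(group_i) · z_i` for the angry condition and
  `base` otherwise.  Default slopes are +0.5 for non-carriers and −0.5
  for carriers of the rs2254298 risk allele, a deliberately well-powered
  crossover so that desk-scale cohorts (n = 60) recover the interaction
  reliably; real effects of this kind are far smaller and need hundreds
  of subjects.

Motion parameters are simulated as per-run random walks and used purely
as nuisance regressors (they do not corrupt the BOLD); head-motion
artifacts, physiological noise, k-space effects and slice timing are out
of scope.  All draws are keyed to `CohortSpec.rng_seed` with per-subject
child streams, so cohorts are bit-reproducible and volumes can be
regenerated lazily.

What passing recovery tests on this generator shows: the pipeline's
estimators are unbiased and correctly wired at realistic SNR and with
realistic spatial structure.  What it cannot show: robustness to motion,
distortion, inter-subject anatomical misalignment, or non-Gaussian
physiological noise.

## First-level GLM

Runs are fitted jointly with run-specific condition, motion and
intercept columns (5 + 6 + 1 per run).  Condition regressors are stick
trains convolved with the canonical HRF on a 16× oversampled grid and
downsampled to scan onsets.  Estimation is voxelwise OLS without
prewhitening (the default synthetic noise is white; enable AR(1) in the
generator and prewhitening is a natural extension, not currently
implemented).  Contrast maps average the condition beta difference
across runs.  On noiseless simulations the GLM recovers injected
amplitudes to numerical precision (~1e-13), which is the module's
primary correctness oracle.

## Searchlight SVR decoding

For every in-mask center voxel, features are the in-mask voxels within a
3-voxel-radius lattice sphere (123 offsets; truncated at the mask edge,
centers with fewer than 10 members are undefined).  A linear
epsilon-insensitive SVR (C = 1, ε = 0.1) predicts the trait under
10-fold cross-validation; one balanced random partition is drawn per map
(seeded) and shared across centers.  Out-of-fold predictions are pooled
and scored by the Pearson correlation with the observed scores.

**Solver.** ~10⁴ sphere×fold fits per map make libsvm (~18 ms/fit)
impractical; the searchlight uses a numba-compiled dual coordinate
descent on the precomputed per-sphere Gram matrix (targets centered on
the training mean; the bias is carried by an augmented constant feature
of height 10, the liblinear intercept-scaling device, so the dual is a
box-constrained problem with closed-form coordinate updates and a
randomized visit order).  The solution matches the standard
unregularized-bias SVR primal to ~1e-2 on the prediction scale —
verified against both an SLSQP quadratic program and libsvm — at ~0.2 ms
per fit.

**Scoring and inference.** Two refinements beyond the naive pooled
correlation:

1. *Fold-mean adjustment* (default on): fold means are partialled out of
   predictions and outcomes before correlating (t degrees of freedom
   reduced by k−1).  Out-of-fold predictions contain the training-fold
   mean, which is anti-correlated with the held-out outcomes by
   construction, biasing the naive pooled r negative under the null.
2. *The parametric p is anti-conservative, by design of the statistic.*
   The default per-voxel p uses the two-sided t transform of r.  Under
   the global null this p is **not** uniform: the pooled CV correlation
   is a symmetric quadratic form in the outcomes (the prediction for
   subject j loads on y_i through training, and vice versa, coherently
   because the Gram is symmetric), which roughly doubles the null
   variance of r relative to the t reference.  Simulated null cohorts
   show a voxelwise false-positive rate of ~0.15 at nominal 0.05, for
   independent and spatially structured noise alike, and no
   rearrangement of folds removes the effect (per-fold Fisher-z
   averaging shows the same inflation; the coherence is cross-fold).
   `SearchlightSpec(p_method="calibrated")` therefore estimates a global
   variance-inflation factor by re-running the CV on trait permutations
   over a random subset of centers (defaults: 20 permutations × 128
   centers; the factor is a property of the learner and fold structure,
   not of the center) and rescales the z statistic; this restores the
   nominal rate in simulation.  The t default is retained because it is
   the convention of the emulated analysis style; any map intended for
   inference should use the calibrated option, and the detection
   threshold it implies is markedly higher — at n = 60 a true
   prediction-outcome correlation of 0.5 is near the edge of
   detectability under whole-mask FDR at q = 0.0125.

Multiple comparisons use Benjamini–Hochberg step-up within the mask; the
per-map level is the family level divided by the number of emotion
contrasts (0.05 / 4 = 0.0125).

## gPPI

Seed series are means over 6-mm spheres mapped through the grid affine
(center-in-sphere rule).  The neural series is estimated by ridge
deconvolution `(H'H + λI)^{-1} H' b` with λ = 1e-2, where H is the HRF
convolution operator on the scan grid (oversampling configurable;
the default scan-grid problem is square and well-posed, and satisfies
conv(deconv(x)) ≈ x within 10% and boxcar recovery correlation > 0.95 on
noiseless inputs — at finer grids the inverse problem is underdetermined
and needs a larger λ).  This linear inverse replaces the empirical-Bayes
deconvolution of the classical toolbox: same role, simpler contract.
The PPI design per run contains the seed series (physiological), five
condition regressors, five PPI regressors — neural series × condition
indicator, reconvolved — plus motion and intercept.  The coupling map is
the voxelwise OLS beta difference angry-PPI − neutral-PPI, the only
context with genotype effects in the emulated analysis (other contrasts
by argument).

## Group genotype × trait moderation

Per-subject coupling maps enter a voxelwise OLS model with intercept,
carrier group (±½ coding), mean-centered trait, and their product; the
interaction t (df = n − 4) is thresholded by **permutation max-|t| FWE**
(Freedman–Lane: reduced-model residuals permuted and added back to the
reduced fit; corrected p = (1 + #{max |t*| ≥ |t|}) / (n_perm + 1),
default 1000 permutations).  Permutation FWE replaces random-field
theory peak FWE, whose smoothness estimation is ill-posed on desk-scale
grids; its family-wise error control is verified by simulation.
Surviving voxels are clustered under 18-neighbor connectivity with an
extent filter k > 10, corrected ×3 across tested emotion contrasts
(Bonferroni), and per-cluster mean couplings are correlated with the
trait within each carrier group (Bonferroni ×8 across 4 SNPs × 2 allele
groupings), flagging slope-sign opposition — the crossover signature.
Tests are two-sided throughout; one-tailed reporting is available only
as an explicit option.

## Statistics utilities

Hardy–Weinberg QC is the conventional 1-df chi-square against p̂², 2p̂q̂,
q̂² (exact test not implemented).  Repeated-measures ANOVA is the
one-way within-subject SS decomposition with uncorrected degrees of
freedom and partial eta squared (no sphericity correction, matching the
reporting style emulated; cross-checked against pingouin).  Power
computations back the sample-size claim: Pearson correlation power by
the Fisher-z approximation (medium effect r = 0.3) and two-sample t
power by the noncentral t (d = 0.5, groups 131/124); the minimum of the
two families exceeds 0.90 at N = 255 and α = 0.05 two-sided.

## Numerical and testing choices

Problem sizes in the test-suite simulations — 60-subject cohorts on a
16³ grid, 50 null cohorts for type-I checks, 200 synthetic-map cohorts ×
500 permutations for FWER, 20 seeds for interaction recovery — are the
package's chosen desk-scale operating points: large enough for the
binomial error bands asserted in the tests, small enough to run on one
CPU in minutes.  Degenerate inputs fail loudly (constant trait vectors,
single-group designs, empty seed intersections, rank-deficient designs,
overlapping ground-truth regions).  Known limitations: no spatial
smoothing or anatomical labeling; the parametric searchlight p is
anti-conservative as documented above; the gPPI beta scale is
arbitrary (deconvolution and reconvolution are not scale-normalized), so
only relative/comparative coupling quantities are meaningful.
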