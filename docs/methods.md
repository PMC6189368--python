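# Methods

## The analysis model

The pipeline treats each subject's resting-state run as a 4D array on a
common grid (the data are assumed already motion-corrected and spatially
normalized upstream; motion *parameters* are consumed as input, never
estimated).  Analysis proceeds in five stages.

**Temporal preprocessing.**  Two variants share the same skeleton —
discard the first 10 volumes, scrub high-motion frames, regress nuisance
signals, band-pass 0.01–0.1 Hz — and differ in exactly two switches:

| switch | wGBC path | seed-FC path |
|---|---|---|
| global-signal regressor | included | excluded |
| 6 mm spatial smoothing | of the final map | of the time series, before scrubbing |

The FC path keeps the global signal because regressing it shifts the
correlation distribution negative and exaggerates anti-correlations; the
wGBC path removes it so the average-correlation statistic is centred.
Framewise displacement follows the Power convention,
FD_t = Σ|Δ translation| + 50 mm · Σ|Δ rotation| with FD_0 = 0; frames with
FD > 0.5 mm are deleted, and a run with more than 1.5 mm translation or
1.5° rotation on any axis (strict inequality, compared in radians to avoid
degree-conversion round-off) is excluded outright.  Nuisance regression
uses an intercept, the six motion parameters, and mean signals over
supplied white-matter and CSF masks (plus the global mean on the wGBC
path); linearly dependent columns are dropped with a warning.  The
band-pass is a zero-phase (forward–backward) Butterworth of order 5; the
filter family is a free choice, pinned instead by a testable transition
contract (≤ 5% loss at 0.05 Hz, ≥ 20× attenuation at 0.2 Hz, TR = 2 s).
Band-pass runs after nuisance regression on the concatenated retained
frames; deleting frames before filtering is an acknowledged approximation,
irrelevant in the no-scrubbing regime the generator produces by default.

**wGBC.**  Within the gray mask (tissue probability strictly > 0.2), each
voxel's Pearson correlations to all other masked voxels are Fisher
transformed with |r| clipped at 1 − 1e−7 (keeps atanh finite), averaged
*with sign* (no thresholding or absolute value), and back-transformed.
Zero-variance voxels are dropped from seed and target sets with a logged
count.  Targets default to the gray mask; a `targets="wholebrain"` switch
correlates against every finite-variance voxel in the grid instead, for
users who prefer the literal whole-brain reading.  The computation streams
seed blocks against the standardized data matrix, so memory stays
O(V·T + block·V) and the V×V matrix never materializes.  Map smoothing is
mask-normalized convolution: NaN voxels outside the mask carry no weight
and do not bleed inward.

**Group inference.**  Subject maps enter a per-voxel OLS GLM
(intercept, group 0/1, age, sex, education; t for the group contrast with
df = n − p).  With no covariates this reduces exactly to the pooled
two-sample t-test, which the tests assert to 1e−10.  One-sample t maps
describe the within-group wGBC distribution.

**Cluster-extent correction.**  Monte-Carlo (AlphaSim-style): fill the
mask's grid with unit Gaussian noise, smooth to the target FWHM,
re-standardize within the mask, threshold two-sidedly at |z| above the
voxel-level p = 0.001 cutoff, and record the maximum connected cluster
extent over both signs (connectivity 18 by default; 6 and 26 available).
The significant-extent threshold is the smallest integer k whose null
probability of being reached by the maximum extent is ≤ α = 0.05 — the
convention of the AlphaSim/3dClustSim tables.  Because extents are
integers the attainable error rates are discrete (e.g. 0.046 rather than
0.050 on a 16³ cube at 6 mm smoothness); this rule always lands on the
conservative side of α.  The FWHM fed to the simulation is estimated from
the GLM residuals, not the nominal applied kernel, since intrinsic plus
applied smoothness is what governs null cluster sizes: per axis, the lag-1
autocorrelation ρ of the standardized residuals (from the variance of
first differences, pooled over subjects) gives FWHM = √(2 ln 2 / −ln ρ)
voxels under a Gaussian autocorrelation model.  Estimates are floored at
one voxel because sub-voxel smoothness is unresolvable on the sampling
grid — pure white noise therefore reports ≈ the voxel size.  On noise
smoothed to a known 6 mm kernel the estimator recovers it within 15%.
Data clusters are formed at the matching two-sided Student-t cutoff for
the map's df, positive and negative components labeled separately.

**Seed FC and cohort statistics.**  Each corrected-significant cluster
seeds a whole-brain Fisher-z correlation map (seed series = unweighted
mean over cluster voxels, the common convention) from the FC-variant runs;
group comparison of the z maps reuses the GLM + Monte-Carlo machinery at
identical thresholds, without further smoothing (the series were already
smoothed).  Demographics use a Pearson chi-square **without** Yates
correction for the 2×2 sex table and **pooled-variance** Student t-tests
for age/education — the conventions pinned down by the published
p-values (0.71/0.69/0.31): with Yates the sex p would be ≈ 0.92, with
Welch the education p ≈ 0.36.  Cluster-mean values correlate against
symptom scores by Pearson r with a t-transform p (df = n − 2).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the physics of acquisition.  Every voxel's series is

x_v = √g·G + √(1−g)·( Σ_k a_vk·L_k + b_v·N_v ),  b_v² = 1 − Σ_k a_vk²,

where the L_k are unit-variance latent signals with flat spectral power in
0.01–0.08 Hz (synthesized in the frequency domain — broadband signal would
be discarded by the 0.01–0.1 Hz band-pass anyway), N_v is stationary
unit-variance AR(1) noise, and G is a brain-wide band-limited "global"
component.  Couplings a²: voxels of hub sphere k carry its latent at
variance fraction c_k; a fixed fraction of non-hub gray voxels
("carriers") mix all hub latents at a small total coupling; everything
else is pure noise.  Group effect regions add a signed delta to the
member voxels' dominant coupling for group-B subjects only, planting a
known group difference.  Output is scaled ×10 and offset +1000 to look
BOLD-like.

Defaults, chosen once as realistic study conditions and not revisited:

| parameter | default | rationale |
|---|---|---|
| grid / volumes / TR | 20³ vox (16³ in acceptance studies), 160, 2 s | desk-scale; the 64×64×33×240 acquisition is unnecessary for testing |
| voxel size | 3 mm isotropic | typical normalized resolution; free choice, flagged in config |
| hub coupling | 0.6 | a strong, clearly detectable hub |
| carrier fraction / coupling | 0.30 / 0.15 total | hub latents reach ~a third of the brain weakly, giving hubs elevated mean correlation |
| global component g | 0.1 | without it the hub latents dominate the global mean and global-signal regression deletes them; real global signal is mostly non-neuronal and brain-wide, which is precisely why the regressor exists |
| AR(1) φ | 0.3 | typical BOLD temporal autocorrelation at TR 2 s |
| planted effect | own sphere at coupling 0.2, +0.4 for group B | an expected wGBC difference of ≈0.04 against a between-subject SD of ≈0.02, i.e. t ≈ 5 at 12+12 — a strong effect, as the recovery criterion presumes |
| motion | random walk, median FD 0.08 mm | the published cohort's no-scrubbing regime (all FD < 0.3) |

Motion spikes are *persistent position steps*, so FD exceeds 0.5 mm at
exactly the injected indices (a one-frame offset would also trip the
following frame).  Demographics are normal draws per group matching the
published means/SDs (ages ≈ 30 ± 7, education 13–14 y, symptom scores
34.3 ± 7.6 in group A only) with the exact 9/14 and 15/19 male/female
splits at sizes 23/34, proportional otherwise.  Sex is encoded 0 = female
/ 1 = male and group 0 = A (patients) / 1 = B (controls), fixed
conventions.  Anatomy is a radial gray-probability gradient (1 at the grid
centre → 0 at the edge) so the "> 0.2" mask rule cuts a nontrivial
boundary, with white-matter and CSF shells outside the gray core feeding
the nuisance regressors.  All randomness derives from one seed via spawned
child streams; identical spec + seed reproduces bit-identical arrays and
NIfTI bytes.

What the generator does **not** emulate — scanner drift and spike
artifacts, physiological cycles, slice-timing and EPI distortion,
spatially varying noise, anatomically realistic tissue geometry, and any
true anatomical localization — bounds what green tests mean: they show the
statistics and their calibration are implemented correctly, not that the
published cluster locations would reproduce on real scans (the patient
data are not deposited, so those are out of reach by construction).

## Numerical choices and degenerate inputs

Correlations are clipped at 1 − 1e−7 before atanh; wGBC values are
strictly inside (−1, 1).  Quantile/threshold comparisons follow the strict
conventions stated above (prob > 0.2, FD > 0.5, motion > limits).  The
Monte-Carlo simulation re-standardizes each null field within the mask,
matching the unit-variance assumption of the voxel threshold.  Rank
deficiency: nuisance matrices drop dependent columns with a warning and
fail only if still deficient; the GLM refuses rank-deficient designs and
names the collinear columns.  Zero-variance voxels get t = 0 (one-sample)
or are dropped (wGBC) with logged counts.  Masks under 100 voxels or
constant residuals make the smoothness estimator fall back to the nominal
applied FWHM with a warning.  Scrubbing below a configurable minimum of
retained volumes (default 50) raises, signalling subject exclusion.

## Study conditions used by the acceptance checks

Desk-scale reductions keep the whole suite within minutes on one CPU:
recovery and specificity run twenty 12+12-subject cohorts each (16³ grid,
160 volumes, planted delta +0.4) with 1000 Monte-Carlo iterations per
cohort, and the familywise-error calibration uses a 1000-iteration
threshold evaluated on 200 fresh 16³ null fields at 6 mm smoothness.
`scripts/acceptance.py` re-runs exactly these conditions from a
command-line seed.

## Known limitations

Filtering after frame deletion treats the retained frames as contiguous.
The cluster correction assumes stationary Gaussian-autocorrelated null
fields; wGBC maps inherit some non-stationarity from the hub/carrier
structure, and empirically the end-to-end familywise error on null
cohorts matches the nominal 0.05 at the tested settings.  The open
ambiguity between gray-mask and whole-brain target sets is exposed as a
config switch rather than resolved.  The Welch option, unweighted GBC,
FDR/permutation inference and surface-based analysis are deliberately out
of scope.
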