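# Methods

`dosefield` implements a multi-level framework for estimating dose-response
relationships in transcranial electrical stimulation (tES): the *dose* is the
simulated cortical electric-field (EF) magnitude each subject receives
(V/m, on a volumetric grid co-registered with the fMRI data), the *response*
is the change in task-evoked BOLD activity or task-modulated connectivity
from a pre-stimulation to a post-stimulation scan. Associations are
quantified at four levels — voxel, atlas region, activation cluster, and
network — in a two-arm (active vs. sham) design. Because the motivating
study's participant MRI data are not public, the package ships a synthetic
cohort generator that emulates the study's conditions and plants a known
dose-response structure, making calibration and parameter recovery
first-class, testable properties.

## Data model

All volumes live on an explicit `GridSpec` (dims + 4×4 voxel-to-world
affine, RAS+ mm). Sphere centres, radii and cluster peak coordinates are
always world-space millimetres. The full-scale analysis grid is
96×114×96 at 2 mm (~1,050,624 voxels); simulation studies use a 16³ grid at
4 mm with a spherical 28-mm "brain" mask so that hundreds of replicate
cohorts fit in minutes on one CPU. The grid is configuration, never
hard-coded.

Undefined values (non-brain voxels, zero-variance correlations, subjects
excluded for motion) are NaN and are excluded from multiple-testing
families rather than imputed.

## Synthetic cohort

One cohort = `n_active + n_sham` subjects (default 30/30, the study's
arm sizes) sharing a grid, an atlas, and one task design.

**EF surrogate.** Each subject's EF magnitude map is a two-lobe Gaussian
field: an anode lobe at a right-frontal locus (F4-like) and a 0.8-weighted
cathode lobe at a left-supraorbital locus (Fp1-like), with per-subject
lognormal amplitude (mean 0.25 V/m, CV 0.3 — a modelling choice; typical
reported prefrontal EF peaks are a few tenths of a V/m) and 2-mm positional
jitter. This is *not* a finite-element head model; the pipeline consumes EF
maps and is agnostic to their provenance.

**Task.** A cue-reactivity block design: 4 drug-cue ("meth") and 4 neutral
blocks in randomized order, each 31 s (6 pictures × 5 s + 5 × 0.2-s gaps),
followed by a 6-s unmodelled response period, with 8–12-s fixation between
blocks and a lead-in/tail; total ≈ 6.5 min at TR = 2 s (~194 volumes).

**BOLD.** Three "nodes" (seed = frontal sphere under the anode, parietal,
amygdala) carry HRF-convolved condition signals with configurable
amplitudes (seed: meth 1.0 / neutral 0.2). The parietal node couples to the
seed with a baseline physiological coupling (0.6) plus a *condition-specific*
coupling built exactly as a gPPI interaction term (centred seed signal ×
centred meth regressor; baseline 0.3). Every in-brain voxel receives i.i.d.
AR(1) noise (φ = 0.3, SD 0.8 in units of the seed's meth amplitude). These
values were chosen so that single-voxel contrasts are noisy (low voxel-level
power at n = 30) while node-averaged connectivity estimates are precise —
the regime the multi-level framework is designed to probe.

The condition-specific coupling term is the gPPI interaction regressor
orthogonalized against the full censored first-level design (drift, motion
and evoked regressors, over the frames that survive motion censoring).
This makes the plant a *pure* connectivity modulation: it changes the
seed-target coupling with zero footprint on the evoked-amplitude betas, so
the regional (voxel/ROI/cluster) analyses see an exact null under a network
plant. Without the orthogonalization, row-deletion censoring couples the
interaction term to the condition regressors and a coupling change aliases
into amplitude change — a real phenomenon in censored GLMs, but one that
would confound the level-contrast property the generator exists to probe.

**Plant.** The planted effect is the ground-truth dose-response structure:

- `network` (default): for active-arm subjects only, the post-session
  meth-vs-neutral coupling gains `delta = gamma * meanEF(seed node) + eps`,
  `eps ~ N(0, noise_sd)` (default 0.4). `gamma` is calibrated from a target
  population correlation `rho` via
  `gamma = rho/sqrt(1-rho^2) * noise_sd / sd(meanEF)`, where the population
  SD of the node-mean EF is computed from the lognormal amplitude moments
  and a short deterministic Monte-Carlo over the positional jitter. Default
  `rho = 0.60`, chosen so that the network level is well-powered
  (two-sided Pearson power ≈ 0.9 at n = 30) while regional levels remain
  null — the level-contrast regime. Sham subjects' planted delta is exactly 0.
- `roi` / `voxel`: the post-session meth amplitude of a target region or
  voxel set gains the same `delta` form.
- `none`: global null, used for calibration studies.

Ground truth (per-subject dose and planted delta) is stored in the cohort
and in a YAML sidecar; the analysis pipeline never reads it. Parameter
recovery tests regress truth on truth, and pipeline recovery compares
measured quantities against the planted population values.

**Motion and craving scores.** Motion is a 6-parameter random walk
(SD 0.02/TR) with occasional persistent jumps (p = 0.02, size 0.5) that
exceed the censoring threshold. VAS craving scores at T0–T5 follow pooled
timepoint means (55, 41, 62, 22, 26, 12, anchored to the study's printed
group means) with a subject random intercept — a time effect with no group
effect, by construction.

## First-level GLM

Per subject and session, voxelwise OLS with columns: Legendre polynomials
of order 0–2 ("three polynomial terms", per-run drift), the six motion
parameters, and one HRF-convolved 31-s block regressor per condition. The
HRF is the canonical double gamma (peak 6 s, undershoot 16 s, ratio 6),
peak-normalized; boxcars are built on a 10× upsampled grid because the
0.2-s picture gaps are sub-TR. TRs whose motion-derivative Euclidean norm
exceeds 0.3 are censored by row deletion (no spike regressors, no
imputation); a session with > 50 % censored TRs is excluded with a warning.
Prewhitening is deliberately omitted: OLS betas are unbiased under AR noise
and only their standard errors (which the pipeline does not use at the
first level) are affected. The response map is the post-minus-pre change in
the meth > neutral contrast.

## The four association levels

Association analyses run in the active arm (the sham arm is analysed only
at the network level, as a negative control).

1. **Voxel.** EF maps are linearly resampled to the functional grid,
   vectorized over the brain mask into voxels × subjects matrices, and each
   voxel's dose column is Pearson-correlated with its response column.
   Two-sided p-values from the t-transform (df = n−2) form a single
   Benjamini–Hochberg family over defined voxels (q = 0.05). The r-map is
   summarized into effect-size bins on |r|: ≤ 0.1 negligible, (0.1, 0.3]
   small, (0.3, 0.5] medium, > 0.5 large (boundaries to the lower bin; the
   bins are open intervals in the source convention, so boundary assignment
   is measure-zero).
2. **ROI.** Region-mean dose vs. region-mean response across subjects, one
   row per atlas region with ≥ 1 in-mask voxel, BH over regions. Both
   uncorrected p and q are reported.
3. **Cluster.** A voxelwise linear mixed-effects model with time, group and
   time×group fixed effects and a subject random intercept. On balanced
   complete data the interaction t-statistic is computed through its exact
   closed form — the two-sample t comparing arms on within-subject
   difference scores (df = n_active + n_sham − 2); unbalanced data fall
   back to REML (statsmodels MixedLM). The t-map is thresholded two-sided
   at voxel p < 0.005, positive and negative suprathreshold sets are
   component-labelled separately (default connectivity 18, configurable;
   the source does not state a neighbourhood), and clusters must exceed a
   minimum extent. The extent is either fixed (the `paper2023` preset uses
   k = 41, honouring "size > 40") or calibrated by Monte-Carlo: white
   Gaussian fields smoothed to the residual smoothness, standardized within
   the mask, thresholded identically; k is the smallest integer whose null
   max-cluster-size exceedance probability is ≤ α. Residual smoothness is
   estimated per axis from the variance of spatial first differences of the
   standardized difference-score residuals, reported as the composite FWHM
   including the intrinsic voxel-size contribution (white noise ≈ voxel
   size). Surviving clusters get a cluster-mean dose vs. cluster-mean
   response correlation, BH over clusters.
4. **Network.** The seed is a 10-mm sphere centred at the centre of mass of
   voxels above the 99th percentile of the group-mean EF map (peak-voxel
   centring is available by configuration; centre-of-mass is the default
   reading of placing a sphere "around" the suprathreshold set, and the
   percentile applies to in-mask mean-EF values). Generalized PPI: the
   design contains drift terms, the HRF-convolved psychological regressors,
   the physiological seed series, and per-condition interaction columns
   (centred seed BOLD × mean-centred condition regressor, then mean-centred
   — the centring is absorbed by the intercept and makes the interaction
   columns orthogonal to it). When a motion table is supplied it provides
   both the censor vector and six nuisance columns (zero-variance columns
   dropped). The interaction is built in BOLD space; deconvolution to
   neural space is ill-posed and is left as an extension point. Seed-to-voxel interaction-contrast maps feed a second-level
   time×group interaction; suprathreshold clusters (voxel p < 0.01) receive
   empirical cluster-level p-values P(max null size ≥ observed) from the
   same smooth-field Monte-Carlo (add-one corrected), BH at q = 0.05.
   ROI-to-ROI gPPI between the seed and each surviving cluster (cluster
   voxels overlapping the seed are excluded) yields per-subject,
   per-session contrast betas; the dose-connectivity correlation is the
   per-arm Pearson r between mean seed EF and the post-minus-pre contrast
   change. Craving-change associations (default ΔVAS from T3 to T4)
   against delta connectivity, baseline connectivity and seed EF complete
   the level.

## Validation studies

`dosefield.validation` packages the deterministic, seed-driven studies that
`scripts/acceptance.py` reruns:

- **Power**: two-sided two-sample t power from the noncentral t
  (df = 2n−2, ncp = d√(n/2)); n = 30/arm at d = 0.74 gives 0.805,
  cross-checked by 200,000 simulated tests. α = 0.05 two-sided is assumed
  (the source states power and d but not α).
- **Null calibration**: 200 plant-free cohorts (16³ grid, 30+30); the
  frequency of ≥ 1 FDR-significant voxel should sit at the Simes level
  (≈ q). Cluster-extent FWE: calibrate k on 2,000 smooth null fields
  (FWHM 9 mm = 2.25× voxel size, the effective-smoothness ratio of
  kernel-smoothed fMRI) and validate on 500 fresh fields.
- **Recovery**: 100 cohorts with a network plant at ρ = 0.45. The mean
  active-arm dose-connectivity r is compared with the small-sample-biased
  expectation ρ − ρ(1−ρ²)/(2(n−1)) ≈ 0.444; the sham arm should show
  |mean r| ≈ 0. Two attenuation sources are inherent and intentionally
  small by design (node averaging, ~190 usable TRs): regression dilution
  from seed-series noise and gPPI estimation error; together they depress
  the measured mean r by ~0.02 relative to the planted value.
- **Level contrast**: 40 cohorts with the default plant (ρ = 0.60);
  frequencies of any FDR finding at voxel/ROI level vs. network-level
  detection (surviving second-level cluster with active-arm dose
  correlation p < 0.05).

A note on detection power: with ρ = 0.45 and n = 30, the two-sided Pearson
test has power ≈ 0.72 (Fisher-z), so detection rates near 0.72 in the
ρ = 0.45 recovery study are the expected behaviour of a correctly
implemented pipeline, not an implementation deficit; at the default
ρ = 0.60 plant, power is ≈ 0.92 before discovery-path losses.

## What the generator does and does not emulate

Emulated: two-lobe frontal EF topography with realistic between-subject
amplitude/position variability; block-design BOLD with condition-dependent
frontoparietal coupling; AR(1) temporal noise; censorable motion spikes;
arm-specific network-level dose-response; VAS decline with a time effect
only. Not emulated: anatomy (tissue boundaries, gyrification), spatially
correlated physiological noise, scanner drift beyond low-order polynomials,
registration error, EF orientation relative to cortical columns. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated noise model — not that effects of this size are
detectable in any particular real dataset.

## Numerical choices and degenerate inputs

- OLS via pseudo-inverse; condition betas are NaN when censoring leaves the
  condition columns unidentifiable.
- Perfect separation in the interaction t-map (zero residual variance with
  a nonzero effect) returns a capped sentinel (10⁶) rather than ±inf.
- Out-of-field resampling fills 0 (the non-brain periphery is masked
  downstream); labels always resample nearest-neighbour.
- Component ties (equal sizes) are ordered by smallest flat voxel index.
- Correlations on constant vectors or n < 3 are undefined, excluded from
  BH families.
- The extent threshold k = smallest integer with empirical
  P(max ≥ k) ≤ α; empirical cluster p-values use the add-one estimator
  (never exactly 0).
- All randomness flows from a single integer seed through spawned
  `numpy.random` streams (one per subject); cohorts are bitwise
  reproducible.

## Known limitations

- The closed-form LME path covers the balanced complete design; REML
  handles imbalance but is far slower and is not used voxelwise.
- Monte-Carlo extent thresholds assume stationary Gaussian smoothness;
  heavy-tailed or nonstationary fields would need permutation approaches
  (out of scope).
- The gPPI omits deconvolution to neural space; the BOLD-space interaction
  is a documented extension point.
- The EF surrogate is radially symmetric per lobe; real fields follow
  sulcal geometry.
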