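# Methods

This note documents the models, estimators, numerical choices and known
limitations of `trackosc`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Experimental design and behavior

Trials are the factorial crossing of the actor's moving hand *A* ∈ {−1, +1},
the endpoint target location *T* ∈ {−1, +1} (observer's perspective) and
the cued response *R* ∈ {−1, +1, 0}: 12 conditions, 8 requiring a
response.  Because the actor faces the observer, *straight* movements
(hand stays in one hemifield) are those with *A* ≠ *T* and *crossed*
movements those with *A* = *T*; congruency compares *T* with *R*
(congruent iff *T* = *R*).  Each block contains every condition equally
often in randomized order (default 10 repetitions → 120 trials/block,
8 blocks, 12 subjects).

Reaction times follow

    RT = base_s + 18·1[incongruent] + 7·1[straight] + c·bias + ε ,

clipped to 300–610 ms, with `base_s` normal around 438.5 ms
(SD 34.6 ms, so the between-subject SEM of mean RT is ≈10 ms at n = 12;
the grand mean works out to 451 ms), and ε a zero-mean shifted lognormal
(scale 100, shape 0.35; trial SD ≈ 38 ms) giving a right-skewed RT body.
`bias` is an optional per-trial covariate (see *Coupling* below).  Medians
use the arithmetic-midpoint convention; 1-df repeated-measures effects are
computed as the squared paired *t* on per-subject contrast scores, which
for balanced designs equals the classical repeated-measures *F*(1, n−1)
(cross-checked against `pingouin.rm_anova` in the tests).

## Source model and forward model

The head is a homogeneous conducting sphere (radius 90 mm).  Magnetometer
gains use the Sarvas closed form, which makes radial dipoles (and any
dipole at the center — rejected with an error) silent.  The sphere center
sits at MNI (0, −25, 15) mm: a sphere about the MNI origin excludes
posterior cortex (e.g. the cuneus at ±12, −84, 22 lies 88 mm from the
origin), so the mask is re-centered toward the brain centroid; all
mirror symmetry is preserved because the center has x = 0.  The default
sensor array is an 80-sensor mirror-symmetric spherical cap with radial
orientations; parieto-occipital (PO) and motor (M) sensor groups are
geometric caps (posterior-inferior and central-superior lateral), a
deliberate stand-in for data-driven cluster selection.

Four default sources: bilateral 10 Hz alpha at the cuneus coordinates
(±12, −84, 22) and bilateral 20 Hz beta at dorsal premotor cortex
(±18, −18, 64), with tangential orientations mirrored as q → −Mq so the
left/right pair generates exactly x-reflected fields.  Each trial is
`Σ gain · a(t; A,T,R) · sin(2πft + φ)` with φ uniform per trial and
source (induced, non-phase-locked power) plus white sensor noise; gains
are normalized to unit RMS over sensors so `noise_sd` is a direct
sensor-level SNR knob (default 1.0).

Envelopes are piecewise-linear **power** profiles relative to baseline
(amplitude = √power, floored at 0.02):

* alpha: bilateral dip to 0.8 at 275 ms; ipsilateral-to-target rebound to
  0.8 × 1.4 = 1.12 peaking at 700 ms with the contralateral side held at
  0.8 (lateral half-amplitude 0.16), held to 1450 ms, recovered by
  2200 ms; the lateral part is scaled by 0.5 on crossed trials.  Note
  this scaling makes `T·scale = 0.75T − 0.25A`, so the generator's alpha
  lateralization genuinely carries a hand component alongside the target
  component — matching the modeled phenomenon.
* beta: bilateral ramp to 0.5 at 1450 ms, recovery by 2600 ms; lateral
  components suppress the hemisphere contralateral to the actor's hand
  (ramping 427→700 ms, depth 0.08), the target (810→1000 ms, depth 0.12)
  and the cued response (1050→1250 ms, depth 0.15, decaying after
  1450 ms).  On incongruent trials (*R* = −*T*) the post-cue component
  reverses the pre-cue lateralization.

All landmark values are configurable (`EnvelopeParams`); magnitudes
between landmarks are linear interpolation — the landmark times and
depths are the committed quantities, the interpolation shape is not.

## Spectral estimation

Planar gradients: per sensor, a local linear model
`b₀ + b₁u + b₂v + b₃w` is fit over the sensor and its k = 6 nearest
neighbors (u, v tangential, w normal offsets); (b₁, b₂) are the
tangential derivatives.  The normal term makes fields linear in space
differentiate exactly despite shell curvature.  Degenerate (collinear)
neighbor geometries raise an error naming the sensor.  The two derivative
channels are combined by **summing their power spectra** after spectral
estimation, so spatially uniform fields contribute nothing.

TFR: Hanning-tapered 500 ms windows at 20 ms steps, power normalized so a
unit-amplitude on-bin sinusoid yields power 1.  The frequency grid is
2–40 Hz in 2 Hz steps (the 500 ms Rayleigh resolution); band summaries
average bins whose centers lie in [8, 12] (alpha) / [16, 25] (beta).
Output times sit on the absolute 20 ms grid; windows that would cross the
epoch edge are flagged invalid (NaN), never padded.  Relative change is
(P − P̄base)/P̄base with P̄base the mean raw power over −500..0 ms, per
channel × frequency (and per condition), with an explicit error for
non-positive baselines.  Trial averaging happens after per-trial spectral
estimation (induced power), accumulated chunk-wise to bound memory.

## Time-resolved regression

Per subject and time point, the 8 response-required condition values are
regressed on [1, A, T, R] by OLS; on this balanced orthogonal design the
slopes are half the (+1 vs −1) condition-mean differences and the
intercept the grand mean (verified against a normal-equations oracle to
1e-12).  Group inference is a two-level summary-statistics approach: a
two-sided one-sample *t* across subjects per coefficient and time point,
thresholded at α/divisor with the divisor defaulting to the number of
evaluated time points (108 on the −500..+1650 ms, 20 ms grid; per-test
p < 4.63e-4).  A slightly stricter conventional variant of this threshold
is p < 0.0004 (divisor 125); the divisor is a config field, and the
acceptance experiments use 125.  Zero between-subject variance with nonzero mean is
flagged significant with a warning (t = ∞).  Maximal runs of flagged
points are reported as (onset, offset) windows on the 20 ms grid.

Calibration note: subject-level band-power coefficients are ratio
statistics, so the one-sample *t* at n = 12 is mildly heavy-tailed; in
null simulations the family-wise rate for a coefficient track lands near
(slightly above) the nominal Bonferroni level rather than far below it.
The null-calibration test asserts the flagged-timepoint fraction, which
is orders of magnitude below α.

## Power–RT coupling

The 8 condition series are collapsed to the four (T, R)
response-congruency cells, multiplied by R (so a congruent-response bias
always points the same way), normalized by the subject's maximum
**absolute** power over 0–1000 ms across all conditions (the lateralized
series is signed), and pooled as subject × cell points (n = 48 at
12 subjects) against normalized median RT at every time point.  The
"normalized median RT" is z-scored within subject (configurable
alternative: divide-by-mean); z-scoring removes between-subject offsets
exactly as the power normalization removes gain.  Pearson p values are
two-sided; source-level tracks first apply a 100 ms moving mean at 50 ms
steps over 0–1650 ms (edge windows truncated and flagged, not dropped)
and are binned into {n.s., p<0.05, p<0.005, p<0.0001, p<0.00001}
(tightest satisfied threshold; uncorrected by design).

The coupling generator draws a lognormal bias strength per subject
(σ = 0.25) and cell (σ = 0.35); the same bias scales the lateralized beta
envelope and enters RT via the coupling term (40 ms per unit bias),
alongside cell-level RT variability (SD 20 ms) and power measurement
noise (SD 0.26 relative units) that are *not* bias-driven.  These two
noise scales were calibrated once, by large-sample simulation, so the
population pre-cue (900–1000 ms) pooled correlation is 0.6; at the study
scale (12 subjects) the estimate spreads roughly ±0.1 around it.

## DICS source analysis

The sensor CSD is the mean over trials and band frequencies of
Hanning-tapered Fourier cross-products over a window (active 600–1100 ms,
baseline −500..0 ms); windows shorter than one cycle of the band's lower
edge are rejected.  Filters are `W = (LᵀC⁻¹L)⁻¹LᵀC⁻¹` with
`C = Re(CSD) + λ·mean(diag)·I`, λ defaulting to 5% (exposed in config).
Because sphere lead fields are rank-2 (silent radial direction), the 3×3
constrained matrix is inverted by an eigenvalue-thresholded pseudoinverse
(relative threshold 1e-7): for full-rank lead fields this is the exact
inverse with W·L = I₃; for sphere fields the unit-gain constraint holds
exactly on the non-silent subspace, where the fixed orientation (dominant
eigenvector of the real 3×3 source CSD) always lies.  Power contrasts use
a common filter from the pooled active+baseline CSD and report
(P_act − P_base)/P_base per voxel.

Group analysis: per subject, condition maps are aligned by each
condition's label side (target side for the stimulus-type contrast,
response side for congruency) as `side·(map(mirror(v)) − map(v))/2` —
antisymmetric across hemispheres, positive where power is suppressed
contralateral to the label — then contrasted (straight − crossed or
congruent − incongruent) and tested across subjects.  FDR uses
Benjamini–Hochberg over in-mask voxels (α = 0.05, statsmodels); bootstrap
CIs resample subjects with replacement (B = 500, percentile 2.5/97.5,
descriptive only — FDR decides the flags).

ROIs: connected components of flagged voxels under 6-neighborhood
(faces-only) connectivity; a component yields one ROI at its global |t|
maximum if it holds the maximum plus ≥4 other significant voxels and its
mean |t| ≥ 2.6 (the |mean t| variant is selectable and differs only for
mixed-sign components).  Each ROI is paired with its mirrored coordinate
even if sub-threshold there.  The grid places x at half-spacing offsets
so every voxel has an exact mirror partner and none sits on the midline.
Lateralized ROI series use fixed-orientation filters from a whole-epoch
band CSD, sliding-window band power of the two virtual channels, relative
change to baseline, and left − right subtraction.

## Pipeline and reproducibility

`run_pipeline` ties behavior to physiology: each subject's per-cell bias
strength scales the simulated lateralized envelopes *and* their RTs, so
the estimated sensor-level coupling has a known ground truth.  All
randomness derives from the config seed through named `SeedSequence`
children; identical (config, seed) pairs produce byte-identical TSVs
(fixed float formatting).  Stage failures abort with the stage name;
MANIFEST.json records per-stage status.  Epochs are stored as HDF5 + JSON
sidecar (none/first/all subjects, default first).

## Problem sizes

Full-scale defaults mirror the modeled study (12 subjects, 8 blocks × 10
repetitions, 80 sensors, 250 Hz, 6 mm grid).  The test suite and the
reproduction script run the same estimators at reduced scale chosen for
desk-speed turnaround: recovery experiments use 12 subjects ×
6 trials/condition, 24 sensors, 100 Hz (Nyquist-safe for ≤25 Hz);
localization uses a 6 mm grid restricted to an interior 40 mm radius;
ROI-oracle maps use a 10 mm grid.  Detection margins at these scales are
large (the tests measure them), but absolute power SNRs are not those of
a real 248-channel recording.

## What the generator does and does not emulate

Emulated: balanced factorial structure; induced (non-phase-locked)
band-limited power with condition-dependent lateralized envelopes;
bilateral mirror symmetry; behavioral effect sizes and RT support; a
latent bias coupling power to RT.  Not emulated: realistic noise
covariance and environmental interference, head movement, channel
dropout/repair, individual anatomy (a canonical sphere replaces MRI head
models), eye/cardiac artifacts, and any stimulus-level visual content.
Passing tests therefore validate the *estimators and inference chain*
under the stated statistical structure — not performance on real
recordings.

## Known limitations

* The sphere forward model cannot express radial sources; localization
  accuracy statements apply to tangentially oriented dipoles.
* The relative-change normalization couples values inside the baseline
  window, deflating their between-subject variance; significance inside
  −500..0 ms should be interpreted with that in mind.
* The group source contrast uses difference-of-relative-changes within
  subject (a ratio alternative exists in the literature and is not
  implemented).
* Bootstrap CIs are descriptive; no cluster-based permutation correction
  is provided for the sensor regression (Bonferroni only, as specified).
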