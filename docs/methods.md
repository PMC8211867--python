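# Methods

This note documents the models, procedures, parameter choices and known
limitations of the `obci` package: a simulation and analysis pipeline for a
two-photon calcium-imaging optical brain-computer interface (oBCI) built
around a delayed center-out reach task.

## The task and session model

A session consists of balanced, randomly interleaved trials to `K` radial
targets (default `K = 4`) placed 10 cm from a central hold point. Each trial
runs: center hold (400 ms) -> target onset -> randomized delay (uniform on
100-700 ms) -> go cue -> reach -> target hold (200 ms) -> return reach ->
inter-trial interval. Reaches are minimum-jerk point-to-point movements of
10 cm amplitude; the outward reach lasts 300 ms (closed-form peak speed
`1.875 * D / T` = 62.5 cm/s), the return 500 ms. Hand position is sampled at
60 Hz.

Movement onset is defined purely behaviorally: the first time in-plane hand
speed exceeds 5% of the trial's peak speed (linearly interpolated between
hand samples). Reaction times are accepted only within a 180-620 ms window;
the generator draws behavioral RTs with a 20 ms guard band inside that window
so every recomputed onset lands inside it. The default RT distribution is
uniform over the accepted window; a truncated-normal mode
(`rt_distribution="truncnorm"`, mean 300 ms, SD 60 ms) concentrates RTs the
way trained primates do, which matters for go-cue-locked decoding (below).

Two timeline constants are deliberately conservative relative to the
indicator kinetics: the inter-trial interval defaults to 2000 ms and the
return reach to 500 ms. With a 0.7 s decay constant, faster pacing leaves
return-reach calcium decaying through the next trial's pre-event windows,
which turns the two-sided pre/post rank-sum tests into detectors of that
carryover ramp on every ROI. With the defaults, residual carryover at the
target-cue window is below the trace noise floor.

## The fluorescence model

Each ground-truth ROI is a non-negative spatial footprint (elongated
Gaussian-profile tube for dendrites, soft disk for somata) with:

- a preferred direction (PD) drawn uniformly on [0, 360);
- a velocity gain `g` (dF/F per cm/s, default uniform on 0.015-0.03);
- a condition-independent gain (peri-movement raised-cosine bump, default
  amplitude ~0.2 dF/F), modeling the direction-free movement signal;
- a baseline brightness `F0` (80-120 a.u. over background 20 a.u.).

The instantaneous drive is a rectified cosine against lagged hand velocity,
`g * max(0, v(t - lag) . u_PD)` with `lag = 50 ms` (fluorescence follows
kinematics). The drive passes through a first-order low-pass
`c[n] = exp(-dt/tau) c[n-1] + (dt/tau) drive[n]` with `tau = 0.7 s`
(GCaMP6f-like), whose impulse response is exactly `exp(-t/tau)`. Pixel
intensity is `sum_r F0_r (1 + c_r(t)) w_r + background`, followed by optional
rigid integer-pixel jitter (<= 2 px, recorded as ground truth) and noise
(Gaussian with variance proportional to the mean — a shot-noise
approximation — or true Poisson).

The rectified-cosine drive was chosen because, for a balanced center-out
design with orthogonal target axes, the OLS velocity-regression estimator of
PD is unbiased under it: `E[max(0, v.u) v]` is proportional to `u` when the
velocity distribution is symmetric under the task's dihedral group. The
calcium low-pass attenuates the coefficients but, by the same symmetry, does
not rotate them; measured median PD recovery error at default conditions is
well under 1 degree noise-free and a few degrees at trace noise 0.02.

Control-mode FOVs ("autofluorescent puncta") reuse the identical task, noise
and jitter models with bright footprints whose gains are all zero.

The default field of view is 128x128 px at 30.3 Hz. That is a desk-scale
choice — the emulated instrument ran 512x512 at the same rate and is
available through the config — and it has one important consequence: one
pixel of motion jitter is, relative to feature size, several times the
motion of the emulated rig, so un-registered (online-path) decoding is
noticeably more jitter-limited at desk scale than the offline, registered
path. Tests that probe signal-limited behavior therefore disable jitter
explicitly and say so.

## Preprocessing

- **Registration**: rigid translation only, per frame, by FFT
  cross-correlation against the mean frame; integer shifts are undone by
  circular shift (exactly invertible on synthetic data), subpixel refinement
  by bilinear interpolation is opt-in. Non-rigid block-wise alignment is out
  of scope: the synthetic motion model is rigid.
- **dF/F**: iterative time-varying baseline. `F0(t)` is a rolling 10th
  percentile over a 30 s window, smoothed, re-estimated on the
  transient-clipped trace `min(F, F0)` until the relative change falls below
  1e-3 (at most 3 passes). The window/percentile defaults are conservative
  for sparse transients at 30.3 Hz. `dF/F = (F - F0)/F0` is exactly invariant
  to rescaling the raw trace.
- **Z-scoring**: pooled pre-trial baseline (default -300..0 ms before target
  onset, when the hand is still), sample (n-1) SD. Zero-SD ROIs are flagged
  and excluded rather than propagated as infinities.
- **Blur**: normalized Gaussian, reflect boundary, kernel truncated at
  4 sigma; sigma 0 is the identity.

## ROI statistics

- **Dendrite classification**: aspect ratio = sqrt of the eigenvalue ratio
  of the weighted pixel-coordinate covariance, regularized by the variance of
  a unit pixel (1/12 px^2 per axis) so one-pixel-wide masks stay finite;
  dendritic iff ratio > 2. On generator footprints the labels agree with the
  generating shape class for >= 95% of ROIs.
- **Duplicates**: Pearson correlation of dF/F traces over all frames;
  pairs at or above the threshold (0.8 strict, 0.6 lenient) are flagged but
  retained. One-sided: anti-correlated pairs are not duplicates.
- **Response-continuum check**: DBSCAN over trial-averaged,
  movement-aligned, direction-concatenated response vectors. `eps` defaults
  to the 95th percentile of 4-NN distances — covering nearly every point's
  local neighborhood keeps a uniform-density continuum in one cluster while
  leaving well-separated groups apart; `min_samples = 4`.

## Per-ROI tuning tests

All tests use p < 0.01. Rank-sum and Kruskal-Wallis use the asymptotic
normal / chi-square approximation with tie correction.

- **Event responsiveness**: per-trial mean fluorescence in pre vs post
  windows (-150..0 vs 0..150 ms for target cue and go cue; -450..-100 vs
  0..350 ms for movement onset, the pre window interpreted from an ambiguous
  printed range), compared across trials with a two-sided rank-sum test.
- **Direction ANOVA**: one-way ANOVA across targets of per-trial means in
  0..350 ms after movement onset.
- **Tuning onset**: Kruskal-Wallis across directions on a 10 ms grid of
  movement-aligned interpolated samples; onset = first of five consecutive
  significant windows.
- **Velocity regression**: OLS of dF/F on `[vx(t-50ms), vy(t-50ms), 1]`;
  PD = atan2(beta_y, beta_x) in [0, 360).
- **Stability**: PD fit separately on the first and last 25% of trials; the
  absolute circular PD difference is ranked against 1000 trial-level
  reshufflings of the early/late labels. One structural caveat, verified by
  simulation: an exactly amplitude-matched 180-degree flip is invisible to
  this test, because the two opposed tunings cancel in every shuffled
  mixture and the null itself concentrates near 180 degrees. Any amplitude
  asymmetry restores full power, so the power simulations use a 180-degree
  flip with a gain change (0.03 -> 0.06).
- **Heterogeneity**: per-pixel velocity-regression coefficients clustered by
  k-means over k = 2..5, scored by the Calinski-Harabasz (CH) criterion.
  CH is undefined at k = 1, so k = 1 is selected when the best score fails an
  effect-size floor of `1.0 * n_pixels` (an isotropic single cluster split in
  two scores about `0.5 * n`). Heterogeneous iff optimal k > 1 AND at least
  two clusters each hold >= 30% of the pixels AND the largest circular
  centroid-PD difference is >= 60 degrees. Because this is a composite
  deterministic rule rather than a p-value test, its null positive rate is
  conservative (below 1%), not centered on 1%; the calibration suite asserts
  it does not exceed the nominal band. At very low coefficient noise and few
  pixels, CH can prefer k = 5 micro-splits whose clusters all fail the 30%
  rule — a known small-sample CH pathology; with realistic ROI sizes
  (>= 20 px) measured power at a 90-degree two-population split is 100%.

## Population axes

Over direction-tuned ROIs only, in a -300..+400 ms movement-aligned window
of z-scored responses:

- **CIS**: first principal axis (over ROIs) of the time-centered
  across-direction mean trajectory, sign-oriented so the peak deflection is
  positive. This replaces regularized demixed PCA with cross-validated
  lambda: both extract a single dimension with temporal but minimal
  cross-condition variance, and the substitute is exact when directional
  components cancel in the cross-condition mean (they do, by design, in the
  generator).
- **TDR**: the x/y readout axes are the rows of the Moore-Penrose
  pseudoinverse of the (ROI x 2) velocity-coefficient matrix, unit-normalized
  and sign-oriented to correlate positively with their coefficient column.
- The triple is successively orthonormalized (Gram-Schmidt, CIS first; the
  CIS direction is unchanged). Single-trial and trial-averaged trajectories
  are projected onto the orthonormal triple.
- **Variance spectrum**: eigenvalues of the pixel covariance of the
  (trials x time) x pixels matrix, computed through the smaller-side Gram
  matrix.

## Decoding

**Online path (raw pixels).** Templates `Y_k` are per-target running
averages of blurred (sigma 3 px) frames from the integration window
`[go + T_skip, go + T_skip + T_int)`; a frame belongs to the window iff its
start time falls inside it (only full frames). A test trial's window-average
image `X` is classified by `argmin_k sum_ij (X_ij - Y_ijk)^2`, ties broken
toward the lowest target index. Defaults are the midpoints of the method's
operating ranges: `T_skip = 300 ms` (range 200-400), `T_int = 132 ms` = four
frame periods (range 70-200), 8-15 training trials per target (default 10).
The emulation enforces causality — no frame after the integration window
can influence a decision — but makes no wall-clock latency claims.

Because the window is go-cue-locked while the signal is movement-locked, the
achievable accuracy depends strongly on the RT distribution: under the
default uniform RTs a 200 ms window simply misses the movement on long-RT
trials regardless of SNR (noise-free ceiling ~50% at 4 targets), while with
truncated-normal RTs, `T_skip = 400 ms`, `T_int = 200 ms`, no jitter and
doubled gains the decoder exceeds 90%. Chance-level behavior (shuffled
labels, control FOVs) is insensitive to all of this.

**Offline path (dF/F pixels).** Per-pixel dF/F with a static 10th-percentile
baseline (the per-pixel standardization inside the classifier makes the
baseline shape immaterial; the iterative estimate is reserved for ROI
traces), causal 200 ms window averages at each timepoint, per-pixel
standardization fit on training folds only, linear one-vs-rest SVM (C = 1),
stratified 5-fold cross-validation with a fixed fold seed. Only successful
trials enter. The decode-score timecourse uses a causal rolling 6-frame
blurred average scored against each template; the first five frames are
undefined and emitted as NaN.

**Pixel masking**: for each square size, 15 squares sampled uniformly from
the FOV; pixels outside the square are dropped and the offline decoder is
rerun at a fixed timepoint. A square covering the whole FOV reproduces the
unmasked accuracy exactly; zero retained pixels degrades the classifier to a
majority-class guess (chance on a balanced design).

**Dendritic-pixel analysis**: per-pixel peak-to-peak range across the
per-target templates and per-pixel dF/F SD over all timepoints, compared
between pixels inside aspect-ratio-classified dendritic ROIs and all other
pixels (two-sided rank-sum); plus offline decoding restricted to dendritic
pixels, all pixels, and a count-matched random draw of non-dendritic pixels.

## Randomness and reproducibility

Every random draw descends from a single integer seed. Pipeline stages draw
from named substreams (`SeedSequence(seed, bytes(stage_name))`), so adding,
removing or re-running one stage never perturbs another stage's stream.
Identical config + seed reproduces bit-identical trials, ROIs, movies and
artifact hashes.

## Problem sizes used by the shipped experiments

The chance-calibration experiments (and `scripts/acceptance.py`) run 20
sessions per target count with 500 held-out test trials each at a 32x32 FOV
— the chance rate of a label-shuffled decoder does not depend on FOV size,
and the small FOV keeps the experiment at a few seconds per session.
The statistical-calibration suite uses 1000-replicate nulls and
200-replicate power runs on trace-level simulations (64-trial sessions;
160-trial sessions for the stability test, whose quartiles must stay
direction-balanced). The end-to-end smoke run uses the full default desk
scale: 128x128 px, 4 targets, 160 trials; inside it, the offline SVM
features, the decode-score timecourse and the pixel variance spectrum are
computed on a 4x spatially binned movie (the pixel Gram matrix at full FOV
would dominate the run's memory and time).

## Known limitations

- No optics/PSF model, z-motion, photobleaching, neuropil-subtraction model
  or red structural channel; jitter is rigid and (by default) integer-pixel.
- No ROI detection: footprints come from ground truth or the user.
- The online decoder emulation reproduces the algorithm and its causality,
  not the real-time engineering (frame buffers, sub-frame latency).
- The CIS stand-in is exact only when directional components cancel in the
  cross-condition mean; with strongly asymmetric tuning distributions it
  absorbs a directional component that demixed PCA would reject.
- Uniform RTs plus a go-locked window bound online accuracy away from 100%
  structurally (see above); this is a property of the task model, not of the
  decoder.
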