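# Methods

This note documents the models and procedures implemented in `escapekit`,
the parameter defaults and why they were chosen, the design decisions made
where the published rule sets leave room, and what the synthetic-data
generators do and do not emulate.

## Coordinate convention and kinematics

All positions are in centimeters in an arena frame with the origin at the
safe short wall and x increasing along the length axis toward the threat
wall (`ArenaSpec.threat_end` selects which wall; internally everything is
computed in the x-max convention and mirrored). The threat zone occupies
`threat_zone_depth_cm` (default 15 cm, the reach of a tethered rat) at the
threat wall; distance-from-threat is measured along the length axis from the
nose to the zone boundary and clipped at zero inside it.

Kinematics are computed from pose keypoints (nose, two ears, tailbase) after
a centered 5-frame moving average on coordinates: raw 30 Hz finite
differences of tracked pose are noise-dominated, and 5 frames (~170 ms) is
short relative to every behavioral time scale used here. The smoothing
window is a parameter of `compute_kinematics`. Speed is the finite
difference of the smoothed tailbase (the most stable keypoint); the freeze
rule additionally uses nose speed, exactly as the rule is written ("nose and
tailbase"). Head direction is the angle of the line from the inter-ear
midpoint through the nose, reported as a cosine in [−1, 1] with +1 facing
away from the threat. Missing keypoints propagate as NaN gaps that no
classifier clause can satisfy; gaps dilate by the smoothing window.

## Behavior classification

Each of the five behaviors is a conjunction of explicit clauses on the
kinematic series (see README for the table). Implementation details that the
rules leave open:

- **Epochs** are half-open frame intervals `[onset, offset)`. A candidate
  epoch is a maximal run of frames satisfying the *rate* clause (e.g.
  away-speed > 2 cm/s); runs of the same label separated by fewer than
  2 frames are merged before the remaining clauses are checked
  (threshold chatter at frame resolution; `merge_gap_frames` is
  configurable). The *magnitude* clauses (initiation distance, traversal,
  minimum duration) are then evaluated per epoch.
- **Escape initiation distance.** The published definition is internally
  ambiguous about the inequality direction; escapes are required to begin
  *within* 30 cm of the threat ("begin near the threat"), and
  `BehaviorThresholds.escape_init_within=False` flips the direction for
  sensitivity analyses.
- **Traversal** is the net change in distance-from-threat between epoch
  onset and offset (escapes and approaches) or the net displacement across
  the width axis (walks) — a displacement rule, not path length, so jitter
  cannot accumulate into a passing traversal.
- **Baseline body length** for the stretch rule is the per-session median
  nose–tailbase distance over non-elongated frames, found in two passes
  (provisional median over all frames → exclude frames above 1.2× it →
  final median). A single-pass median would be dragged upward by sessions
  rich in stretch-attend postures.
- **Freeze duration** is `n_frames / frame_rate` of the below-threshold run,
  compared against the 0.33 s minimum with a 1e-9 tolerance (10 frames at
  30 Hz is 0.3333… s and must pass).
- Labels are *not* mutually exclusive: overlapping epochs of different
  labels are permitted, and classification is a pure function of
  (kinematics, thresholds).

## Photometry

The interleaved 20 Hz recording is de-interleaved into 10 Hz channel
streams; the 405 nm reference is linearly interpolated onto the 470 nm
timestamps. Correction fits `signal ≈ a·reference + b` by ordinary least
squares over the whole session and reports
`df/F = (signal − fit)/fit`, z-scored per session. Choices:

- The OLS fit is global (no windowing); windowed or robust variants can be
  layered on but the global affine fit is the simplest faithful model of
  shared bleaching and motion artifacts.
- The df/F denominator is the *fitted reference* (a proxy for baseline
  fluorescence at each sample). Consequence: adding an affine transform of
  the reference to the signal leaves the corrected output unchanged only to
  tolerance — the residual numerator is exactly invariant, the denominator
  is not. Empirically the corrected signals correlate at r > 0.98 under a
  40% perturbation; a session-constant denominator would make the invariance
  exact at the cost of ignoring slow baseline drift.
- Behavior-triggered averages use only instances separated by ≥ 5 s from
  every other classified epoch, require ≥ 3 qualifying instances per
  session (otherwise the session is flagged excluded), and report the mean
  over [−2, 0] s as the pre-onset scalar.
- Alignment between the 10 Hz corrected signal and 30 Hz behavior frames is
  by nearest timestamp.

## Ensemble statistics

- **Variance filter:** cells are retained when their variance is ≥ 25% of
  the maximum variance among non-outlier cells. "Non-outlier" is defined
  here as variance ≤ Q75 + 1.5·IQR of cell variances (configurable); without
  some outlier rule one exploding ROI would silently empty the population.
- **Behavior-tuned cells:** identity-link least-squares GLM of the z-scored
  trace on a single 0/1 behavior indicator (one behavior per fit — the
  coefficient's *rank*, not scale, drives the test). The null randomizes
  onset times 100 times, preserving epoch durations and session bounds,
  **without overlap** (real epoch trains never overlap; overlapping null
  epochs shrink the indicator on-fraction, inflate null coefficient
  variance, and bias the test conservative — measured ~3.9% vs the nominal
  ~5% before the constraint). A cell is flagged when its observed
  coefficient exceeds at least 95 of the 100 null values
  (`np.percentile(..., method="higher")`); under exchangeability the flag
  probability is 5/101 ≈ 4.95%. One-sided: activation only.
- **Escape-speed cells:** Pearson r between trace and speed restricted to
  escape samples; the null pools 100 circular shifts per cell (uniform in
  [30 s, T − 30 s]) across all classifiable cells, and a cell is flagged
  when |r| exceeds the pooled 95th percentile (two-sided via the absolute
  value; per-cell null for behavior tuning vs pooled null here is
  deliberate — they mirror the respective published procedures).
  Constant-trace cells are marked non-classifiable and excluded from
  pooling rather than raising.

## Decoding

- **Discrete (escape/approach/stretch/freeze):** positives are all
  timepoints within 2 s after each onset; negatives are an equal count of
  randomly selected timepoints outside the positive windows *and* a 2 s
  guard band around them (unguarded negatives adjacent to onsets are
  trivially ambiguous; the guard width is configurable). Every timepoint is
  an individual sample. Five temporally contiguous folds; training samples
  within 10 s of the validation block are dropped, and classes are
  re-balanced inside every training and validation set, keeping chance at
  exactly 50%. A small ridge penalty (logistic C = 10) stabilizes separable
  fits. Sessions with < 5 usable instances return an exclusion flag, not an
  exception. Future-escape decoding uses positive windows
  [onset − lag − 2 s, onset − lag] with negatives matched per lag; epochs
  whose window precedes the session start are dropped with a notice.
- **Continuous (position / velocity_away / velocity_toward):** targets are
  the tailbase coordinate along the threat axis, or the speed along that
  axis restricted to samples moving in the named direction. The session is
  cut into alternating 60 s blocks with 10 s gaps (even blocks train, odd
  blocks test). Features are z-scored with training statistics; PCA is
  fitted on training blocks only (leakage-safe, stricter than fitting on
  the whole session) and components are kept to ≥ 80% cumulative variance;
  a ridge-regularized linear model (α = 1e−3) predicts the target, scored
  as test MSE. The chance distribution re-runs the *entire* pipeline —
  z-scoring, PCA refit, fit, test — on 100 circular rotations of the
  neural matrix by ≥ 30 s. Temporal hygiene (no test sample within the gap
  of any training sample) is asserted structurally on every split.

## Mutual information

Equal-width binning over each signal's observed min–max (20 bins;
equal-frequency available as `strategy="frequency"`), joint distribution
from the 2-D histogram, `0·log 0 = 0`. No bias correction is applied; the
analytic first-order bias under independence,
(binsₓ−1)(bins_y−1)/(2·n·ln 2) bits, is exposed as
`analytic_bias_bits` and used by the tests. The region-pair wrapper masks to
samples with speed > 1 cm/s and optionally removes escape-epoch samples.
Corrected, z-scored df/F is the intended input for dual-photometry use.

## PLS pathway model

The first PLS component of two column-centered trial × voxel blocks is
computed exactly as the leading singular-vector pair of `Xcᵀ Yc` (the
NIPALS first-component solution; verified against scikit-learn's `PLSSVD`
in the tests). Only component 1 is used. Signs are fixed so the
largest-magnitude predictor weight is positive.

- **Pathway strength** is estimated with leave-one-subject-out
  cross-validation: weights and column means from the remaining subjects,
  held-out trials centered with training means, per-subject Pearson
  correlation of the projected scores.
- **Partial correlation** (pathway specificity vs a confound region) is
  computed on the *held-out* scores, not in-sample scores: a
  covariance-maximizing fit aligns the two blocks' noise in-sample, which
  leaves a large spurious partial correlation even for a pure confound.
  Fold weights are sign-aligned to the full-data solution so that the
  pathway and confound score streams keep one sign convention across folds.
  The confound latent is the confound-region score of a confound → outcome
  PLS fitted with the same machinery; both pathway scores are residualized
  on it. Controlling for a *noisily estimated* confound is intrinsically
  incomplete — shared estimation noise enters both residuals — so the
  demonstration requires the confound region to represent its own latent
  several-fold more strongly than it drives the remote regions (see the
  generator's `confound_block_gain`).
- **Voxel localization** bootstraps subjects with replacement, sign-aligns
  each replicate to the full-data weights, and tests per-voxel means by
  normal approximation (z = mean/sd) with Benjamini–Hochberg FDR.
- **Condition contrast:** pathway expression per trial is the product of
  the standardized X and Y scores (co-activation of the paired latents; a
  mean of the scores would be zero by construction regardless of gain).
  Per-subject condition means are compared by Wilcoxon signed-rank; the
  intensity trend is the per-subject least-squares slope of expression over
  the four intensity levels, tested across subjects. Inference is flagged
  unavailable below two subjects.
- Centering is per training fold; single-trial estimates enter raw
  (no variance normalization). Functional alignment across subjects is
  assumed done upstream; synthetic blocks are generated pre-aligned.

## Synthetic-data generators

The generators exist to give every analysis a planted ground truth. All
randomness comes from one `numpy.random.default_rng(seed)` per call — same
seed, same bytes.

- **Trajectories.** A rigid three-point body (nose 7 cm ahead of the
  tailbase, ears at 72% of the body axis, ±1.2 cm) moves through planted
  episodes: straight runs for escapes/approaches/walks (constant speed,
  parameterized start distance and traversal), full stillness for freezes,
  tailbase micro-motion at 0.5 cm/s with nose elongation to 1.35× for
  stretch postures. Between episodes the animal mills on slow circular
  orbits (0.6 cm/s, bounded within 2 r of the episode start point) and
  transits between start points in straight lines at ≤ 1.7 cm/s. The orbit
  design is deliberate: a free random walk reverses direction, and reversals
  inside the smoothing window produce near-zero displacement speeds that
  plant spurious freeze bouts; the orbit keeps smoothed speed strictly
  inside (0.25, 2) cm/s so the inter-episode baseline can never satisfy any
  classifier clause. Episodes flagged with `violate=` break exactly one
  clause of their rule (e.g. escape initiated at 35 cm, traversal 6 cm,
  speed 1.5 cm/s) while satisfying the rest. Freeze bout durations default
  to N(2.0 s, 0.5²) clipped to [0.8, 4] s — a realistic bout-length scale
  for rodent freezing. Default gaps of 22 s (`make_schedule`) cover the
  longest sub-threshold transit between default start points in the 70 cm
  arena.
- **Photometry.** Both channels share a multiplicative artifact
  (1 + 0.3·exp(−t/600 s) bleaching plus smooth motion bumps); the signal
  channel adds planted activity — behavior-onset transients convolved with
  the calcium kernel, or speed/position-proportional drive — scaled to 5%
  df/F per unit gain. Defaults (`TuningSpec.photometry()`: gain 2, noise
  0.5% of baseline per sample) produce z-scored transient peaks around 5,
  typical of a healthy prep. Channels are interleaved at 20 Hz
  (405/470 alternating).
- **Ensembles.** Each trace is a Poisson transient train (0.1 Hz baseline,
  exponential amplitudes) convolved with a single-exponential calcium
  kernel (τ = 1.5 s, the slow-indicator regime) plus the tuned drive and
  white noise. Convolution is *circular*: it makes traces circularly
  stationary, so circular-shift nulls are exactly exchangeable with the
  observed statistic (for sessions much longer than the kernel the wrap is
  negligible). Tuning targets: behavior labels (onset-locked transients),
  speed, directional velocity (away/toward), position (threat proximity),
  or none.
- **Region pairs** mix a shared smooth latent into two signals with
  variance-preserving weights (√c, √(1−c)), so the inter-signal correlation
  equals the coupling parameter exactly: 0 = independent, 1 = identical.
- **Voxel blocks.** One latent per trial, shared between predictor and
  outcome blocks through fixed loading maps, amplitude modulated by
  condition and a four-level intensity covariate; an optional confound
  latent drives both blocks (`confound_gain`) and its own region
  (`confound_block_gain`, default 4 — see the partial-correlation note
  above).

What the generators do **not** emulate: pose-estimation error structure
(keypoint swaps, occlusions — pose noise is optional white jitter),
naturally variable within-episode speed profiles, bout-to-bout behavioral
variability beyond the scheduled parameters, hemodynamics, spatial
autocorrelation of voxel noise, or inter-subject anatomical variability.
Passing round-trip and calibration tests therefore demonstrates that the
analysis code implements its rules and statistics correctly — not that the
rules themselves are robust to real pose-estimation noise or real neural
variability.

## Validation protocols and problem sizes

`escapekit.validation` fixes the problem sizes used by the test suite and
the reproduction script: 20 decoder seeds on a ~8 min session with 12
escapes and 6 approaches at speeds 3–8 cm/s; 10 round-trip sessions plus one
session per violation type; 500 white-noise cells × 20 seeds for classifier
calibration (white noise makes the observed statistic exactly exchangeable
with its null; kernel-autocorrelated traces are mildly conservative);
100 circular permutations for the continuous-decoding chance; n = 10⁴–10⁵
samples for the information-theoretic checks; 8–12 subjects × 30–40 trials
× 15–50 voxels with 400 bootstrap replicates for the pathway checks. These
sizes put every Monte-Carlo check's sampling error well inside its
assertion band while keeping the whole validation run around a minute.

## Known limitations

- The behavior classifiers implement the written rule set exactly; there is
  no learned component and no manual-review stage, so borderline epochs are
  decided purely by thresholds.
- The photometry correction assumes artifacts enter both channels affinely;
  wavelength-dependent artifact scaling beyond an affine map leaks through.
- Binned MI is biased upward at small masked-sample counts (the analytic
  independence bias is documented, not subtracted) and is not corrected for
  autocorrelation of the inputs.
- The onset-randomization null assumes epochs are exchangeable in time; it
  does not model slow nonstationarity in the traces (the circular-shift
  null for speed cells does).
- Partial-correlation control of a confound is attenuated by estimation
  noise in the confound latent (see above); a weakly measured confound
  cannot be fully controlled for by any residualization.
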