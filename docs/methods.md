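# Methods

This note documents the models, parameter choices, and numerical
conventions behind graspkin, and what the synthetic-data generator
does and does not emulate.

## Units and conventions

Positions are millimetres on RAS axes, angles radians, time seconds.
Kinematics are sampled at 60 Hz; functional volumes at TR = 0.8 s
(48 frames per TR). Phase intervals are half-open `[start, end)` on
the speed-series frame grid, and partition
`[reaction_frame, trial_end_frame)` exactly.

## Synthetic sessions

`SessionSpec` defaults encode the reference block design: 7
participants x 4 runs x 15 blocks (5 per condition:
MoveVisible / MoveInvisible / NoMovement) x 3 trials = 1260 trials, 60
per condition per participant. Each block opens with a 0.6 s auditory
instruction and a 0.4 s gap; targets stay lit 2.5 s.

Inter-trial intervals follow an exponential law truncated to a
[min, max] window; the exponential scale is solved numerically so the
*truncated* mean matches the configured mean, and samples are drawn by
rejection. Published timing for this paradigm exists in two forms that
differ by exactly the 2.5 s target duration (5–13 s mean 7 s
onset-to-onset vs 2.5–10.5 s mean 4.5 s offset-to-onset); the
generator parameterizes offset-to-onset by default and exposes
`iti_onset_to_onset=True` as the equivalent preset, leaving the choice
to the user rather than declaring one canonical.

Grip types are counterbalanced within each participant-by-condition
cell. Error-prone trials are injected at the rates observed in a
1260-trial session set (`ErrorRates`): tracking losses appear as long
dropout gaps and no-movement violations as actual movements — both
detected computationally downstream — whereas feedback bugs and
unexpected movements are sidecar annotations, emulating flags that
come from visual inspection rather than from the signal itself.

## Trial kinematics

A trial is still until the reaction latency, transports the wrist to
the target along a laterally bowed path (sine arc of configurable
height), holds still during the grip phase while the fingers close,
transports back along a separately bowed path, and rests. Six
segments are emitted (elbow, forearm, wrist, hand, index tip, thumb
tip) with positions and orientation angles.

**Transport speed profile.** The tangential speed follows a
minimum-jerk bell rescaled into `[v_peak/2, v_peak]`. A raised bell
keeps onsets and offsets crisp at the 60 Hz frame grid: with the pure
bell (which leaves and re-enters zero quadratically) any
threshold-based or cluster-based segmentation necessarily places
boundaries several frames inside the movement, making generated
boundaries unrecoverable by construction. With the raised bell the
stored boundary frames are exactly the frames at which the noiseless
speed crosses half the movement's peak, so they serve as a
construction oracle for the segmentation stage. Positions are obtained
by arc-length parameterization of the path, so the wrist speed equals
the designed profile and the path length equals the integral of the
speed exactly.

**Phase-duration and aperture distributions.** Trial parameters are
drawn from normal distributions matching reported group kinematics —
reaction 624 ± 85 ms, reach 789 ± 166 ms, grip 1132 ms (trial-level sd
tightened to 300 ms, since the reported 625 ms is an across-subject
spread), back 1040 ± 232 ms — with clipping to physiologic ranges.
Aperture minima follow the grip-type contrast (power 45 ± 4 mm grip /
122 mm hand; precision 72 ± 5 mm grip / 162 mm hand), clipped so the
precision-above-power ordering holds for every single trial. The back
movement's duration is 1.05–1.5 times the reach and its path is
lengthened (via the arc height) so that its peak speed stays at
0.75–0.92 of the reach's; slower *and* shorter returns would otherwise
sit too close to the still cluster for any velocity-based segmentation,
which is also why returns meander more than outward reaches here.
The finger-aperture minimum is anchored to a sampled frame, so the
generated minimum is attained exactly in noiseless data.

**Noise and dropout.** Positional noise is Gaussian with the stated
marginal sd but temporally correlated (AR(1), coefficient 0.9 over
frames): optical reconstruction jitter is band-limited, and white
noise at 60 Hz would imply frame-to-frame velocity noise far beyond
what tracking systems show. Dropout frames are explicit NaNs, never
silent zeros. Default pipeline conditions: 1 mm noise (static-marker
reconstruction sd in this setting is bounded by 2 mm) and 0.002
dropout probability per frame.

## Segmentation

`compute_speed` → five-frame moving-average `smooth` (shrinking
windows at the edges — no data invented beyond the trial) → 2-cluster
k-means (scikit-learn, 10 restarts, fixed seed; the higher-centroid
cluster is "moving") → `parse_phases`. Runs shorter than 100 ms are
merged into their neighbours before parsing (shortest first); the
accepted pattern is still-moving-still-moving(-still), all deviations
flagged with a reason (`no_movement`, `incomplete_movement`,
`extra_movement`, `moving_at_start`) rather than raised.

`segment_trial` composes the full path and adds two standard
refinements:

- **Position pre-smoothing** (five-frame) before differentiation,
  mirroring the smoothing the acquisition chain applies to movement
  data. Differentiating raw jitter inflates the apparent speed of
  still frames (the norm of a noise difference is positive), eroding
  the still/moving separation.
- **SNR-adaptive boundary localization.** Cluster labels from the
  smoothed series fix the run structure; each boundary is then
  re-placed at the nearest crossing (within ±5 frames) of a
  per-movement threshold — the still level plus 30 % of that
  movement's peak — evaluated on a lightly (3-frame) averaged raw
  speed when the data are clean (still level ≤ 10 % of peak), or on
  the position-smoothed speed otherwise. Per-movement thresholds
  matter because the reach and the return have different peak speeds;
  a single global threshold systematically clips the slower movement.

Measured on the generator's conditions: with no noise all boundaries
of 200 trials are recovered exactly; with 2 mm noise ≥ 95 % fall
within ±5 frames. Gaps are bridged by linear interpolation with the
five-frame smoother applied to interpolated spans only; gaps longer
than 10 frames flag the trial as tracking loss.

## Kinematic measures

28 per accepted trial: 2 phases x (6 arm + 5 hand) + 6 grip. Hand
measures use the index tip expressed relative to the wrist; the hand
shares the arm's phase duration (a separate hand duration would be
redundant, and the 28-count bookkeeping forces the shared one).
Speeds for the velocity measures come from the same five-frame
smoothed series used in segmentation. The maximum deviation is the
distance to the *infinite* line through start and end (configurable in
principle; the straight-line path is not clamped to the segment). A
curvature index is undefined when the net displacement is below 1 mm;
the value is set missing and imputed downstream (participant-wise
column mean) before PCA — trials are kept, single measures are not
allowed to discard them.

## Dimensionality reduction

Correlation-matrix PCA (measures mix units, so covariance PCA would
let millimetre-scale measures dominate; a covariance option is a
one-line change on the correlation call). One pooled PCA across all
participants and both movement conditions. Components retained by
Horn's parallel analysis: observed eigenvalues against the 95th
percentile of eigenvalues from 1000 column-permuted tables, counting
leading exceedances. Varimax with Kaiser normalization (SVD
iteration, tolerance 1e-10; verified against R `stats::varimax`);
components re-ordered by rotated variance and sign-fixed so the
largest loading is positive. Scores are loading-weighted sums of
z-scored measures — deliberately not regression scores, matching the
loading-weighting convention; they are zero-mean over the fitted set
by construction.

## Motion QC

FD uses the printed formula with r = 50 / 300 / 180 mm for head /
forearm / hand. Effector FD derives from kinematics resampled at each
TR (sample-and-hold at the stride frame, 48 at 60 Hz; linear
interpolation is a config alternative), with rotational displacements
taken from the recorded segment-orientation angles
(`orientation-delta`); a `none` strategy zeroes the rotation term for
data without usable orientations. RMSD follows the Jenkinson
relative-RMS formulation (80 mm sphere, run-level mean).
Standardized DVARS divides the RMS temporal difference by its
expectation under temporally independent fluctuations at the observed
channel variances, so clean data hover near 1; it operates on
whatever channel panel is supplied (ROI series here — raw volumes are
out of scope). Censoring statistics default to the 0.5 mm and 0.2 mm
thresholds. FD-to-FD coupling is a Pearson correlation within
movement-block TRs, with a one-sample t test on Fisher-transformed
per-subject values.

The head-motion generator produces a target head-FD series as a scaled,
shifted Gaussian mixture of a standardized arm-FD component (weight =
the coupling c) and independent noise, clipped at zero, then decomposes
it into six cumulative rigid parameters whose FD reproduces the target
exactly. With the default amplitude the head FD mean sits near 0.1 mm.
Clipping at zero attenuates the realized correlation by well under the
0.05 tolerance at the default shape offset.

## GLM

Events are zero-duration impulses at trial onset (a boxcar duration is
a parameter); the HRF is the conventional double-gamma (peak delay 6 s,
undershoot delay 16 s, dispersions 1, ratio 6, 32 s kernel),
peak-normalized. Modulators are zero-centred scores convolved and
residualized against their condition's main regressor; nuisance FD
columns follow the arm-on-head, hand-on-arm orthogonalization scheme.
Any number of pre-supplied confound columns is accepted. The constant
column is last; error trials contribute up to two regressors split by
whether the participant actually moved.

Fitting is least squares via a rank-revealing decomposition (rank
deficiency reported, not raised). Serial correlation: the default is
AR(1) prewhitening with a **trace-matched** coefficient — the naive
lag-1 autocorrelation of OLS residuals is biased low because the
smooth design absorbs part of the autocorrelated noise, so the
estimate solves "expected residual lag-1 ratio under the projection =
observed ratio" using the design's orthonormal basis (AR(1) covariance
applied by forward/backward recursion; Brent root-finding). Without
the correction the modulator F test rejects true nulls at ~8–9 %
instead of ~5 % at these problem sizes; with it, simulated type-I
error is calibrated (5.9 % over 2000 runs at alpha = 0.05) and plain
OLS remains available (`ar_model="none"`) with unbiased betas.
Inference: t contrasts, partial F over the modulator columns, and
Benjamini–Hochberg across ROIs (surface-based cluster-level inference
is out of scope at desk scale, so FDR across a small ROI set replaces
topological FDR).

## Pipeline and trial accounting

`run_pipeline` chains all stages deterministically from one seed
(per-stage seeds spawned via `SeedSequence`). Every trial receives
exactly one category: `accepted`, `tracking_loss`, `feedback_bug`,
`unexpected_movement`, `moved_in_no_movement`, or `parse_failure`.
Annotated categories take precedence (they emulate manual inspection);
movement in a no-movement trial counts only when the parsed movement
is physically plausible (peak smoothed speed above 150 mm/s), so
clustered jitter is not misread as a violation. ROI BOLD is simulated
with known condition/modulator/motion effects (six motor-network ROIs
by default, a subset carrying planted kinematic effects) and fitted
per run; `std_dvars` is computed on the simulated ROI panel.

## Problem sizes

The test suite and the acceptance script use the sizes the analyses
are specified at: 200 trials per segmentation-recovery condition, 50
seeds x 800 trials for component recovery, 2000 null runs and 500
planted-effect runs for GLM calibration, ~10,000 movement TRs for
coupling recovery, and a one-participant, four-run session for the
end-to-end pipeline. The full suite runs in a few minutes on one CPU.

## What the generator does not emulate

Camera physics, marker occlusion geometry, real-time reconstruction
error structure beyond band-limited Gaussian jitter, glove flexion
sensors (fingertip positions are generated directly), non-rigid
head motion, image-space artifacts (DVARS operates on ROI panels, not
voxels), physiological noise beyond AR(1), and between-participant
kinematic idiosyncrasies beyond distributional spread. Passing tests
demonstrate correctness of the analysis chain under these idealized
conditions, not robustness to every failure mode of real recordings —
in particular, real velocity profiles need not respect the raised-bell
onset crispness, so real-data boundary accuracy should be validated
against manual parsing, as done in practice.
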