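# Methods

## The simulator: what it emulates and what it does not

`doublestep.simulate` generates sessions of a double-step reaching task on a
horizontal touchscreen. Coordinates: x = horizontal (rightward +), y =
sagittal depth (away from the body +), z = vertical (up +); the screen lies
in z = 0; positions are cm, sampling is 100 Hz.

**Geometry.** Four static targets sit 8 cm from the central fixation point
(left/right along x, near/far along y). Each has two shifted variants 2.4 cm
away along its own dimension's axis, so direction shifts displace targets
laterally and depth shifts displace them in distance from the body. A
session holds 120 trials — 60 static, 60 shifted — in seed-randomized
order. The 60 shifted trials divide evenly over the four static parents
(15 each); within a parent the two variants receive 8 and 7 trials, the
larger share alternating across parents so neither shift direction is
systematically favoured. (An exactly balanced-per-endpoint variant is
available by choosing `n_shifted` divisible by 8.)

**Movement model.** Each reach is a minimum-jerk trajectory (fifth-order
polynomial, zero endpoint velocity and acceleration) from a start position
near the body to the cued target. In shifted trials the target jumps at
movement onset (experiment 1) or 100 ms after it (experiment 2); after a
dimension-specific correction latency a second minimum-jerk submovement
toward the new target is superposed on the primary one, completing at touch.
Superposition (rather than re-planning) is the standard kinematic model of
double-step corrections and produces the smooth lateral-velocity divergence
the deviation analysis expects. If the latency leaves no room to correct —
or, for sagittal shifts in the experiment-2 defaults, with probability
`p_no_correction_sagittal = 1` — no correction occurs and the hand lands
near the original target, producing an endpoint error close to the 2.4 cm
shift distance.

**Default parameters and where they come from.**

| parameter | default | rationale |
|---|---|---|
| movement duration | truncated normal, mean 630 ms, sd 60 ms, min 400 ms | anchored so that 63% of the movement corresponds to ≈ 396 ms |
| reaction time | truncated normal, mean 350 ms, sd 50 ms, min 150 ms | typical visually guided reach initiation; free parameter |
| correction latency, horizontal | (195, 20) ms exp 1; (140, 20) ms exp 2 | matches the deviation times the analyses should recover (~196/193 and ~144/133 ms) |
| correction latency, sagittal | (290, 30) ms exp 1 | depth corrections are slower (~357/229 ms); uncorrected in exp 2 |
| marker noise | 0.05 cm i.i.d. per sample per axis | small relative to the 8 cm reach; tunable |
| endpoint noise | 0.4 cm | touchscreen scatter; tunable |
| wrist | index + (0, −5, 3) cm + independent noise | rigid-arm approximation |

The simulator does **not** model muscle dynamics, movement sub-segmentation,
speed–accuracy trade-offs, endpoint-dependent duration differences, or gaze.
Its trials are far more stereotyped than human reaches: decoders therefore
reach ceiling accuracy faster than they would on real data, and passing
tests demonstrate the *pipeline's* correctness and the *qualitative*
temporal structure (static goals readable before shifted ones; prediction
degrading with look-ahead), not human effect sizes.

## Kinematic analyses

**Deviation (correction) time.** For two groups of shifted trials toward
the opposite variants of one static target, the velocity component along the
shift axis is computed per trial by central differences over the movement
segment, aligned to the shift. A two-tailed two-sample t-test runs at every
sample; the deviation time is the first sample (at or after the shift)
opening a run of ≥ `run_length` consecutive significant samples. The default
`run_length = 10` (100 ms) suppresses isolated false crossings; a
single-sample criterion is available but produces spurious early detections
at realistic noise. Unequal trial lengths are handled by truncating all
traces to the shortest — no imputation. Detection necessarily trails the
generative correction latency by ~10–30 ms, because the corrective
minimum-jerk velocity ramps quadratically and must exceed the noise floor
before any test can see it; the simulator round-trip
(`kinematics.latency_recovery`) quantifies this.

**Endpoint accuracy** is the planar Euclidean distance between touch point
and target. **Reaction time** is cue-to-onset. **Trajectory variability**
is the across-trial sd of the x (or y) coordinate at the sample of peak 3D
speed.

## Decoding

Trials are time-normalized: the movement segment is linearly interpolated
onto 100 equally spaced points of 0–100% movement time, giving a 100 × 6
matrix (index x, y, z; wrist x, y, z). Windows of T = 8 consecutive samples
slide with stride 4 during training (24 chunks/trial) and stride 1 during
inference (93 window positions); a window's accuracy is plotted at its last
sample, so "% of movement" = end_index/99.

One network per problem is trained on the pooled chunks of all window
positions (a per-window-position variant would multiply models without
changing the questions asked here; pooled training matches a single reported
architecture). The network is a single 100-unit GRU layer read out at the
last time step by a dense head — softmax with categorical cross-entropy for
classification, linear with MSE for regression (6 outputs = the future
feature vector). Training: Adam (lr 0.001), batch size 32, early stopping on
a seeded random (stratified, for classification) 20% validation split of the
training chunks, best-validation weights restored. The GRU and Adam are
implemented in numpy with manual backprop through time, checked against
numeric gradients; everything is deterministic under a seed.

Evaluation is fivefold stratified cross-validation **split at the trial
level**: all chunks of a trial stay on one side of every fold, which the
test suite verifies by intersecting trial-id sets. On a 60-trial two-class
problem this gives 48 training and 12 test trials per fold, balanced across
classes. Features are z-scored with statistics fitted on training folds
only. For regression, targets are likewise standardized on training folds
and predictions mapped back before computing per-component R² pooled over
all valid stride-1 test chunks; chunks whose future sample would fall
outside the trial are dropped.

**Decoding problems.** Pairwise: the two static targets of one dimension
(static trials), or the two shifted variants of one static target (shifted
trials). Six-way: all six endpoints of a dimension. "Target clusters" for
regression are one static target plus its two shifted variants
(left/right/near/far). The pre-movement control decodes the raw
(un-normalized) 500 ms before movement onset — 50 samples in which the
simulated hand is stationary noise, so accuracy must sit at chance.

**Epoch budgets.** The library default mirrors a patience-500 /
10,000-epoch regime; the analyses in the acceptance script and tests use
`max_epochs = 100, patience = 12`, which on this simulator's
cleanly separable data reaches the same plateaus in a fraction of the time.
Problem sizes used by the acceptance script: 10 sessions (t6), one balanced
60-trial six-way problem (t7), 2 sessions × 4 clusters (t8), 12 simulated
participants (t9).

## Temporal statistics

**Curve comparison.** Per node, the two-sample Hotelling T² (for the scalar
accuracy, the squared pooled-variance t). Family-wise control uses the
max-statistic permutation distribution: group labels are permuted `n_perm`
times, the maximum node statistic recorded, and the (1−α) quantile taken as
the threshold — assumption-light, seeded, and calibrated (family-wise error
0.03–0.08 at α = 0.05 in the suite's 500-replicate null study). A
random-field (SPM-style) threshold would need smoothness parameters the
permutation approach does not; the inferential target (any-node false
positive ≤ α) is the same. Supra-threshold runs are reported as
[start%, end%] intervals at node resolution (93 nodes ≈ 1.1% granularity).

**Chance crossing** is the first node opening a run of ≥ 3 nodes strictly
above the chance level (run length 3 is the package's anti-flicker choice).

**Confidence ellipses.** Eigen-decomposition of the 2D sample covariance;
semi-axes √(χ²₂(coverage)·λᵢ) (5.991 at 95%), area πab. Because "area from
the standard deviations" is ambiguous, the raw one-sigma area π√(λ₁λ₂) is
also emitted (`area_sigma`); the χ²-scaled area is the default. Collinear
clouds are allowed and flagged degenerate (λ₂ = 0, zero area).

**Empirical chance level.** Two permutation controls are provided and they
are *not* equivalent at small n. `cross_validated_goal_decoding(...,
permute_labels=True)` permutes trial labels and retrains — the classical
pipeline null. With ~10 trials per class and cluster-separable features this
null is biased *above* 1/n (≈ 0.21–0.24 for the six-way problem): the
retrained network learns each kinematic cluster's majority permuted label,
and a test trial matches it more often than 1/n. `empirical_chance_curve`
instead trains on true labels and scores the fixed predictions against
permuted labels; its expectation is exactly the class-marginal chance level
(1/6 ≈ 0.17 on a balanced six-endpoint design), so it is the estimator used
when the quantity of interest is the chance level itself. The retrain-null
bias is a known small-sample property, not an error in either procedure.

## Reproducibility and numerical choices

A single global seed fans out to per-stage seeds through
`stage_seed(seed, stage_name, index)` (SeedSequence over a stable hash), so
simulation, each participant's decoding, and each statistical test are
independently reproducible; sessions are bitwise identical under a fixed
seed, and full report tables reproduce exactly. Event times are snapped to
the 10 ms sample grid so segment extraction is exact. Degenerate inputs
(single-class training sets, offsets leaving no chunks, unstratifiable
folds, collinear ellipse input, malformed sessions) raise explicit errors.

## Known limitations

- Simulated reaches are smooth and low-noise; absolute decoding accuracies
  and R² values are optimistic relative to human data, and only orderings
  and qualitative temporal structure should be compared.
- The deviation-time estimator has an intrinsic late bias of ~10–30 ms
  (detectability of a soft-onset correction), largest when the correction
  window is long.
- The permute-then-retrain null overstates chance at small trials-per-class
  (see above); use `empirical_chance_curve` for chance-level questions.
- The curve comparison treats participants as exchangeable units; no
  hierarchical (within-participant fold) variance modelling is attempted.
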