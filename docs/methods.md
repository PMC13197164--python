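# Methods

## Model structure

The task is modelled as a finite-horizon, discrete-time linear-quadratic
game between two controllers, each commanding one planar point-mass hand.
The 16-dimensional base state holds, per hand, position, velocity, and
muscle force (x/y pairs), followed by the center-cursor and target
positions. Hand dynamics are `m v̇ = −b v + f`, `τ ḟ = u − f`; the center
cursor integrates the mean hand velocity; the target is constant under the
dynamics (jumps are display events, see below). The base block is
discretized by forward Euler at dt = 10 ms (matrix-exponential
discretization is available via `build_dynamics(..., discretization=
"exact")`; at these time constants the two differ most on the muscle rows,
e^(−dt/τ) = 0.607 vs 0.5, which only rescales the effective control gain).

Visual feedback is delayed by 110 ms, implemented by augmenting the state
with its last 11 base blocks (192 states total). Each player observes, from
the *oldest* slot only: own hand position/velocity/force, partner hand
position/velocity, center-cursor and target position — 14 channels; the
partner's muscle force is never observable.

### Costs and hypotheses

Individual costs charge the control signal every step (R = r·I) and the
state only at the final step: the lateral center-cursor-vs-target error is
weighted 40,000 (narrow, task-relevant target) or 100 (wide,
task-irrelevant); the forward error always carries 40,000 because the
targets are short in that dimension. Small terminal regularizers on the
player's own hand velocity (10) and muscle force (0.01) make the solution
arrive and stop. There is no running state cost — all accuracy pressure
sits in the terminal matrix — so movement spreads smoothly over the
horizon (N = 130 steps, 1.3 s).

The joint cost is J_i + α_i·J_j. Policy hypotheses: `no_rep_self` solves
each player's LQR as if the partner never acts (and its estimator predicts
a zero partner command); the three representation models solve the coupled
game, with α = 0, 1, or 0.5.

### Nash solver

Backward recursion from the joint terminal matrices. At each step the pair
(F₁, F₂) must satisfy the coupled stationarity conditions
`F_i = (R_i + B_i'P_iB_i)⁻¹ B_i'P_i (A − B_j F_j)`; this is solved by
(optionally damped) fixed-point iteration to 1e-10 on the gain change, max
500 iterations, warm-started from the previous step. Because the control
dimension is 2, each iteration costs only thin matrix products; the
iteration is a linear contraction whose rate is set by the product of the
two 2×2 coupling blocks, and in practice converges in a handful of
iterations. Value matrices are symmetrized every step.

### Estimation

Kalman gains are precomputed by the standard forward covariance recursion
with diagonal measurement noise (SD 2 mm position, 0.02 m/s velocity,
0.02 N force) and diagonal process noise on the current base block only
(history slots are deterministic copies). During a trial, each player's
prior applies the internal model to its previous posterior using its own
efference copy and a prediction of the partner's command — the partner's
known gains applied to the player's *own* estimate under a representation,
zero without one.

**Process noise is the one estimator parameter that materially shapes the
model's probe response.** With process SD 1e-4 against 2 mm measurement
noise, the filter trusts its internal model so strongly that a displayed
3 cm jump is absorbed with a ~200 ms time constant, and the
involuntary-epoch response collapses to ~0.15 N. The default is SD 1e-3,
at which the update is fast (further increases change little) and
involuntary responses reach 0.4–1.4 N in relevant conditions, the scale
observed empirically. The control weight r = 0.1 was then fixed so that
the irrelevant terminal weight (100) produces a near-zero response while
the relevant weight (40,000) does not saturate — at much smaller r both
weights correct fully and the condition contrast vanishes. Both values
were chosen once and are recorded here and in the defaults.

## Trial simulation

Jumps are purely visual: the physical state never changes; a time-varying
lateral offset is added to the center-cursor (cursor-jump experiment 1) or
target (target-jump experiment 2) channels of each measurement, delayed by
the same 110 ms line (a measurement at step k shows the display as it was
11 steps earlier). History is never retro-edited. Perturbation trials ramp
the offset over 25 ms and hold it; probe trials ramp out 25 ms, hold
200 ms, ramp back 25 ms. The jump triggers when the true center cursor
crosses 25% of the 25 cm reach.

Force-channel probe trials zero the lateral column of both input matrices
in the plant **and in both players' internal models**: neither player's
command can move anything laterally, in fact or in prediction, and the
lateral hand states are pinned exactly (channel trials also carry no
lateral process noise). Using the unconstrained internal model instead
lets the predicted partner command cancel the estimated cursor error,
which produces a spurious condition contrast even for pure self-cost
policies; the channel-consistent model recovers the expected hypothesis
signatures. Feedback gains are always those of the unconstrained game —
the channel is a probe, not something the players plan around. The
reported response is the lateral component of B₁u₁ under the *original*
input matrix, and the per-trial VFR trace is the left-minus-right
(experiment 1) or right-minus-left (experiment 2) probe force difference
aligned to jump onset.

One subtlety of the coupled equilibrium: even at α = 0, a partner
representation makes F₁ depend on the partner's cost through F₂, so
`rep_self` shows a small (≈0.04 N, under 3% of the model's dynamic range)
*decrease* from pi/si to pr/si rather than exact equality — the best
response to a strongly correcting partner shrinks one's own small lateral
gain. Only `no_rep_self` is exactly condition-independent on the self-
irrelevant side.

## Analysis pipeline

Kinetic traces are filtered with a 5th-order Butterworth low-pass at 14 Hz
applied forward–backward (zero phase; the dual pass squares the magnitude
response, i.e. effective attenuation is doubled — DC gain stays exactly 1).
Recorded-style traces are re-timed so 0 is the instant the jump was
actually displayed (42 ms display latency). Epoch means use half-open
windows on the sample grid: involuntary [180, 230) ms, semi-involuntary
[230, 300) ms, voluntary [300, 400) ms. Final lateral hand deviation is
the difference between mean final lateral hand position on
non-perturbation and perturbation trials, with left-jump trials mirrored
about the non-perturbation mean before averaging so corrections in either
direction accumulate positively (the folding is configurable). Null-probe
trials are retained for drift checks and are not baseline-subtracted.
Trials are averaged within jump direction before differencing.

## Synthetic data

The generator reproduces the experimental design exactly: per block, one
lead-in non-perturbation trial plus 10 shuffled sets of
8 non-perturbation / 2+2 perturbation / 1+1+1 probe trials (81/40/30 per
block); four blocks per pair give each of the 48 participants all four
conditions, with the two partners realizing swapped conditions in the same
block.

Probe force traces (1000 Hz) are a quintic smoothstep rising between 100
and 170 ms after presentation to a plateau, scaled so the participant's
injected involuntary epoch mean survives the analysis filter exactly (the
unit shape's filtered epoch gain is divided out — a closed pipeline
identity), plus white trial noise (SD 0.3 N). Participant × condition
means are the game model's own noise-free predictions for a chosen
hypothesis (computed once and cached) plus between-participant Gaussian
variability, SD 0.2 N — chosen once so that the two planned contrasts land
at θ̂ ≈ 91% and ≈ 61% at n = 48, the empirical scale. A fast path
(`generate_epoch_table`) draws the epoch table directly from the same
distribution (between-participant SD plus the 0.012 N residual the
filtered, trial-averaged trace noise leaves) for power studies.

What the generator does **not** emulate: participant-specific kinematics,
learning or drift across blocks, reaction-time variability, non-Gaussian
or temporally structured force noise, and any trial-exclusion process.
Passing tests therefore show that the pipeline and statistics behave
correctly under the assumed data structure, not that recorded data meet
those assumptions.

## Statistics

The omnibus test is a 2×2 within-subject ANOVA (statsmodels `AnovaRM`);
in this design every F equals the squared paired-t of the corresponding
contrast, which the tests exploit as an independent oracle. Planned
comparisons use a non-parametric bootstrap of the paired differences:
recentered null, resampled with replacement, two-tailed, +1 continuity on
numerator and denominator. The default resampled statistic is the
**studentized** t-ratio: the plug-in percentile (raw-mean) variant is
measurably liberal at n = 48 (true size ≈ 0.058–0.061: its null is
narrower than the sampling distribution by √(47/48) and ignores the
t-tails), while the bootstrap-t holds 0.0495 in a 5000-test Monte-Carlo
at 10⁴ resamples; the mean variant remains available
(`statistic="mean"`). The default 10⁶ resamples are used for reported
results; tests run reduced counts. Holm–Bonferroni correction uses
statsmodels. θ̂ is the percentage of participants whose paired difference
lies in the hypothesized direction, ties counted half — on tie-free data a
multiple of 100/n.

## Reproducing published statistics from recorded data

`tests/test_acceptance.py::test_deposited_statistics_reproduce_printed_values`
recomputes the published interaction F values (±0.01) and θ̂ effect sizes
(exact) for both experiments from per-participant epoch data. Recorded
data cannot be bundled with the package; export the deposited dataset as
epoch tables (CSV, `participant` index column plus the four condition
columns `pi/si, pr/si, pi/sr, pr/sr`) to
`data/deposited/exp<1|2>_epoch_<involuntary|semi_involuntary|voluntary>.csv`.
Without those files the test reports failure rather than passing silently.

## Numerical choices and limitations

* dt = 10 ms is forced by the 110 ms delay being 11 steps; the probe's
  25 ms ramps are sampled on that grid via the continuous displacement
  profile.
* Horizon N = 130 (1.3 s) covers an ~800 ms reach plus stabilization; the
  jump onset falls near step 60, leaving the full response window inside
  the horizon for every tested noise seed.
* Simulations guard against divergence with a state-norm bound and raise a
  diagnostic error instead of returning garbage.
* The model omits signal-dependent motor noise, nonlinear arm dynamics,
  infinite-horizon solutions, reaction-time modelling, and the
  familiarization/washout phases of the experimental session.
* The exact observation/process covariances of the original implementation
  are not published; the defaults here are the package's own calibration
  (documented above) and everything is configurable.
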