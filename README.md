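# dyadreach

Models and analysis tools for **jointly controlled reaching**: two people
each hold a robotic handle and together steer a *center cursor* — displayed
at the midpoint of their hands — into their own target. When the targets
differ in width, lateral accuracy matters to one partner but not the other,
and the rapid, involuntary force a person produces in response to a sudden
cursor (or target) jump reveals how much of the *partner's* goal is built
into their feedback control policy.

`dyadreach` is for sensorimotor-control researchers who want to:

* solve two-player **linear-quadratic dynamic games** (coupled-Riccati Nash
  feedback gains over a finite horizon) with delayed, noisy sensory
  feedback handled by Kalman estimation;
* simulate reaching trials — plain reaches, persistent 3 cm cursor/target
  jumps, and **force-channel probe trials** that convert corrective intent
  into measurable wall force;
* run the **visuomotor feedback response (VFR)** analysis pipeline
  (zero-phase Butterworth filtering, display-latency alignment, left/right
  probe differencing, involuntary / semi-involuntary / voluntary epoch
  means) and the statistics stage (2×2 repeated-measures ANOVA, bootstrap
  paired tests with Holm–Bonferroni correction, common-language effect
  sizes θ̂);
* generate **synthetic multi-pair datasets** with the full trial design
  (24 pairs × 4 blocked conditions × 151 trials) so every downstream stage
  is testable without recorded data.

## The model

Each hand is a planar point mass (m = 1.5 kg, viscosity b = 0.1 N·s/m)
driven by a muscle force that low-pass filters the control signal
(τ = 20 ms). The state stacks both hands, the center cursor (midpoint
dynamics, ṗ_cc = (ṗ₁+ṗ₂)/2), and the target:

```
x_{k+1} = A x_k + B₁ u_{1,k} + B₂ u_{2,k}
```

Player *i* minimizes a joint quadratic cost J_i + α_i J_j, where the
individual cost J_i charges the control signal every step (R = r·I) and the
center-cursor-vs-target error at the final step only — the lateral error
weight is 40,000 when the player's target is narrow (task-relevant) and 100
when it is wide. The equilibrium feedback gains u*_i = −F_{i,k} x̂_{i,k}
solve the coupled Riccati recursions; each player's state estimate x̂ comes
from a Kalman filter over a 110 ms delay line (the state is augmented with
its last 11 copies at 10 ms resolution), fed by noisy observations of both
hands, the cursor, and the target — but not the partner's muscle force.

Four policy hypotheses differ in whether F₁ is solved with knowledge of F₂
(partner representation) and in α: `no_rep_self` (F₂ ≡ 0 assumed, α = 0),
`rep_self` (Nash, α = 0), `rep_equal` (Nash, α = 1), and `rep_weighted`
(Nash, α = 0.5).

## Worked example

```bash
python examples/model_predictions.py
```

prints the involuntary-epoch (180–230 ms) model VFR per hypothesis and
condition (`pi`/`pr` = partner-irrelevant/relevant, `si`/`sr` = self):

```
hypothesis        pi/si    pr/si    pi/sr    pr/sr
--------------------------------------------------
no_rep_self       0.055    0.055    0.633    0.633
rep_self          0.038    0.001    1.371    0.492
rep_equal         0.079    0.548    0.548    0.556
rep_weighted      0.057    0.443    0.606    0.523
```

Each number is the mean left-minus-right probe-trial channel force (N)
during the involuntary epoch. Self-cost policies (top two rows) never
raise their response when only the *partner's* target is relevant
(`pr/si` ≈ `pi/si`, both near zero); joint-cost policies do
(`pr/si` ≫ `pi/si`) — they spend energy to help the partner. The weighted
joint cost additionally responds less when it expects a relevant-target
partner to share the correction (`pr/sr` < `pi/sr`), the signature that
distinguishes it from the equal joint cost.

`examples/simulate_trials.py` rolls out single trials (reach accuracy,
jump corrections, probe force time course) and
`examples/synthetic_study.py` runs a reduced synthetic experiment through
the complete analysis + statistics pipeline.

A thin CLI chains the stages on disk:

```bash
dyadreach synth --pairs 24 --seed 1 -o synth/
dyadreach analyze --in synth/probe_traces.csv -o epochs/
dyadreach stats --in epochs/epoch_involuntary.csv --nboot 1000000 --seed 3
```

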