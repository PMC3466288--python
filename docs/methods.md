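# Methods

This note documents the model implemented in `impedadapt`: its equations
and assumptions, every tunable parameter with its default and rationale,
what the simulated protocols emulate (and what they do not), the
numerical choices, and the places where the design was genuinely open.

## 1. Plant

A rigid planar two-link arm moves in the horizontal plane (no gravity),
shoulder at the origin, x to the subject's right, y away from the body,
counter-clockwise angles positive:

```
M(q) q̈ + C(q, q̇) q̇ + B q̇ = τ + J(q)ᵀ F_ext
```

with the standard two-link inertia matrix `M`, Coriolis matrix `C`, hand
Jacobian `J`, and a constant passive joint-viscosity matrix `B`.
Defaults (upper arm 0.31 m / 1.93 kg, forearm+hand 0.34 m / 1.52 kg,
inertias 0.0141 / 0.0188 kg m², com distances 0.165 / 0.19 m, B =
[[0.8, 0.2], [0.2, 0.8]] N m s/rad) are anthropomorphic values from the
planar-arm modelling literature.

Six muscles — shoulder flexor/extensor, elbow flexor/extensor,
biarticular flexor/extensor — act through **constant moment arms**

```
A = [[ 0.040 −0.040 0      0      0.028 −0.028 ]
     [ 0      0     0.025 −0.025  0.028 −0.028 ]]  (m)
```

so muscle lengths are linear in posture, `l = l0 − Aᵀ(q − q_ref)`.
Posture-dependent moment arms, tendon dynamics and force–velocity curves
are out of scope.  The antagonists of each pair carry equal moment-arm
magnitudes, so uniform co-activation of a pair is exactly
torque-balanced: it cancels at the joint while raising impedance.  (An
asymmetric biarticular pair injects a net torque bias that grows with the
co-activation the learning rule accumulates; the symmetric default keeps
co-activation mechanically silent, which is the property the model's
impedance story rests on.)

Muscle tension is affine-visco-elastic and rectified (muscles only pull):

```
T = max(0, T0·u + (k0 + k1 u)·e + (b0 + b1 u)·ė)
```

where `e = l − l_r(t)` is stretch relative to the *reference trajectory*
length and `u ≥ 0` the activation.  Intrinsic stiffness and viscosity
increase with activation — co-contraction stiffens the limb.  Defaults:
`T0 = 300 N`, `k0 = 3700 N/m`, `k1 = 20000 N/m`, `b0 = 40 N s/m`,
`b1 = 160 N s/m` per unit activation.  These are calibrated (see §7)
rather than measured: the tension scale puts fast reaching at activations
of order 0.3–1, and the stiffness scale puts the operational endpoint
stiffness of a trained fast movement in the several-hundred N/m range of
human measurements.

**Signal-dependent noise**: each muscle's command is multiplied by
`1 + cv·n(t)` where `n` is a unit-variance Ornstein–Uhlenbeck process
low-pass filtered at 10 Hz (white noise at the 1 ms step would produce
unphysically high-frequency force).  `cv = 0.03`.  Commands are rectified
after the noise.

Integration is fixed-step explicit RK4 at `dt = 1 ms`, with the neural
command held over the step (zero-order hold) and the reference sampled on
a half-step grid so the RK4 stages read it exactly.  Trials whose hand
speed exceeds 10 m/s abort and are excluded from learning.

## 2. Controller

The command is `u = max(0, u_ff) + u_fb`.

Feedback uses the **sliding error** `ε(t) = e(t−δ) + κ ė(t−δ)` — a
velocity-weighted muscle-length error read out one neural delay in the
past (`δ = 60 ms` by default, configurable up to the 200 ms the model
family tolerates; `κ = 50 ms`).  The V-shape

```
u_fb = a⁺ ε⁺ − a⁻ ε⁻,    a⁺ = 30, a⁻ = 15  (activation per metre)
```

is zero exactly at zero error, activates stretched muscles at the steeper
slope and shortening muscles at half that slope (2:1 by default — only
the inequality `a⁺ > a⁻` is constrained by the model).  Feedback acts
continuously within the trial; learning only between trials.

Reference movements are minimum-jerk point-to-point reaches and
constant-speed circles, converted to joint space by inverse kinematics
(elbow-positive branch) and to reference muscle lengths through the
linearized geometry.  For unstable tasks an *empirical-mean* reference
(mean muscle-length path of the last n successful trials, warm-started
from the plan) is implemented; it feeds **only the error pathway**
(feedback and learning), never the mechanical equilibrium of the muscle
elasticity — see §6.

## 3. Learning law

The feedforward command is linear in non-negative parameters,
`u_ff = Φ(x) w`.  The cost of a trial is defined as

```
J(w) = (Q/2) Σ_t ‖u_fb(t)‖² dt + R ‖w‖₁
```

feedback effort plus a parameter (activation/impedance) effort.  Under
the *feedback-absorption* assumption — each unit of feedforward
activation at a state removes one unit of the feedback that had to
correct for it there, `∂u_fb/∂w = −Φ` — gradient descent with step η
gives the between-trial update

```
Δw = η Q Σ_t Φ(x_t)ᵀ v(s(t)) dt − η R 1,     v(s) = a⁺ s⁺ − a⁻ s⁻
```

applied to the **delay-compensated** sliding error `s(t) = e(t) + κ ė(t)`
(the sliding error one delay ahead, aligned with the state that caused
it), and clipped at zero.  Writing `v(s) = α s + β |s|` with
`α = (a⁺−a⁻)/2`, `β = (a⁺+a⁻)/2` decomposes each update into

* a signed **reciprocal** term `∝ α s` — force opposing systematic error
  on the next trial;
* a non-negative **co-activation** term `∝ β |s|` — impedance raised by
  deviations of either sign, noise included, hence *stochastic deviation
  alone builds co-activation*;
* the uniform **decay** `−ηR` — the same subtraction for every parameter,
  so weakly supported parameters are extinguished first (winner-take-all
  pruning of superfluous impedance).

Defaults: `η = 6`, `Q = 1`, `R = 0.002`, hence decay γ = ηR = 0.012 per
trial.  These were calibrated jointly so that a velocity-field learning
curve plateaus within roughly 100 trials while the noise-driven
co-activation equilibrium stays modest (§7).  A trial containing
non-finite errors, or an aborted trial, is discarded without an update.

## 4. RBF network

`u_ff(x) = max(0, W g(x))` with Gaussians
`g_j(x) = exp(−½ Σ_d ((x_d−c_jd)/σ_jd)²)` over the standardized 4-D state
(positions and velocities z-scored over the training states, the scaling
frozen into the network).  Centres come from best-of-restarts Lloyd
K-means (delegated to scikit-learn) on the interaction-free states; the
neuron count is searched in [3, 80] from an initial 20 by **diminishing
returns**: grow while one more neuron still cuts the clustering objective
D by at least 5% (for states sampled along movement trajectories the
relative gain decays like 2/K, making the criterion insensitive to the
number of movements; it lands at 20–35 neurons on the protocols here).
The total restart budget is 2000 across the counts examined, at most 100
Lloyd iterations each.  Per-neuron, per-dimension widths cover the
assigned cluster (largest within-cluster distance per dimension) times an
overlap factor of 2.0, floored at 0.15 standardized units; an isotropic
option exists.  Centres and widths are then frozen — only `W` adapts, so
generalization happens purely through overlapping activation fields.

With the weight matrix flattened, the network is exactly the generic
linear-in-parameters primitive with `Φ(x) = kron(I₆, g(x)ᵀ)`; the test
suite asserts this identity and the equivalence of the network update
with the generic law.

## 5. Protocols (the synthetic data)

All inputs are generated internally; the three drivers emulate the
*structure* of published human experiments at simulation scale:

* **Movement generalization** — eight 12 cm / 300 ms centre-out reaches
  plus a 10 cm-radius / 300 ms counter-clockwise circle around
  (0, 0.45) m.  The network is initialized on these movements' states and
  pre-trained for 400 mixed free trials (the 300 ms circle demands hand
  speeds of 2.1 m/s and is far outside naive skill, so the free practice
  is what makes the free-condition circle round).  Two arms then adapt to
  the velocity field `F = [[0, 13], [−13, 0]] v` (N s/m): 100 circle
  trials, or 100 reach trials in balanced random blocks.  Five catch
  circles per phase (learning off) give the axis-ratio metric
  (horizontal extent / vertical extent).
* **Granularity** — sixteen directions, 22.5° apart; 200 free
  pre-training trials, 80 free template trials, then 160 trials in VF1,
  VF2 or VF4 (`F = 30·sin(kθ)·[[0,−1],[1,0]] v` N s/m, θ the planned
  target direction, constant within a trial).  Learning curves are
  Pearson correlations of the 2-D velocity time series against the
  same-direction free templates, smoothed with a 20-movement moving
  average.  The same network (size and fields) serves all three fields.
* **Impedance learning** — 600 ms, 25 cm movements from (−0.09, 0.30) m
  at bearings 45° and 10° (35° apart), randomly intermixed, 60 free then
  300 trials in the divergent field (`β = 250 N/m`, barrier at 5 cm with
  50 N s/m damping, force-free 2.5 cm start/end circles).  Endpoint
  stiffness ellipses are computed from mid-movement activation averaged
  over the last ten trials per direction, before and after learning.

What the generator does **not** emulate: human inter-subject variability,
EMG-level muscle recruitment, reflex-gain modulation (explicitly outside
the model), fatigue, or the visual feedback loop.  Passing tests show the
model reproduces the *simulation-scale* phenomena, not that it fits any
individual human data set.

## 6. Design choices that were genuinely open

* **Error reference in the unstable task.**  Using the mean of the
  model's own recent successful trials as the error reference is
  self-referential: it relieves the corrective pressure mid-path and the
  trials drift outward.  The default therefore keeps the planned
  minimum-jerk path as the error reference; the empirical-mean mode
  remains available (`run_kadiallah(..., n_mean=5)`), engages only once
  enough successful trials exist, and acts only on the error pathway.
* **Initialization states.**  The basis must carry activation fields
  wherever the early error signal lives.  For the movement-generalization
  protocol the planned states are augmented with one naive
  (feedback-only) performance of each movement — the naive circle
  deviates by tens of centimetres and learning needs support along that
  path.  For the reaching-only granularity protocol the planned
  trajectories alone describe the free condition (subjects arrive
  skilled at ordinary reaches), and the tighter basis is what preserves
  the contrast between learnable and unlearnable field granularities.
  For the unstable task the states span a lateral *variability corridor*
  (reference paths plus smooth lateral bumps up to the barrier,
  persisting through the hold): the unstable dynamics amplify
  trial-to-trial variability across exactly that tube, and a network
  cannot learn where it has no fields.
* **Target randomization** is balanced (every target once per random
  block) — "randomly intermixed" with even sampling; it removes most of
  the seed-to-seed variance of the learning curves.
* **Reflex contribution to measured stiffness.**  A static displacement
  stretches one muscle of a pair (tension up, slope a⁺) and shortens the
  other — which the V-shape *also* activates, with that tension acting
  along the displacement.  The net first-order reflex stiffness per
  muscle is therefore `(a⁺−a⁻)/2 · T0`, the reciprocal half of the
  V-shape only; the co-activation half contributes a restoring-free
  tension bias.  The analytic ellipse uses this slope and matches a
  brute-force static force-probe of the full plant within 5%.
* **Movement geometry of the unstable task** (the printed coordinates are
  not machine-readable in the source text): bearings were chosen so that
  each movement's lateral direction lies near directions the muscle set
  can actually stiffen — at the mid posture the shoulder pair acts on the
  hand along ≈135°, the elbow pair along ≈90°, the biarticulars along
  ≈40°, and no non-negative co-activation can make a direction far from
  these the major axis.  With these bearings the free-condition ellipse
  is already elongated roughly laterally, consistent with the behaviour
  the model family describes.
* **Cost functional.**  The V-shaped update law is derived here from the
  feedback-effort cost with the absorption assumption (§3); the
  finite-difference gradient oracle in the tests pins the exact
  correspondence.  The l1 effort on parameters (rather than on the
  time-integrated command) is what makes the decay uniform across
  parameters.

## 7. Calibration

Nothing in the model's numeric surface is printed in a machine-readable
form by its sources, so all defaults were set by simulation calibration,
once, against the phenomena the protocols are meant to exhibit: a round
free-condition circle; first-exposure distortion of the circle around
ratio 0.8 with after-effects around 1.2 in both training arms; learning
curves that separate VF1/VF2 (> 0.9) from VF4 (< 0.9) at the free-motion
correlation ceiling set by motor noise; divergent-field trials that are
noticeably unstable at first and near-straight after 300 trials with a
predominantly lateral stiffness increase; and 20–35 neurons from the
sizing stage.  The couplings are real: noise amplitude trades the
correlation ceiling against noise-driven co-activation; muscle stiffness
gain trades first-exposure distortion against impedance masking of the
fine-grained field; decay trades after-effect size against co-activation
equilibrium.  The shipped configuration is the joint compromise;
individual experiments were *not* given private physics.

## 8. Known limitations

* The 300 ms, 10 cm-radius circle requires ~44 m/s² centripetal
  acceleration; tracking it is at the edge of the plant's strength, and
  the after-effect ratio consequently runs ~0.05–0.1 above the nominal
  1.2 on some seeds.
* The VF4-vs-0.9 separation and the 100-trial error-halving criterion
  are reproduced with margins comparable to their seed-to-seed spread;
  occasional seed sets land on the wrong side.
* Feedback gains are fixed: modulation of reflex responses by task or
  learning phase is outside the model.
* The stiffness ellipse ignores the geometric (posture-curvature) and
  viscous terms; the probe test bounds the resulting error at the 5%
  level for the postures used.
* Muscle geometry is linearized; far outside the calibrated workspace the
  constant-moment-arm assumption degrades.
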