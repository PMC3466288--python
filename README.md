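# impedadapt

Trial-by-trial learning of **force and impedance** in a simulated planar
two-joint, six-muscle human arm, with generalization across movements
through a radial-basis-function representation of the joint state space.

When people move against novel dynamics — a tool, a robot handle, an
unstable object — they adapt both the forces they produce *and* the
mechanical stiffness of the limb, and what they learn on one movement
transfers to neighbouring ones. `impedadapt` implements a computational
model of this process and reproduces three classic force-field adaptation
experiments in simulation: transfer of learning between reaching and
circular movements in a velocity-dependent field, the limits of learning
increasingly fine-grained (direction-variant) fields, and selective
impedance learning for multiple movement directions in a divergent,
unstable field.

## The model

The motor command for the six muscles (shoulder, elbow and biarticular
antagonist pairs) is

```
u(t) = u_ff(x(t)) + u_fb(t)
```

* **Feedback** is a delayed V-shaped function of the per-muscle sliding
  error `ε(t) = e(t−δ) + κ ė(t−δ)` (muscle-length error relative to the
  reference trajectory, delay δ = 60 ms):
  `u_fb = a⁺ ε⁺ − a⁻ ε⁻` with `a⁺ > a⁻ > 0` — *both* a stretched muscle
  and its shortening antagonist are activated, the stretched one more, so
  perturbations of either sign produce corrective force *and*
  co-activation.
* **Feedforward** is a Gaussian RBF network over the 4-D state
  `x = (q, q̇)`: `u_ff = max(0, W g(x))`, with centres placed by K-means
  on the states of interaction-free movements, widths covering each
  cluster scaled for overlap, and non-negative weights `W`.
* **Learning** is gradient descent, between trials, on a cost of feedback
  error plus effort:
  `ΔW = η Q Σ_t v(s(t)) g(x_t)ᵀ dt − γ`, where `v` is the V-shape applied
  to the delay-compensated sliding error `s(t) = e(t) + κ ė(t)` and `γ` is
  a uniform decay.  Splitting `v` into odd and even parts decomposes each
  update into a signed *reciprocal* term (opposes systematic error), a
  non-negative *co-activation* term (stiffens the limb in response to
  deviations of either sign — noise included), and the decay that removes
  superfluous co-activation winner-take-all style.
* The **plant** is a rigid two-link arm driven by pull-only muscles with
  constant moment arms and activation-dependent visco-elasticity
  `T = max(0, T0·u + (k0+k1 u)·e + (b0+b1 u)·ė)`, signal-dependent motor
  noise, and RK4 integration at 1 ms.

Environments: the null field NF, a velocity-dependent field `F = B v`,
its direction-variant versions VF1/VF2/VF4 (curl gain `∝ sin(kθ)` of the
movement direction θ), and a divergent field `F_lat = β·p` pushing the
hand away from the straight path, with a damping safety barrier beyond
5 cm and force-free 2.5 cm start/end circles.

## Worked example

```bash
python examples/02_movement_generalization.py
```

prints, for one seed of the movement-generalization protocol,

```
circle axis ratios (horizontal / vertical extent):
  free condition                       1.03
  first exposure to the field          0.81
  in field after circle training       1.04
  in field after reach-only training   0.90
  after-effect (circle-trained)        1.36
  after-effect (reach-trained)         1.24
```

The drawn 10 cm circle is round in the free condition (ratio ≈ 1),
squeezed vertically on first exposure to the velocity field (≈ 0.8),
round again after adapting — whether the field was learned on the circle
itself or *only on reaching movements* (transfer) — and distorted in the
mirror direction (> 1) when the field is silently removed.  The other
examples print the granularity learning curves (`03_field_granularity.py`)
and the divergent-field stiffness ellipses (`04_impedance_learning.py`).

A thin CLI wraps the same drivers:

```bash
impedadapt run kadiallah --seed 1 --out results/kad1
impedadapt metrics --in results/kad1
```

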