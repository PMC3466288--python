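# Default physical and algorithmic parameters.
#
# The planar two-joint six-muscle arm and its learning controller.  All
# quantities carry SI units noted in the comments.  Muscle columns are ordered
#   [shoulder flexor, shoulder extensor, elbow flexor, elbow extensor,
#    biarticular flexor, biarticular extensor]

arm:
  l1: 0.31          # upper-arm length (m)
  l2: 0.34          # forearm+hand length (m)
  m1: 1.93          # upper-arm mass (kg)
  m2: 1.52          # forearm+hand mass (kg)
  lc1: 0.165        # shoulder -> upper-arm centre of mass (m)
  lc2: 0.19         # elbow -> forearm centre of mass (m)
  I1: 0.0141        # upper-arm moment of inertia about its com (kg m^2)
  I2: 0.0188        # forearm moment of inertia about its com (kg m^2)
  viscosity:        # passive joint viscosity matrix (N m s / rad)
    - [0.80, 0.20]
    - [0.20, 0.80]
  q_min: [-0.30, 0.05]   # joint limits (rad), [shoulder, elbow]
  q_max: [2.80, 2.80]

geometry:
  # moment-arm matrix A (m): rows = [shoulder, elbow], columns = muscles.
  # Flexors produce counter-clockwise (positive) torque.
  moment_arms:
    - [0.040, -0.040, 0.000,  0.000, 0.028, -0.028]
    - [0.000,  0.000, 0.025, -0.025, 0.028, -0.028]
  # muscle lengths at the reference posture (m); only differences matter
  # in the linearized geometry
  l0: [0.130, 0.130, 0.110, 0.110, 0.260, 0.260]
  q_ref: [1.0472, 1.5708]   # reference posture (rad)

muscle:
  T0: [300.0, 300.0, 300.0, 300.0, 300.0, 300.0]  # tension per unit activation (N)
  k0: 3700.0         # intrinsic muscle stiffness at rest (N/m)
  k1: 20000.0       # stiffness increase per unit activation (N/m)
  b0: 40.0          # intrinsic muscle viscosity at rest (N s/m)
  b1: 160.0         # viscosity increase per unit activation (N s/m)

noise:
  cv: 0.03          # signal-dependent noise: std = cv * activation
  cutoff_hz: 10.0   # low-pass cutoff of the motor-noise process (Hz)

feedback:
  stretch_slope: 30.0       # V-shape gain on stretch error (activation / m)
  shortening_slope: 15.0    # V-shape gain on shortening error (activation / m)
  kappa: 0.05               # velocity weighting in the sliding error (s)
  delay: 0.060              # neural feedback delay (s); robust up to 0.2

learning:
  error_weight: 1.0     # Q: cost weight on squared feedback command
  effort_weight: 0.002  # R: cost weight on the l1 norm of the parameters
  rate: 6.0             # eta: gradient-descent step per trial
  decay: null           # gamma = eta * effort_weight unless set explicitly

rbf:
  k_min: 3              # smallest admissible neuron count
  k_max: 80             # largest admissible neuron count
  k_init: 20            # neuron count at which the size search starts
  restart_budget: 2000  # total k-means restarts across the size search
  lloyd_max_iter: 100   # Lloyd iterations per restart
  width_scale: 2.0      # overlap factor multiplying the data-coverage width
  width_floor: 0.15     # minimum width (standardized state units)
  improvement_tol: 0.05    # stop adding neurons below this relative gain in D
  isotropic: false      # per-dimension widths by default

fields:
  vf_matrix:            # velocity-dependent field gain B (N s/m): F = B v
    - [0.0, 13.0]
    - [-13.0, 0.0]
  vfk_gain: 30.0        # direction-modulated curl gain amplitude (N s/m)
  df_gain: 250.0        # divergent-field lateral stiffness (N/m)
  barrier_threshold: 0.05   # lateral deviation engaging the safety barrier (m)
  barrier_damping: 50.0     # barrier damping on lateral velocity (N s/m)
  endzone_diameter: 0.025   # start/end circles with no field (m)

simulation:
  dt: 0.001             # integration step (s), fixed-grid explicit RK4
  max_hand_speed: 10.0  # divergence guard: abort trial beyond this (m/s)
  baseline_activation: 0.02  # resting muscle tone (dimensionless)
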