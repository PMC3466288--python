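"""Simulate one reaching trial and inspect the per-step logs.

Builds a 12 cm, 300 ms minimum-jerk reach, clusters an RBF network on its
interaction-free states, runs a single noisy trial in the null field and
prints what the simulator recorded.  With zero feedforward weights the
movement is carried by muscle visco-elasticity and delayed V-shaped
feedback alone, so the hand undershoots — the error the learning law
feeds on.
"""

import numpy as np

import impedadapt as ia
from impedadapt.experiments import CENTER, network_for_plans

cfg = ia.default_config()
plan = ia.reach_plan(CENTER, CENTER + [0.0, 0.12], 0.3, cfg, hold=0.1)
net = network_for_plans([plan], cfg, seed=0)

res = ia.simulate_trial(plan, net, ia.null_field(), cfg,
                        rng=np.random.default_rng(0))

print(f"network size:        {net.n_neurons} neurons")
print(f"steps logged:        {res.n_steps} (1 ms each)")
print(f"terminal error:      {res.terminal_error() * 1e3:.1f} mm "
      "(naive undershoot: no feedforward learned yet)")
print(f"peak hand speed:     {np.linalg.norm(res.hand_vel, axis=1).max():.2f} m/s "
      "(planned peak 0.75 m/s)")
print(f"peak muscle tension: {res.tensions.max():.1f} N")
print(f"max |lateral dev|:   {np.max(np.abs(res.lateral_deviation())) * 1e3:.1f} mm")
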