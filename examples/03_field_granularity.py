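"""How fine-grained an environment can the feedforward model learn?

16-direction reaching against direction-variant curl fields whose gain
flips sign with spatial frequency k = 1, 2 or 4 across target directions.
The learning curve is the velocity correlation between field trials and
free-movement templates (20-trial moving average).  The coarse fields
(VF1, VF2) are learned — correlation climbs above 0.9 and removing the
field leaves large after-effects; the finest field (VF4) cannot be
represented across the overlapping activation fields, its correlation
stays below 0.9, and its small after-effects show that impedance, not a
learned force, masked it.
"""

import impedadapt as ia

out = ia.run_thoroughman(seed=1)

print(f"free-movement correlation ceiling: {out['nf_correlation']:.3f}")
for k in (1, 2, 4):
    print(
        f"VF{k}: final smoothed correlation {out['final_correlation'][k]:.3f}"
        f"   after-effect deviation {out['after_effect_deviation'][k]*1e3:5.1f} mm"
    )
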