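"""Transfer of velocity-field learning between reaches and circles.

Runs the movement-generalization protocol for one seed: the network is
first trained on free reaches and circles, then adapts to a
velocity-dependent force field either directly on the 10 cm circle or on
reaching movements only, and circles are probed in the field and after
its silent removal.  The printed numbers are horizontal/vertical extent
ratios of the drawn circle: ~1 free and after adaptation, <1 (vertical
elongation) on first field exposure, >1 (mirror-image after-effect) when
the field is removed — in both the circle-trained and the reach-trained
(transfer) arm.
"""

import impedadapt as ia

out = ia.run_conditt(seed=1)

labels = {
    "nf": "free condition",
    "first_exposure": "first exposure to the field",
    "in_field_direct": "in field after circle training",
    "in_field_transfer": "in field after reach-only training",
    "after_direct": "after-effect (circle-trained)",
    "after_transfer": "after-effect (reach-trained)",
}
print("circle axis ratios (horizontal / vertical extent):")
for key, label in labels.items():
    print(f"  {label:36s} {out['ratios'][key]:.2f}")
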