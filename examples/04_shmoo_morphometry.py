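"""Inscribed-circle morphometry of yeast mating projections.

Generates synthetic cell masks (disc body + capsule protrusion of known
geometry) and measures each one: body circle, shmoo circle, projection
length and width, and the circular fraction of the mask.
"""

import numpy as np

from gammatail import ShmooGroundTruth, analyze_mask, make_shmoo_mask

print(f"{'true len':>8s} {'true wid':>8s} {'body r':>7s} {'length':>7s} {'width':>6s} {'circ frac':>9s}")
for L in (10.0, 20.0, 30.0):
    for w in (5.0, 9.0):
        mask, _ = make_shmoo_mask(ShmooGroundTruth(20.0, L, w, angle=0.7, grid_size=112))
        m = analyze_mask(mask)
        print(
            f"{L:8.0f} {w:8.0f} {m.body.radius:7.2f} {m.length:7.2f} "
            f"{m.width:6.2f} {m.circular_fraction:9.3f}"
        )

print(
    "\nLength and width track the generating geometry to sub-pixel accuracy; "
    "the circular fraction (foreground inside the body circle) falls as the "
    "projection grows — a round, unresponsive cell scores near 1."
)
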