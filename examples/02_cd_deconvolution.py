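"""Decompose CD spectra into helix/sheet/coil fractions.

Simulates noisy far-UV spectra of peptides with increasing helix
content, recovers the structure fractions by simplex-constrained least
squares, and reports helix% relative to the most helical variant —
the normalisation used when ranking a mutant ladder by CD.
"""

import numpy as np

from gammatail import (
    StructureFractions,
    fit_fractions,
    make_basis,
    relative_helix_percent,
    simulate_cd_spectrum,
)

basis = make_basis(np.arange(190.0, 250.5, 0.5))

truths = {
    "WT": StructureFractions(0.05, 0.10, 0.85),
    "M1": StructureFractions(0.30, 0.10, 0.60),
    "M3": StructureFractions(0.55, 0.10, 0.35),
    "M4": StructureFractions(0.75, 0.05, 0.20),
}

fits = {}
for seed, (name, truth) in enumerate(truths.items(), start=101):
    spec, _ = simulate_cd_spectrum(truth, basis, noise_sd=0.05, seed=seed)
    fits[name], resid = fit_fractions(spec, basis)

print(f"{'variant':8s} {'true fH':>8s} {'fit fH':>8s} {'fit fE':>8s} {'fit fC':>8s} {'rel. helix%':>12s}")
for name, f in fits.items():
    rel = relative_helix_percent(f, fits["M4"])
    print(
        f"{name:8s} {truths[name].fH:8.2f} {f.fH:8.3f} {f.fE:8.3f} {f.fC:8.3f} {rel:12.1f}"
    )

print(
    "\nFractions are recovered from spectra with 5%-of-max Gaussian noise; "
    "relative helix% expresses each variant's helix fraction as a "
    "percentage of M4's (M4 = 100)."
)
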