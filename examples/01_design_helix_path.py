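"""Greedy disorder-to-order design of a peptide tail.

Starting from a disordered 11-mer, find the minimal ladder of single
mutations that drives the predicted helix content as high as possible,
then build the two isometric controls: C1 (same positions, residues
chosen to keep the tail disordered) and C2 (same positions, residues
from the original residue's physicochemical class chosen to promote
helix).
"""

from gammatail import (
    Peptide,
    greedy_helix_path,
    helix_percent,
    isometric_controls,
    mutation_percent,
    predict_ss,
)

scorer = lambda p: helix_percent(predict_ss(p))

wt = Peptide("wt", "MNESSQKTSGS")
print(f"wildtype  {wt.sequence}  ss={predict_ss(wt)}  Hel%={scorer(wt):5.1f}")

path = greedy_helix_path(wt, scorer, max_steps=10, allow_insertions=True)
for i, step in enumerate(path.steps, 1):
    mut_pct = mutation_percent(wt, step.result, [s.as_edit() for s in path.steps[:i]])
    print(
        f"M{i}        {step.result.sequence}  ss={predict_ss(step.result)}  "
        f"Hel%={step.helix_pct:5.1f}  Mut%={mut_pct:4.1f}  "
        f"({step.kind} {step.from_aa or '-'}{step.position}{step.to_aa})"
    )

for mode in ("C1", "C2"):
    ctrl = isometric_controls(path, scorer, mode)
    print(f"{mode}        {ctrl.sequence}  ss={predict_ss(ctrl)}  Hel%={scorer(ctrl):5.1f}")

print(
    "\nEach step is the single edit that most increases predicted helix%; "
    "Mut% is edits over mutant length. C1 re-mutates the same positions to "
    "stay disordered; C2 stays within each residue's physicochemical class."
)
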