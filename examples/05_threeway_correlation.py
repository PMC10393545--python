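"""Three-way correlation of relative helix%, abundance and hydrophobicity.

Builds the per-variant measurement table (each column normalised to a
reference variant) and computes the pairwise correlation matrix across
variants, as used to ask whether helix content, protein abundance and
tail hydrophobicity move together along a mutant ladder.
"""

import pandas as pd

from gammatail import Peptide, hydrophobicity_percent, relative_percent, threeway_correlation

# measured helix fractions and abundances for a WT -> M4 ladder (arbitrary units)
helix = {"WT": 0.06, "M1": 0.28, "M3": 0.61, "M4": 0.74}
abundance = {"WT": 1.00, "M1": 0.55, "M3": 0.30, "M4": 0.18}
variants = {
    "WT": Peptide("WT", "MNESSQKTSGS"),
    "M1": Peptide("M1", "MNEASQKTSGS"),
    "M3": Peptide("M3", "MNEASQKEAGS"),
    "M4": Peptide("M4", "MLEASQKEAGS"),
}

table = pd.DataFrame(
    {
        "relative_helix_pct": relative_percent(helix, "M4"),
        "relative_abundance": relative_percent(abundance, "WT"),
        "relative_hydrophobicity_pct": pd.Series(
            {k: hydrophobicity_percent(v, variants["M4"]) for k, v in variants.items()}
        ),
    }
)
print(table.round(1), "\n")
print(threeway_correlation(table).round(3))
print(
    "\nPositive helix/hydrophobicity correlation with negative abundance "
    "correlations indicates that more helical, more hydrophobic tails are "
    "less abundant in the cell."
)
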