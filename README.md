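# gammatail

Tools for studying N-terminal intrinsic disorder in G-protein γ (Gγ)
subunits such as yeast Ste18, whose short disordered N-terminal tail can
be converted, mutation by mutation, into a stable α-helix.  The package
implements the desk-computable stages of that research programme as a
tested, reusable Python library:

- **Peptide structure metrics** — a deterministic Chou–Fasman-style
  secondary-structure predictor (nucleation/extension on published
  helix/sheet propensity scales), windowed disorder profiles on the
  TOP-IDP scale, helix% (Hel%), mutation% (Mut%), N-terminal disorder
  length and relative hydrophobicity% (Kyte–Doolittle).
- **Greedy disorder-to-order design** — the iterative search that, at
  each step, introduces the single substitution (or, once substitutions
  plateau, the single insertion) that most increases predicted helix%,
  producing a minimal WT → M1 → … → M4-style mutant ladder, plus the two
  isometric control sets (disorder-preserving C1, class-preserving
  helix-promoting C2).
- **CD spectral deconvolution** — far-UV circular-dichroism spectra
  modelled as convex mixtures of canonical helix/sheet/coil basis bands
  (positive ~193 nm and negative ~208/222 nm for helix; negative
  ~200 nm for coil); fractions recovered by *exact* simplex-constrained
  least squares (active-set enumeration, no iterative solver).
- **Marginal ancestral sequence reconstruction** — Felsenstein pruning
  plus a downward pass under a reversible amino-acid CTMC (WAG shipped,
  frequencies re-estimable from the alignment), with per-node posterior
  vectors, MAP sequences, and N-terminal disorder lengths exportable as
  annotated Newick.
- **Shmoo morphometry** — the inscribed-circle quantitation of yeast
  mating projections: body circle (largest circle inscribed in the cell
  mask via the Euclidean distance transform), shmoo circle (largest
  circle in the remainder), projection length and width, and circular
  fraction.
- **Synthetic data with ground truth** for every stage, and a thin
  statistics layer (relative normalisation, pairwise correlations).

## The core model in brief

For a peptide of length *L* with secondary-structure string *s* ∈
{H,E,C}^L, Hel% = 100·|{i : sᵢ=H}|/L.  A helix nucleates on any
6-residue window with ≥4 residues of Pα > 1.00 and mean Pα > 1.03, and
extends while the growing end's 4-residue mean Pα ≥ 1.00 (proline stops
N-ward growth); sheets behave analogously on 5-residue windows.  CD
fractions solve min‖y − A·f‖² over the simplex {f ≥ 0, Σf = 1} with A
the H/E/C basis matrix.  Marginal ASR computes, per node v and site,
P(xᵥ = a | leaves) ∝ Lᵥ(a)·Oᵥ(a), the product of inside (pruning) and
outside messages under P(t) = exp(Qt).  Shmoo length runs along the ray
through the body- and shmoo-circle centres, from the body boundary to
the last foreground point on the ray.

## Worked example

`python examples/01_design_helix_path.py` designs a minimal
disorder-to-order ladder for an 11-residue tail:

```
wildtype  MNESSQKTSGS  ss=CCCCCCCCCCC  Hel%=  0.0
M1        MNEASQKTSGS  ss=HHHHHHHHCCC  Hel%= 72.7  Mut%= 9.1  (substitution S4A)
M2        MNEASQKESGS  ss=HHHHHHHHHHC  Hel%= 90.9  Mut%=18.2  (substitution T8E)
M3        MNEASQKEAGS  ss=HHHHHHHHHHH  Hel%=100.0  Mut%=27.3  (substitution S9A)
C1        MNECSQKCAGS  ss=CCCCCCCCCCC  Hel%=  0.0
C2        MNEQSQKQNGS  ss=HHHHHHHHHCC  Hel%= 81.8
```

Three single substitutions take the tail from fully coil to fully
helical; the disorder-preserving control (C1) at the same positions
stays at 0% helix, while the class-preserving control (C2) reaches 82%.
The other examples cover CD deconvolution (`02`), ancestral disorder
mapping (`03`), shmoo morphometry (`04`) and the three-way correlation
of relative helix%, abundance and hydrophobicity (`05`).

A command-line front end mirrors the stages:

```bash
gammatail simulate mask --out mask.txt
gammatail morph mask.txt --out shmoo.csv
gammatail mutpath wt.fasta --out path.csv
gammatail asr alignment.fasta tree.nwk --out lengths.csv
```

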