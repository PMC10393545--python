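# Methods

This note documents the models and procedures implemented in
`gammatail`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Secondary-structure prediction

Neural peptide predictors used in the original experimental workflow
are remote services whose outputs cannot be re-derived from first
principles.  `gammatail` instead implements the classical
nucleation/extension (Chou–Fasman) procedure, which is fully specified
by two published propensity scales shipped as plain-text config
(`helix_chou_fasman.txt`, `sheet_chou_fasman.txt`):

- **Helix nucleation**: any 6-residue window with ≥ 4 residues of
  Pα > 1.00 and window mean Pα > 1.03.  Overlapping nuclei merge.
- **Extension**: a segment grows one residue at a time while the
  4-residue window at the growing end keeps mean Pα ≥ 1.00; proline
  vetoes N-ward growth.
- **Sheet**: the same with 5-residue nucleation windows (≥ 3 residues
  of Pβ > 1.00) and no proline rule.
- **Conflicts**: a residue claimed by both a helix and a sheet segment
  goes to the segment with the larger mean propensity; exact ties go to
  helix.

All thresholds live in `SSParams` and can be changed per call.  The
procedure is deterministic and total on peptides over the 20 canonical
residues; only the *ordinal* behaviour of helix% along a mutant ladder
is promised, not agreement with any particular neural predictor, and
the design search is therefore validated against its own exhaustive
oracle rather than against external predictions.

## Disorder profiles and N-terminal disorder length

Per-residue disorder scores are the TOP-IDP propensity scale, min–max
normalised to [0, 1] using the scale's own extreme values (P at 1,
W at 0), then smoothed by a centred moving average (default window 5,
odd; windows truncate at the termini rather than padding).  The
N-terminal disorder length is the maximal prefix with every score at or
above the threshold (default 0.5).  Different published disorder
predictors disagree by a few residues on real proteins; the windowed
propensity profile is intended to reproduce ordinal contrasts
(disordered prefix vs ordered core), which is what the prefix-recovery
tests exercise.

## Mutation% and relative hydrophobicity%

Mut% = 100 × (#substitutions + #insertions) / mutant length, with the
edit list replayed against the wildtype to guarantee consistency.
Relative hydrophobicity% divides mean Kyte–Doolittle hydropathies after
affine-shifting the scale so its minimum (R, −4.5) maps to 0; without
the shift, means straddle zero and percentages lose meaning.  The shift
convention is this package's own; no standard definition exists for a
"relative hydrophobicity%".  A peptide of all-arginine therefore has a
zero shifted mean and is rejected as a degenerate reference.

## Greedy disorder-to-order design

At each iteration every single-point substitution (19L variants) is
scored; the strict argmax is accepted.  Insertions (20(L+1) variants)
are tried only when substitutions plateau and `allow_insertions` is
set — mirroring a design campaign in which an insertion was needed only
after substitutions alone stopped helping — and the search returns to
substitutions afterwards.  Scores are compared exactly (helix
percentages are rationals #H/L; no epsilon), so a plateau is a true
plateau.  Tie-breaking is lowest position, then alphabetically earliest
target residue; this is a reproducibility convention, not a claim about
which of several equally good paths is "right".  The scorer is probed
twice on the wildtype and must return identical values (scorer
contract).

Isometric controls re-edit exactly the path's positions: C1 chooses,
cumulatively and per position, the residue minimising the scorer
(operationalising "preserve disordered structure" as minimum predicted
helix%, since no metric is standard); C2 chooses the scorer-maximising
residue from the original residue's physicochemical class (partition in
`physchem_classes.txt`: hydrophobic, aromatic, polar-uncharged,
positive, negative, special {C,G,P}; overridable).  For insertion steps
the class of the inserted residue is used, as there is no original
residue at that position.

## CD deconvolution

The three-state basis uses Gaussian components (`cd_basis_bands.txt`):
helix +65 at 193 nm, −32 at 208 nm, −33 at 222 nm; sheet +35 at
196 nm, −22 at 217 nm; coil −42 at 198 nm with a weak +3 band at
220 nm (amplitudes in 10³ deg·cm²·dmol⁻¹; widths 5–12 nm).  Sign
invariants of the canonical band shapes are enforced at construction.
Eight-component deconvolution packages resolve finer sheet taxonomy,
but ranking the helix content of a five-peptide ladder needs only
H/E/C, which is the use case here.

The fit minimises ‖Af − y‖² over the probability simplex.  Because the
problem is 2-dimensional after the sum constraint, the KKT active sets
can be enumerated (7 supports): each support's equality-constrained
solution is computed in closed form and the feasible one with the
smallest objective is returned.  This is exact (machine precision),
deterministic, and verified in tests against a dense simplex
grid-search oracle.  Spectra on other grids are linearly interpolated
onto the basis grid; extrapolation is refused.  A near-collinear basis
triggers a warning and a non-negative least-squares fallback.  For
measured spectra of unknown concentration an optional free positive
amplitude can be co-fitted (`fit_scale=True`, off by default).

## Marginal ancestral reconstruction

The substitution model is a reversible CTMC Q_ij = s_ij·π_j built from
symmetric exchangeabilities and stationary frequencies, normalised to
one expected substitution per site per unit branch length.  WAG is
shipped as the default empirical matrix; π can be replaced by
alignment-derived frequencies (non-gap counts plus a pseudocount),
matching the common "alignment-based background frequencies" usage.  A
single global rate multiplier (default 1.0) is exposed rather than any
bespoke alignment-based rate formula.  P(t) = exp(Qt) via `scipy`
`expm`, clipped and renormalised against round-off.

Reconstruction combines the inside (Felsenstein pruning) pass with an
outside pass computed without divisions: the outside message of a child
is the parent's outside message times the sibling inside messages,
propagated through the child's transition matrix, with the stationary
prior folded in at the root.  Posterior(v, site) ∝ inside × outside,
normalised per site.  Gaps are missing data (all-ones partial
likelihood), not a 21st state; MAP ties break alphabetically.  Internal
nodes without labels get stable preorder names N1, N2, ….
Disorder-length annotation scores leaves on their ungapped alignment
rows and ancestors on their (gap-free) MAP sequences.

Validated invariants: two-leaf posteriors equal direct 20-state
enumeration to 1e-12; posteriors sum to 1 (1e-9); P(0) = I and
Chapman–Kolmogorov to 1e-8; likelihood is invariant to child order.

## Shmoo morphometry

"Largest inscribed circle" is operationalised with the exact Euclidean
distance transform, the frame border counting as background: the centre
is the foreground pixel with maximal EDT (ties: smallest (row, col)),
the radius that EDT value — so a single isolated pixel has radius 1.
The shmoo is the largest inscribed circle of the largest 8-connected
component of the remainder (foreground farther than the body radius
from the body centre); extra components are logged and ignored.

Length: the ray from the body centre through the shmoo centre is
marched at 0.25-px steps with bilinear mask interpolation (inside ⇔
value ≥ 0.5); length = (last inside point) − (body radius), floored at
0.  Coincident centres are flagged degenerate with length 0.  Width:
perpendicular to the axis at its midpoint, marched both ways to the
periphery; undefined when length ≤ 1 px; reported as 1 when only one
crossing exists.  Circular fraction counts foreground pixel centres
within the body radius of the body centre, over all foreground.  Batch
mode analyses each label independently and skips labels under 5 px (a
size filter standing in for manual curation of broken segmentations).
Lengths are in pixels; an optional `pixel_size` rescales them.

## Synthetic data

Generators are pure functions of (parameters, seed) and emit sidecar
ground-truth records.  Shmoo masks are a disc of radius R centred on a
pixel centre plus a capsule whose rounded tip reaches exactly
R + protrusion_length, rasterised by a pixel-centre-in test — so
generated length/width are exact, and measured geometry is accurate to
a few tenths of a pixel.  Real Cellpose masks have rough boundaries and
occasional concavities the generator does not emulate; the random-blob
generator (a union of a disc random walk) covers irregular shapes for
the inscribed-circle oracle tests, but segmentation noise robustness is
not claimed.  CD mixtures add Gaussian noise scaled to the maximum
basis amplitude; real spectra additionally carry baseline drift and
aromatic side-chain contributions that are out of scope.  Sequence
evolution is substitution-only (no indels), so simulated "alignments"
are trivially aligned; disordered-prefix families draw the prefix from
{P,E,K,Q,S} and the core from {W,F,I,L,V}, a sharper contrast than real
Gγ tails exhibit — prefix-recovery results bound what is achievable
under a correct model, not predictor performance on real proteins.

## Problem sizes

Default test and reproduction sizes — 100 random blobs ≤ 48×48 for the
inscribed-circle oracle, an 80-mask geometry grid (body radius 20,
lengths 10–30, widths 5–11, 4 angles), 50 length-≤8 peptides for the
greedy oracle, 200 noisy CD draws, 20 replicate 16-leaf/100-site
reconstructions, 10 disordered families — were chosen so the whole
suite runs in seconds while keeping Monte-Carlo error well below the
tolerances being checked.

## Known limitations

- The structure predictor reproduces qualitative helix ladders, not any
  neural predictor's percentages; no tertiary context is modelled.
- The greedy search is single-edit and myopic by design; it finds *a*
  minimal ladder, not the global optimum over multi-edit sets.
- Three-state CD fitting cannot separate parallel/antiparallel sheet or
  turn content.
- ASR here is marginal (per-site, per-node); joint reconstruction and
  branch-length/rate optimisation are out of scope, and trees must come
  rooted.
- Morphometry assumes one cell per mask with a single dominant
  projection axis; two equal projections yield the larger lobe only.
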