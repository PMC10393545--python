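"""Greedy disorder-to-order sequence design.

Starting from a wildtype peptide tail, the search introduces one edit per
iteration — the single substitution (or, once substitutions plateau, the
single insertion) that most increases a helix-content scorer — and stops
when no single edit strictly improves the score.  This mirrors the
stepwise mutant ladder used to convert an intrinsically disordered
N-terminal tail into a helix while touching as few residues as possible.

Isometric controls re-mutate exactly the same positions, either to
minimise helix content (disorder-preserving controls) or to maximise it
within the wildtype residue's physicochemical class (alternative
helix-promoting controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    InvalidConfigError,
    InvalidInputError,
    NoValidControlError,
    ScorerContractError,
)
from .peptide import AMINO_ACIDS, Peptide
from .seqmetrics import Edit, apply_edits

__all__ = [
    "MutationStep",
    "MutationPath",
    "enumerate_substitutions",
    "enumerate_insertions",
    "greedy_helix_path",
    "isometric_controls",
    "load_physchem_classes",
]

Scorer = Callable[[Peptide], float]


@dataclass(frozen=True)
class MutationStep:
    """One accepted edit plus the resulting peptide and its score."""

    kind: str  # "substitution" | "insertion"
    position: int  # 1-based, in the coordinates of the predecessor sequence
    from_aa: Optional[str]
    to_aa: str
    result: Peptide
    helix_pct: float

    def as_edit(self) -> Edit:
        return Edit(self.kind, self.position, self.from_aa, self.to_aa)


@dataclass(frozen=True)
class MutationPath:
    """An ordered, strictly score-improving ladder of single edits."""

    wildtype: Peptide
    steps: Tuple[MutationStep, ...]

    def __post_init__(self) -> None:
        seq = self.wildtype.sequence
        prev = -float("inf")
        for step in self.steps:
            seq = apply_edits(Peptide("tmp", seq), [step.as_edit()])
            if seq != step.result.sequence:
                raise InvalidInputError(
                    f"step {step} does not replay onto its recorded result"
                )
            if not step.helix_pct > prev:
                raise InvalidInputError("helix_pct must strictly increase along the path")
            if not 0.0 <= step.helix_pct <= 100.0:
                raise InvalidInputError("helix_pct must lie in [0, 100]")
            prev = step.helix_pct

    @property
    def final(self) -> Peptide:
        return self.steps[-1].result if self.steps else self.wildtype

    def edits(self) -> list[Edit]:
        return [s.as_edit() for s in self.steps]


def enumerate_substitutions(peptide: Peptide) -> list[Tuple[int, str, Peptide]]:
    """All 19 x L single-substitution variants, ordered by (position, residue)."""
    out = []
    seq = peptide.sequence
    for pos in range(1, len(seq) + 1):
        wt_aa = seq[pos - 1]
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            variant = seq[: pos - 1] + aa + seq[pos:]
            out.append((pos, aa, peptide.with_sequence(variant, f"{peptide.id}_{wt_aa}{pos}{aa}")))
    return out


def enumerate_insertions(peptide: Peptide) -> list[Tuple[int, str, Peptide]]:
    """All 20 x (L+1) single-insertion variants, ordered by (position, residue)."""
    out = []
    seq = peptide.sequence
    for pos in range(1, len(seq) + 2):
        for aa in AMINO_ACIDS:
            variant = seq[: pos - 1] + aa + seq[pos - 1 :]
            out.append((pos, aa, peptide.with_sequence(variant, f"{peptide.id}_ins{pos}{aa}")))
    return out


def _best(candidates, scorer):
    """Argmax of scorer over (pos, aa, variant) triples.

    Candidates come pre-sorted by (position, residue), so keeping the
    first strict maximum implements the tie-break: lowest position, then
    alphabetically earliest target residue.
    """
    best = None
    best_score = -float("inf")
    for pos, aa, variant in candidates:
        s = float(scorer(variant))
        if s > best_score:
            best, best_score = (pos, aa, variant), s
    return best, best_score


def _checked_scorer(scorer: Scorer, probe: Peptide) -> None:
    a, b = scorer(probe), scorer(probe)
    if a != b:
        raise ScorerContractError(
            f"scorer returned {a} then {b} for the same peptide; it must be deterministic"
        )


def greedy_helix_path(
    wt: Peptide,
    scorer: Scorer,
    max_steps: int = 50,
    allow_insertions: bool = False,
) -> MutationPath:
    """Greedy stepwise maximisation of ``scorer`` by single edits.

    At each iteration every single substitution is scored and the strict
    argmax accepted.  When substitutions plateau and ``allow_insertions``
    is set, single insertions are tried (at most one per plateau event);
    the search then returns to substitutions.  Terminates at a full
    plateau or after ``max_steps`` accepted edits.
    """
    if max_steps < 1:
        raise InvalidInputError("max_steps must be >= 1")
    _checked_scorer(scorer, wt)
    current = wt
    score = float(scorer(wt))
    steps: list[MutationStep] = []
    while len(steps) < max_steps:
        (sub, sub_score) = _best(enumerate_substitutions(current), scorer)
        if sub is not None and sub_score > score:
            pos, aa, variant = sub
            steps.append(
                MutationStep("substitution", pos, current.sequence[pos - 1], aa, variant, sub_score)
            )
            current, score = variant, sub_score
            continue
        if allow_insertions:
            (ins, ins_score) = _best(enumerate_insertions(current), scorer)
            if ins is not None and ins_score > score:
                pos, aa, variant = ins
                steps.append(MutationStep("insertion", pos, None, aa, variant, ins_score))
                current, score = variant, ins_score
                continue
        break
    return MutationPath(wt, tuple(steps))


def load_physchem_classes(path: Union[str, Path, None] = None) -> dict[str, frozenset]:
    """Load the physicochemical partition (class name -> residue set)."""
    if path is None:
        text = resources.files("gammatail.data").joinpath("physchem_classes.txt").read_text()
    else:
        text = Path(path).read_text()
    classes: dict[str, frozenset] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        name, _, members = line.partition("=")
        classes[name.strip()] = frozenset(m.strip() for m in members.split(",") if m.strip())
    covered = frozenset().union(*classes.values()) if classes else frozenset()
    if covered != frozenset(AMINO_ACIDS):
        raise InvalidConfigError(
            f"physicochemical classes must partition the 20 amino acids; covered {sorted(covered)}"
        )
    return classes


def _class_of(aa: str, classes: Mapping[str, frozenset]) -> frozenset:
    for members in classes.values():
        if aa in members:
            return members
    raise InvalidConfigError(f"residue {aa!r} missing from physicochemical classes")


def isometric_controls(
    path: MutationPath,
    scorer: Scorer,
    mode: str,
    classes: Optional[Mapping[str, frozenset]] = None,
) -> Peptide:
    """Build a control peptide mutated at exactly the path's edit positions.

    ``mode="C1"`` picks, position by position, the residue that minimises
    the scorer of the cumulative control sequence (disorder-preserving);
    ``mode="C2"`` picks the scorer-maximising residue drawn from the
    original residue's physicochemical class (helix-promoting but
    class-preserving).  Insertions in the path are mirrored as insertions
    of the chosen control residue.  Ties go to the alphabetically
    earliest residue.
    """
    if mode not in ("C1", "C2"):
        raise InvalidInputError(f"mode must be 'C1' or 'C2', got {mode!r}")
    if not path.steps:
        raise InvalidInputError("path must contain at least one step")
    if classes is None:
        classes = load_physchem_classes()

    seq = path.wildtype.sequence
    for step in path.steps:
        if step.kind == "substitution":
            original = step.from_aa
            pool = sorted(
                (_class_of(original, classes) if mode == "C2" else set(AMINO_ACIDS))
                - {original}
            )
            if not pool:
                raise NoValidControlError(
                    f"no class-mate available for {original!r} at position {step.position}"
                )
        else:  # insertion: mirror with a control residue; class of the inserted one
            pool = sorted(
                _class_of(step.to_aa, classes) if mode == "C2" else set(AMINO_ACIDS)
            )
        i = step.position - 1
        if step.kind == "substitution":
            make = lambda aa: seq[:i] + aa + seq[i + 1 :]
        else:
            make = lambda aa: seq[:i] + aa + seq[i:]
        best_aa, best_score = None, None
        for aa in pool:
            s = float(scorer(Peptide("tmp", make(aa))))
            better = (
                best_score is None
                or (mode == "C1" and s < best_score)
                or (mode == "C2" and s > best_score)
            )
            if better:
                best_aa, best_score = aa, s
        seq = make(best_aa)
    return Peptide(f"{path.wildtype.id}_{mode}", seq)
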