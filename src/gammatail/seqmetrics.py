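"""Per-residue structure and disorder metrics for short peptides.

The module provides a deterministic Chou-Fasman-style secondary-structure
predictor (nucleation + extension on published helix/sheet propensity
scales), a windowed-propensity disorder profiler, and the scalar metrics
built on top of them: helix%, mutation%, N-terminal disorder length and
relative hydrophobicity%.

The predictor is intentionally classical.  Neural peptide predictors give
finer-grained outputs, but they are not reproducible from first
principles; the nucleation/extension rules used here are fully specified
by the shipped propensity scales and the thresholds below, so identical
inputs always give identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateReferenceError, InvalidInputError
from .peptide import AMINO_ACIDS, Peptide
from .scales import PropensityScale, load_builtin

__all__ = [
    "SSParams",
    "DisorderProfile",
    "Edit",
    "predict_ss",
    "helix_percent",
    "mutation_percent",
    "apply_edits",
    "disorder_profile",
    "nterm_disorder_length",
    "mean_hydropathy",
    "hydrophobicity_percent",
]


@dataclass(frozen=True)
class SSParams:
    """Thresholds of the nucleation/extension secondary-structure rules.

    Defaults follow the classical Chou-Fasman prescription: a helix
    nucleates on any 6-residue window in which at least 4 residues have
    P_alpha > 1.00 and the window mean exceeds 1.03; it extends while the
    4-residue mean at the growing end stays >= 1.00, with proline vetoing
    N-ward growth.  Sheets nucleate on 5-residue windows (>= 3 residues
    with P_beta > 1.00) and extend the same way.  Overlapping helix/sheet
    calls go to the segment with the larger mean propensity (ties: helix).
    """

    helix_nucleation_window: int = 6
    helix_nucleation_count: int = 4
    helix_former_threshold: float = 1.00
    helix_nucleation_mean: float = 1.03
    helix_extension_mean: float = 1.00
    sheet_nucleation_window: int = 5
    sheet_nucleation_count: int = 3
    sheet_former_threshold: float = 1.00
    sheet_nucleation_mean: float = 1.03
    sheet_extension_mean: float = 1.00
    extension_window: int = 4


class Edit(NamedTuple):
    """One sequence edit, applied in the coordinates of the current sequence.

    ``position`` is 1-based; for an insertion it is the index the new
    residue occupies after the edit.  ``from_aa`` is ``None`` for
    insertions.
    """

    kind: str  # "substitution" | "insertion"
    position: int
    from_aa: Optional[str]
    to_aa: str


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] plus the calling threshold."""

    scores: Tuple[float, ...]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.scores:
            raise InvalidInputError("disorder profile must be nonempty")
        if not 0.0 < self.threshold < 1.0:
            raise InvalidInputError("threshold must lie strictly inside (0, 1)")
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise InvalidInputError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# secondary structure


def _nucleation_seeds(vals, window, count, former_thr, mean_thr):
    seeds = []
    n = len(vals)
    for i in range(n - window + 1):
        win = vals[i : i + window]
        if sum(v > former_thr for v in win) >= count and float(np.mean(win)) > mean_thr:
            seeds.append((i, i + window - 1))
    return seeds


def _merge(segments):
    merged: list[list[int]] = []
    for s, e in sorted(segments):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _extend(seg, vals, sequence, ext_mean, w, proline_blocks_n):
    s, e = seg
    n = len(vals)
    # C-ward: admit residue e+1 while the trailing w-residue mean stays high
    while e + 1 < n and float(np.mean(vals[e + 2 - w : e + 2])) >= ext_mean:
        e += 1
    # N-ward: symmetric, with optional proline veto
    while s - 1 >= 0 and float(np.mean(vals[s - 1 : s - 1 + w])) >= ext_mean:
        if proline_blocks_n and sequence[s - 1] == "P":
            break
        s -= 1
    return s, e


def _segments(sequence, vals, window, count, former_thr, nuc_mean, ext_mean, ext_w, proline_blocks_n):
    seeds = _nucleation_seeds(vals, window, count, former_thr, nuc_mean)
    extended = [
        _extend(seg, vals, sequence, ext_mean, ext_w, proline_blocks_n) for seg in _merge(seeds)
    ]
    return _merge(extended)


def predict_ss(
    peptide: Peptide,
    p_alpha: Optional[PropensityScale] = None,
    p_beta: Optional[PropensityScale] = None,
    params: SSParams = SSParams(),
) -> str:
    """Assign one of H (helix), E (sheet), C (coil) to every residue.

    Helix and sheet segments are found independently by the
    nucleation/extension rules in ``params``; residues claimed by both are
    resolved in favour of the segment with the larger mean propensity
    (ties go to helix).  Everything else is coil.  The result is a string
    over {H, E, C} of the same length as the peptide.
    """
    if p_alpha is None:
        p_alpha = load_builtin("helix_chou_fasman")
    if p_beta is None:
        p_beta = load_builtin("sheet_chou_fasman")
    seq = peptide.sequence
    a_vals = p_alpha.profile(seq)
    b_vals = p_beta.profile(seq)

    helices = _segments(
        seq, a_vals,
        params.helix_nucleation_window, params.helix_nucleation_count,
        params.helix_former_threshold, params.helix_nucleation_mean,
        params.helix_extension_mean, params.extension_window,
        proline_blocks_n=True,
    )
    sheets = _segments(
        seq, b_vals,
        params.sheet_nucleation_window, params.sheet_nucleation_count,
        params.sheet_former_threshold, params.sheet_nucleation_mean,
        params.sheet_extension_mean, params.extension_window,
        proline_blocks_n=False,
    )

    states = ["C"] * len(seq)
    seg_mean = {}
    for s, e in helices:
        m = float(np.mean(a_vals[s : e + 1]))
        for i in range(s, e + 1):
            states[i] = "H"
            seg_mean[i] = m
    for s, e in sheets:
        m = float(np.mean(b_vals[s : e + 1]))
        for i in range(s, e + 1):
            if states[i] == "H" and seg_mean[i] >= m:
                continue  # helix keeps ties
            states[i] = "E"
    return "".join(states)


def helix_percent(ss: str) -> float:
    """Percentage of residues in the H state: 100 x #H / length."""
    if not ss:
        raise InvalidInputError("secondary-structure string must be nonempty")
    bad = set(ss) - set("HEC")
    if bad:
        raise InvalidInputError(f"states must be in {{H,E,C}}; got {sorted(bad)}")
    return 100.0 * ss.count("H") / len(ss)


# ---------------------------------------------------------------------------
# edits and mutation%


def apply_edits(wt: Peptide, edits: Sequence[Edit]) -> str:
    """Replay ``edits`` (in order) on the wildtype sequence."""
    seq = wt.sequence
    for ed in edits:
        i = ed.position - 1
        if ed.kind == "substitution":
            if not 0 <= i < len(seq) or seq[i] != ed.from_aa:
                raise InvalidInputError(
                    f"substitution {ed} does not match sequence {seq!r}"
                )
            seq = seq[:i] + ed.to_aa + seq[i + 1 :]
        elif ed.kind == "insertion":
            if not 0 <= i <= len(seq):
                raise InvalidInputError(f"insertion {ed} out of range for {seq!r}")
            seq = seq[:i] + ed.to_aa + seq[i:]
        else:
            raise InvalidInputError(f"unknown edit kind {ed.kind!r}")
    return seq


def mutation_percent(wt: Peptide, mutant: Peptide, edits: Sequence[Edit]) -> float:
    """Mut% = 100 x (#substitutions + #insertions) / mutant length.

    The edit list must map ``wt`` to ``mutant`` exactly when replayed.
    """
    replayed = apply_edits(wt, edits)
    if replayed != mutant.sequence:
        raise InvalidInputError(
            f"edit list replays to {replayed!r}, not to mutant {mutant.sequence!r}"
        )
    return 100.0 * len(edits) / len(mutant.sequence)


# ---------------------------------------------------------------------------
# disorder


def disorder_profile(
    peptide: Peptide,
    scale: Optional[PropensityScale] = None,
    window: int = 5,
    threshold: float = 0.5,
) -> DisorderProfile:
    """Windowed disorder propensity, min-max mapped onto [0, 1].

    Raw per-residue values are first normalised with the scale's fixed
    bounds, then averaged over a centred ``window`` (odd); windows are
    truncated (shrunken), not padded, at the termini.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidInputError(f"window must be a positive odd integer, got {window}")
    if scale is None:
        scale = load_builtin("disorder_top_idp")
    vals = np.array([scale.normalized(aa) for aa in peptide.sequence])
    half = window // 2
    n = len(vals)
    scores = tuple(
        float(np.mean(vals[max(0, i - half) : min(n, i + half + 1)])) for i in range(n)
    )
    return DisorderProfile(scores, threshold)


def nterm_disorder_length(profile: DisorderProfile) -> int:
    """Length of the maximal disordered prefix (scores >= threshold)."""
    n = 0
    for s in profile.scores:
        if s >= profile.threshold:
            n += 1
        else:
            break
    return n


# ---------------------------------------------------------------------------
# hydrophobicity


def mean_hydropathy(peptide: Peptide, scale: Optional[PropensityScale] = None) -> float:
    """Mean raw hydropathy of the peptide under ``scale``."""
    if scale is None:
        scale = load_builtin("hydropathy_kyte_doolittle")
    return float(np.mean(scale.profile(peptide.sequence)))


def hydrophobicity_percent(
    peptide: Peptide,
    reference: Peptide,
    scale: Optional[PropensityScale] = None,
) -> float:
    """Relative hydrophobicity%: peptide vs reference, reference = 100.

    The hydropathy scale is affine-shifted so its minimum is zero before
    the ratio is taken; without the shift, mean hydropathies can straddle
    zero and the ratio loses meaning.
    """
    if scale is None:
        scale = load_builtin("hydropathy_kyte_doolittle")
    shift = -scale.lower
    pep = mean_hydropathy(peptide, scale) + shift
    ref = mean_hydropathy(reference, scale) + shift
    if ref == 0.0:
        raise DegenerateReferenceError(
            "reference peptide has zero shifted mean hydropathy"
        )
    return 100.0 * pep / ref
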