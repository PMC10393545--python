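"""Synthetic inputs with known ground truth for every pipeline stage.

Generators here are pure functions of (parameters, seed): shmoo-shaped
cell masks (disc body + capsule protrusion), noisy convex mixtures of CD
basis bands, sequences evolved along a tree under a substitution model,
disordered-prefix peptide families, random peptides and correlated
tables.  Each generator returns a :class:`SimulationRecord` carrying the
seed, the echoed parameters and the latent truth, so recovery tests
never have to re-derive what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
import pandas as pd

from .asr import GAP, SubstitutionModel, node_label, transition_matrix, _AA_INDEX
from .cdspec import BasisSet, CDSpectrum, StructureFractions
from .errors import InvalidConfigError, InvalidInputError
from .peptide import AMINO_ACIDS, Peptide

__all__ = [
    "ShmooGroundTruth",
    "SimulationRecord",
    "make_shmoo_mask",
    "random_blob_mask",
    "simulate_cd_spectrum",
    "evolve_sequences",
    "make_disordered_family",
    "random_peptide",
    "make_correlated_table",
]

#: Residues favoured in designed disordered prefixes (high disorder propensity).
DISORDER_POOL = "PEKQS"
#: Residues favoured in designed ordered cores (low disorder propensity).
ORDER_POOL = "WFILV"


@dataclass(frozen=True)
class ShmooGroundTruth:
    """Generating geometry of a synthetic shmoo mask.

    ``protrusion_length`` is measured beyond the body-disc boundary along
    the protrusion axis; ``angle`` is measured from the +column axis
    toward +row.  The capsule tip is rounded but reaches exactly
    ``body_radius + protrusion_length`` from the disc centre.
    """

    body_radius: float
    protrusion_length: float
    protrusion_width: float
    angle: float = 0.0
    grid_size: int = 96

    def __post_init__(self) -> None:
        if self.body_radius <= 0 or self.protrusion_length < 0 or self.protrusion_width <= 0:
            raise InvalidConfigError("radii, lengths and widths must be positive")
        if self.protrusion_width >= 2.0 * self.body_radius:
            raise InvalidConfigError("protrusion width must be < body diameter")
        reach = self.body_radius + self.protrusion_length
        if reach + 2.0 > self.grid_size / 2.0:
            raise InvalidConfigError(
                f"geometry (reach {reach:.1f}px) exceeds the grid with a 2-px margin"
            )


@dataclass(frozen=True)
class SimulationRecord:
    """Seed + parameters + latent truth of one generator call."""

    seed: Optional[int]
    parameters: Mapping[str, object]
    truth: Mapping[str, object]

    def write_sidecar(self, path: Union[str, Path]) -> None:
        """Write a flat ``key=value`` ground-truth record."""
        lines = [f"seed={self.seed}"]
        for scope, mapping in (("param", self.parameters), ("truth", self.truth)):
            for key, value in mapping.items():
                lines.append(f"{scope}.{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# masks


def make_shmoo_mask(gt: ShmooGroundTruth) -> tuple[np.ndarray, SimulationRecord]:
    """Rasterise a disc-plus-capsule cell: pixel centre-in test, 0/1 grid."""
    n = gt.grid_size
    c = float((n - 1) // 2)  # on a pixel centre, so the body circle is exact
    rows, cols = np.indices((n, n), dtype=float)
    in_disc = np.hypot(rows - c, cols - c) <= gt.body_radius

    ur, uc = np.sin(gt.angle), np.cos(gt.angle)
    half_w = gt.protrusion_width / 2.0
    seg_len = max(0.0, gt.body_radius + gt.protrusion_length - half_w)
    # distance from each pixel centre to the axis segment [centre, centre + seg_len*u]
    t = np.clip((rows - c) * ur + (cols - c) * uc, 0.0, seg_len)
    d = np.hypot(rows - (c + t * ur), cols - (c + t * uc))
    in_capsule = (d <= half_w) if gt.protrusion_length > 0 else np.zeros_like(in_disc)

    mask = in_disc | in_capsule
    record = SimulationRecord(
        seed=None,
        parameters={
            "body_radius": gt.body_radius,
            "protrusion_length": gt.protrusion_length,
            "protrusion_width": gt.protrusion_width,
            "angle": gt.angle,
            "grid_size": gt.grid_size,
        },
        truth={
            "center_row": c,
            "center_col": c,
            "length": gt.protrusion_length,
            "width": gt.protrusion_width,
            "disc_area": float(np.pi * gt.body_radius**2),
            "foreground_area": int(mask.sum()),
        },
    )
    return mask, record


def random_blob_mask(size: int, seed: int, n_discs: int = 4) -> np.ndarray:
    """A random connected blob: union of a short random walk of discs.

    Useful as an adversarial but realistic mask for geometry tests; the
    result is guaranteed 8-connected and clear of the frame border.
    """
    if size < 12:
        raise InvalidInputError("size must be >= 12")
    rng = np.random.default_rng(seed)
    rows, cols = np.indices((size, size), dtype=float)
    mask = np.zeros((size, size), dtype=bool)
    r, c = size / 2.0, size / 2.0
    for _ in range(n_discs):
        radius = rng.uniform(2.5, size / 5.0)
        r = float(np.clip(r + rng.uniform(-radius, radius), radius + 1, size - radius - 2))
        c = float(np.clip(c + rng.uniform(-radius, radius), radius + 1, size - radius - 2))
        mask |= np.hypot(rows - r, cols - c) <= radius
    return mask


# ---------------------------------------------------------------------------
# CD spectra


def simulate_cd_spectrum(
    fractions: StructureFractions,
    basis: BasisSet,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[CDSpectrum, SimulationRecord]:
    """Convex mixture of the basis bands plus additive Gaussian noise.

    The noise standard deviation is ``noise_sd`` times the maximum
    absolute basis amplitude, so ``noise_sd=0.05`` means 5%-of-max noise.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    A = basis.matrix()
    y = A @ fractions.as_array()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * np.abs(A).max(), size=y.shape)
    spec = CDSpectrum(basis.grid.copy(), y)
    record = SimulationRecord(
        seed=seed,
        parameters={"noise_sd": noise_sd},
        truth={"fH": fractions.fH, "fE": fractions.fE, "fC": fractions.fC},
    )
    return spec, record


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequences(
    tree: dendropy.Tree,
    root: Peptide,
    model: SubstitutionModel,
    seed: Optional[int] = None,
) -> tuple[dict[str, str], SimulationRecord]:
    """Evolve ``root`` down the tree by per-branch CTMC sampling.

    Each site evolves independently; along every branch the child state
    is drawn from the row of P(branch length) for the parent state.
    Returns the leaf alignment (no indels, so it is trivially aligned)
    and a record holding the true sequence of every node.
    """
    rng = np.random.default_rng(seed)
    n_sites = len(root)
    states: dict[dendropy.Node, np.ndarray] = {}
    root_idx = np.array([_AA_INDEX[aa] for aa in root.sequence])
    truth: dict[str, str] = {}
    leaves: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            states[nd] = root_idx
        else:
            P = transition_matrix(model, nd.edge.length)
            parent = states[nd.parent_node]
            u = rng.random(n_sites)
            cdf = np.cumsum(P[parent], axis=1)
            states[nd] = np.minimum((u[:, None] > cdf).sum(axis=1), 19)
        seq = "".join(AMINO_ACIDS[i] for i in states[nd])
        truth[node_label(nd)] = seq
        if nd.is_leaf():
            leaves[nd.taxon.label] = seq
    record = SimulationRecord(
        seed=seed,
        parameters={"n_sites": n_sites, "rate": model.rate},
        truth=truth,
    )
    return leaves, record


def make_disordered_family(
    tree: dendropy.Tree,
    prefix_len: int,
    core_len: int,
    model: SubstitutionModel,
    seed: Optional[int] = None,
) -> tuple[dict[str, str], SimulationRecord]:
    """A peptide family with a designed disordered N-terminal prefix.

    The root is a prefix drawn from disorder-promoting residues
    (:data:`DISORDER_POOL`) followed by a core of order-promoting ones
    (:data:`ORDER_POOL`), then evolved along the tree.  The record's
    truth holds the designed ``prefix_len`` and every true node sequence.
    """
    if prefix_len < 0 or core_len < 1:
        raise InvalidInputError("need prefix_len >= 0 and core_len >= 1")
    rng = np.random.default_rng(seed)
    prefix = "".join(rng.choice(list(DISORDER_POOL), size=prefix_len))
    core = "".join(rng.choice(list(ORDER_POOL), size=core_len))
    root = Peptide("root", prefix + core)
    leaves, evo = evolve_sequences(tree, root, model, seed=int(rng.integers(2**31)))
    truth = dict(evo.truth)
    truth["prefix_len"] = prefix_len
    truth["root_sequence"] = root.sequence
    record = SimulationRecord(
        seed=seed,
        parameters={"prefix_len": prefix_len, "core_len": core_len, "rate": model.rate},
        truth=truth,
    )
    return leaves, record


# ---------------------------------------------------------------------------
# peptides and tables


def random_peptide(
    length: int,
    composition: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> Peptide:
    """Sample a peptide i.i.d. from ``composition`` (default uniform)."""
    if length < 1:
        raise InvalidInputError("length must be >= 1")
    if composition is None:
        weights = np.full(20, 1.0)
    else:
        if any(w < 0 for w in composition.values()):
            raise InvalidInputError("composition weights must be nonnegative")
        weights = np.array([composition.get(aa, 0.0) for aa in AMINO_ACIDS])
        if weights.sum() <= 0:
            raise InvalidInputError("composition weights sum to zero")
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=p))
    return Peptide(f"random_{seed}", seq)


def make_correlated_table(
    n: int,
    target_r: float,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, SimulationRecord]:
    """Two columns drawn from a bivariate normal with correlation ``target_r``.

    ``|target_r| = 1`` degenerates to an exact linear construction.
    """
    if not -1.0 <= target_r <= 1.0:
        raise InvalidInputError("target_r must lie in [-1, 1]")
    if n < 3:
        raise InvalidInputError("n must be >= 3")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if abs(target_r) == 1.0:
        y = np.sign(target_r) * x
    else:
        z = rng.standard_normal(n)
        y = target_r * x + np.sqrt(1.0 - target_r**2) * z
    df = pd.DataFrame({"x": x, "y": y})
    record = SimulationRecord(seed=seed, parameters={"n": n}, truth={"r": target_r})
    return df, record
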