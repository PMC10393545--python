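"""Marginal ancestral sequence reconstruction on rooted trees.

Implements the standard machinery: a reversible amino-acid CTMC built
from symmetric exchangeabilities and stationary frequencies (WAG shipped
as the default, frequencies optionally re-estimated from the alignment),
Felsenstein pruning for the upward pass, a downward ("outside") pass, and
per-node per-site marginal posteriors over the 20 residues.  Gap
characters are treated as missing data (an all-ones partial likelihood),
not as a 21st state.

Trees are handled through :mod:`dendropy`; node annotations written as
``[&key=value]`` Newick comments survive a write/read round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.linalg import expm

from .errors import InvalidConfigError, InvalidInputError
from .peptide import AMINO_ACIDS, Peptide
from .scales import PropensityScale
from .seqmetrics import disorder_profile, nterm_disorder_length

__all__ = [
    "SubstitutionModel",
    "AncestralReconstruction",
    "read_newick",
    "write_newick",
    "read_alignment_fasta",
    "estimate_frequencies",
    "transition_matrix",
    "marginal_asr",
    "annotate_disorder_lengths",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"


# ---------------------------------------------------------------------------
# substitution model


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid CTMC: Q_ij = s_ij * pi_j (i != j).

    ``exchangeabilities`` is symmetric with zero diagonal, ``pi`` a
    distribution over :data:`~gammatail.peptide.AMINO_ACIDS` (alphabetical
    order), ``rate`` a global branch-length multiplier.  The generator is
    normalised to one expected substitution per site per unit time.
    """

    exchangeabilities: np.ndarray
    pi: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "pi", pi)
        if S.shape != (20, 20) or not np.allclose(S, S.T) or np.any(S < 0):
            raise InvalidConfigError("exchangeabilities must be a symmetric nonnegative 20x20 matrix")
        if np.any(np.diag(S) != 0):
            raise InvalidConfigError("exchangeability diagonal must be zero")
        if pi.shape != (20,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("pi must be a length-20 distribution")
        if self.rate <= 0:
            raise InvalidConfigError("rate must be positive")

    @property
    def Q(self) -> np.ndarray:
        """Normalised rate matrix (rows sum to zero, mean rate 1)."""
        Q = self.exchangeabilities * self.pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(self.pi @ np.diag(Q))
        return Q / mean_rate

    @classmethod
    def wag(cls, pi: Optional[np.ndarray] = None, rate: float = 1.0) -> "SubstitutionModel":
        """The WAG model; pass ``pi`` to replace its stationary frequencies
        with alignment-derived ones (see :func:`estimate_frequencies`)."""
        S, wag_pi = _load_wag()
        return cls(S, wag_pi if pi is None else np.asarray(pi, dtype=float), rate)

    @classmethod
    def poisson(cls, pi: Optional[np.ndarray] = None, rate: float = 1.0) -> "SubstitutionModel":
        """Equal-exchangeability (F81-style) model, mainly for testing."""
        S = np.ones((20, 20)) - np.eye(20)
        if pi is None:
            pi = np.full(20, 0.05)
        return cls(S, np.asarray(pi, dtype=float), rate)


def _load_wag() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("gammatail.data").joinpath("wag_exchangeabilities.txt").read_text()
    S = np.zeros((20, 20))
    pi = np.zeros(20)
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "pair":
            i, j = _AA_INDEX[parts[1]], _AA_INDEX[parts[2]]
            S[i, j] = S[j, i] = float(parts[3])
        elif parts[0] == "freq":
            pi[_AA_INDEX[parts[1]]] = float(parts[2])
        else:
            raise InvalidConfigError(f"bad line in WAG data: {raw!r}")
    pi = pi / pi.sum()
    return S, pi


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = expm(Q * rate * t); rows are probability distributions."""
    if t < 0:
        raise InvalidInputError(f"branch length must be nonnegative, got {t}")
    if t == 0:
        return np.eye(20)
    P = expm(model.Q * model.rate * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# alignment I/O and frequencies


def read_alignment_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a pre-aligned FASTA into a label -> gapped-sequence map."""
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    _validate_alignment(aln)
    return aln


def _validate_alignment(aln: Mapping[str, str]) -> None:
    if not aln:
        raise InvalidInputError("alignment is empty")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise InvalidInputError(f"alignment rows differ in length: {sorted(lengths)}")
    ok = set(AMINO_ACIDS) | {GAP}
    for label, seq in aln.items():
        bad = set(seq) - ok
        if bad:
            raise InvalidInputError(f"row {label!r} contains invalid characters {sorted(bad)}")


def estimate_frequencies(aln: Mapping[str, str], pseudocount: float = 0.0) -> np.ndarray:
    """Background residue frequencies: normalised non-gap counts + pseudocount."""
    _validate_alignment(aln)
    if pseudocount < 0:
        raise InvalidInputError("pseudocount must be nonnegative")
    counts = np.full(20, pseudocount, dtype=float)
    for seq in aln.values():
        for aa in seq:
            if aa != GAP:
                counts[_AA_INDEX[aa]] += 1.0
    total = counts.sum()
    if total == 0:
        raise InvalidInputError("all-gap alignment with zero pseudocount")
    return counts / total


# ---------------------------------------------------------------------------
# tree I/O


def read_newick(source: Union[str, Path]) -> dendropy.Tree:
    """Parse a rooted Newick tree (string or file path) with branch lengths.

    Every non-root edge must carry a branch length; leaf labels must be
    unique.  ``[&key=value]`` comments are parsed into node annotations.
    """
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if not text.strip():
        raise InvalidInputError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise InvalidInputError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise InvalidInputError("duplicate leaf labels in Newick input")
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None:
            raise InvalidInputError(
                f"missing branch length on edge above {node_label(nd)!r}"
            )
        if nd.edge.length < 0 or not np.isfinite(nd.edge.length):
            raise InvalidInputError("branch lengths must be finite and nonnegative")
    _assign_internal_labels(tree)
    return tree


def node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "?"


def _assign_internal_labels(tree: dendropy.Tree) -> None:
    """Give every unlabeled internal node a stable preorder label N1, N2, ..."""
    taken = {node_label(nd) for nd in tree if node_label(nd) != "?"}
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.taxon is None and not nd.label:
            k += 1
            while f"N{k}" in taken:
                k += 1
            nd.label = f"N{k}"


def write_newick(
    tree: dendropy.Tree,
    node_annotations: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> str:
    """Serialise with optional per-node annotations as ``[&k=v]`` comments."""
    if node_annotations:
        for nd in tree:
            ann = node_annotations.get(node_label(nd))
            if ann:
                for key, value in ann.items():
                    nd.annotations.drop(name=key)
                    nd.annotations.add_new(key, value)
    return tree.as_string(schema="newick", suppress_annotations=False, suppress_rooting=True)


# ---------------------------------------------------------------------------
# marginal reconstruction


@dataclass(frozen=True)
class AncestralReconstruction:
    """Per-node marginal posteriors and MAP sequences.

    ``posteriors`` maps node label -> array of shape (n_sites, 20) in
    alphabetical residue order; ``map_sequences`` maps node label -> the
    per-site argmax sequence (alphabetically earliest residue on exact
    posterior ties).  ``log_likelihood`` is the total tree log-likelihood
    from the pruning pass.
    """

    posteriors: Mapping[str, np.ndarray]
    map_sequences: Mapping[str, str]
    log_likelihood: float

    def __post_init__(self) -> None:
        for label, post in self.posteriors.items():
            if not np.allclose(post.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidInputError(f"posteriors at {label!r} do not sum to 1")


def _leaf_partials(seq: str, n_sites: int) -> np.ndarray:
    L = np.zeros((n_sites, 20))
    for s, aa in enumerate(seq):
        if aa == GAP:
            L[s, :] = 1.0  # missing data
        else:
            L[s, _AA_INDEX[aa]] = 1.0
    return L


def marginal_asr(
    tree: dendropy.Tree,
    aln: Mapping[str, str],
    model: SubstitutionModel,
) -> AncestralReconstruction:
    """Marginal posteriors at every node by an upward + downward pass.

    Upward: Felsenstein pruning gives, per node x state, the likelihood
    of the data below it.  Downward: an outside message carries the
    likelihood of everything else (prior folded in at the root).  Their
    product, normalised per site, is the marginal posterior.
    """
    _validate_alignment(aln)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(aln):
        raise InvalidInputError(
            f"tree/alignment label mismatch: only-in-tree {sorted(leaf_labels - set(aln))}, "
            f"only-in-alignment {sorted(set(aln) - leaf_labels)}"
        )
    n_sites = len(next(iter(aln.values())))
    _assign_internal_labels(tree)

    P = {}  # node -> transition matrix of its parent edge
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            P[nd] = transition_matrix(model, nd.edge.length)

    up: dict[dendropy.Node, np.ndarray] = {}
    upmsg: dict[dendropy.Node, np.ndarray] = {}  # P @ up, per child
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            up[nd] = _leaf_partials(aln[nd.taxon.label], n_sites)
        else:
            prod = np.ones((n_sites, 20))
            for ch in nd.child_nodes():
                upmsg[ch] = up[ch] @ P[ch].T  # sum_y P[x,y] L_ch(y)
                prod *= upmsg[ch]
            up[nd] = prod

    root = tree.seed_node
    site_lik = up[root] @ model.pi
    if np.any(site_lik <= 0):
        raise InvalidInputError("zero site likelihood; check model and data")
    log_likelihood = float(np.log(site_lik).sum())

    # downward/outside pass: out[nd][s, x] = likelihood of everything outside
    # the clade of nd, given state x at nd, with the root prior folded in
    out: dict[dendropy.Node, np.ndarray] = {root: np.tile(model.pi, (n_sites, 1))}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            rest = out[nd].copy()
            for sib in nd.child_nodes():
                if sib is not ch:
                    rest *= upmsg[sib]
            out[ch] = rest @ P[ch]  # sum_x rest(x) P[x,y]

    posteriors: dict[str, np.ndarray] = {}
    map_sequences: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        joint = up[nd] * out[nd]
        post = joint / joint.sum(axis=1, keepdims=True)
        label = node_label(nd)
        posteriors[label] = post
        map_sequences[label] = "".join(AMINO_ACIDS[i] for i in np.argmax(post, axis=1))
    return AncestralReconstruction(posteriors, map_sequences, log_likelihood)


def annotate_disorder_lengths(
    tree: dendropy.Tree,
    rec: AncestralReconstruction,
    aln: Mapping[str, str],
    scale: Optional[PropensityScale] = None,
    window: int = 5,
    threshold: float = 0.5,
) -> dict[str, int]:
    """N-terminal disorder length for every node (leaves and ancestors).

    Leaves are scored on their ungapped alignment rows; internal nodes on
    their MAP sequences.  Returns a node-label -> length map suitable for
    :func:`write_newick` annotation export.
    """
    import warnings as _warnings

    lengths: dict[str, int] = {}
    for nd in tree.preorder_node_iter():
        label = node_label(nd)
        seq = aln[label] if nd.is_leaf() else rec.map_sequences[label]
        ungapped = seq.replace(GAP, "")
        if not ungapped:
            _warnings.warn(f"node {label!r} has an empty ungapped sequence", RuntimeWarning)
            lengths[label] = 0
            continue
        prof = disorder_profile(Peptide(label, ungapped), scale, window, threshold)
        lengths[label] = nterm_disorder_length(prof)
    return lengths
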