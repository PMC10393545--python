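"""Residue propensity scales and their plain-text configuration format.

Every per-residue lookup table the package uses — Chou-Fasman helix and
sheet propensities, the Kyte-Doolittle hydropathy index, the TOP-IDP
disorder propensity scale — is a :class:`PropensityScale` loaded from a
``key=value`` text file (one amino acid per line).  Nothing numeric is
hard-coded in the scoring operations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Tuple, Union

import math

from .errors import InvalidConfigError
from .peptide import AMINO_ACIDS

#: Names of the scales shipped with the package.
BUILTIN_SCALES = (
    "helix_chou_fasman",
    "sheet_chou_fasman",
    "hydropathy_kyte_doolittle",
    "disorder_top_idp",
)


@dataclass(frozen=True)
class PropensityScale:
    """A named map from each of the 20 amino acids to a real number.

    ``bounds`` are the fixed lower/upper values used when the scale is
    min-max normalised (e.g. for disorder profiles); they default to the
    scale's own extreme values.
    """

    name: str
    values: Mapping[str, float]
    bounds: Optional[Tuple[float, float]] = field(default=None)

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise InvalidConfigError(
                f"scale {self.name!r} must cover exactly the 20 canonical "
                f"amino acids (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise InvalidConfigError(f"scale {self.name!r} has non-finite entries")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise InvalidConfigError(f"invalid bounds {self.bounds} for {self.name!r}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    @property
    def lower(self) -> float:
        return self.bounds[0] if self.bounds is not None else min(self.values.values())

    @property
    def upper(self) -> float:
        return self.bounds[1] if self.bounds is not None else max(self.values.values())

    def normalized(self, aa: str) -> float:
        """Value of ``aa`` min-max mapped onto [0, 1] using the scale bounds."""
        return (self.values[aa] - self.lower) / (self.upper - self.lower)

    def profile(self, sequence: str) -> list[float]:
        """Raw per-residue values for ``sequence``."""
        return [self.values[aa] for aa in sequence]


def parse_scale(text: str, name: str, bounds: Optional[Tuple[float, float]] = None) -> PropensityScale:
    """Parse a ``key=value`` scale definition (``#`` starts a comment)."""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidConfigError(f"{name}: line {lineno} is not 'AA=value': {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key in values:
            raise InvalidConfigError(f"{name}: duplicate entry for {key!r}")
        try:
            values[key] = float(val)
        except ValueError as exc:
            raise InvalidConfigError(f"{name}: bad number on line {lineno}: {raw!r}") from exc
    return PropensityScale(name, values, bounds)


def load_scale(path: Union[str, Path], bounds: Optional[Tuple[float, float]] = None) -> PropensityScale:
    """Load a scale from a ``key=value`` config file."""
    path = Path(path)
    return parse_scale(path.read_text(), path.stem, bounds)


def load_builtin(name: str) -> PropensityScale:
    """Load one of the scales shipped in :mod:`gammatail.data`."""
    if name not in BUILTIN_SCALES:
        raise InvalidConfigError(f"unknown builtin scale {name!r}; choose from {BUILTIN_SCALES}")
    text = resources.files("gammatail.data").joinpath(f"{name}.txt").read_text()
    return parse_scale(text, name)
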