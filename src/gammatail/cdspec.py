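"""Far-UV CD spectra as convex mixtures of canonical basis bands.

A measured circular-dichroism spectrum of a peptide is modelled as

    y(lambda) = fH * H(lambda) + fE * E(lambda) + fC * C(lambda) + noise

where H, E and C are canonical alpha-helix, beta-sheet and random-coil
band shapes (sums of Gaussian components, all parameters in plain-text
config) and the fractions (fH, fE, fC) live on the probability simplex.
Fractions are recovered by exact simplex-constrained least squares:
with only three states the KKT conditions can be solved by enumerating
the active sets, so the minimiser is found in closed form rather than
iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DegenerateReferenceError, InvalidConfigError, InvalidInputError

__all__ = [
    "CDSpectrum",
    "BasisSet",
    "StructureFractions",
    "load_band_params",
    "make_basis",
    "fit_fractions",
    "relative_helix_percent",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

STATES = ("H", "E", "C")
WAVELENGTH_RANGE = (190.0, 250.0)


@dataclass(frozen=True)
class CDSpectrum:
    """Wavelength (nm) / mean-residue-ellipticity table."""

    wavelengths: np.ndarray
    ellipticities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticities", el)
        if wl.ndim != 1 or el.ndim != 1 or wl.size != el.size or wl.size == 0:
            raise InvalidInputError("wavelengths/ellipticities must be equal-length 1-D arrays")
        if not (np.all(np.diff(wl) > 0)):
            raise InvalidInputError("wavelengths must be strictly increasing")
        lo, hi = WAVELENGTH_RANGE
        if wl[0] < lo or wl[-1] > hi:
            raise InvalidInputError(f"wavelengths must lie within [{lo}, {hi}] nm")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(el))):
            raise InvalidInputError("spectrum contains non-finite values")


@dataclass(frozen=True)
class BasisSet:
    """H/E/C band shapes evaluated on a shared wavelength grid."""

    grid: np.ndarray
    bands: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if set(self.bands) != set(STATES):
            raise InvalidConfigError(f"basis must define exactly the bands {STATES}")
        for k, v in self.bands.items():
            if np.asarray(v).shape != grid.shape:
                raise InvalidConfigError(f"band {k} not on the shared grid")
        self._check_signs()

    def _value_at(self, state: str, wavelength: float) -> Optional[float]:
        grid = self.grid
        if wavelength < grid[0] or wavelength > grid[-1]:
            return None
        return float(np.interp(wavelength, grid, np.asarray(self.bands[state], dtype=float)))

    def _check_signs(self) -> None:
        # canonical far-UV signatures: helix +193 / -208 / -222; coil -200
        checks = [("H", 193.0, +1), ("H", 208.0, -1), ("H", 222.0, -1), ("C", 200.0, -1)]
        for state, wl, sign in checks:
            v = self._value_at(state, wl)
            if v is not None and v * sign <= 0:
                raise InvalidConfigError(
                    f"{state} band has the wrong sign at {wl} nm ({v:+.3g})"
                )

    def matrix(self) -> np.ndarray:
        """(n_wavelengths, 3) design matrix in state order H, E, C."""
        return np.column_stack([np.asarray(self.bands[s], dtype=float) for s in STATES])


@dataclass(frozen=True)
class StructureFractions:
    """Point on the H/E/C probability simplex."""

    fH: float
    fE: float
    fC: float

    def __post_init__(self) -> None:
        arr = np.array([self.fH, self.fE, self.fC], dtype=float)
        if np.any(arr < -1e-12):
            raise InvalidInputError(f"fractions must be nonnegative, got {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise InvalidInputError(f"fractions must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.fH, self.fE, self.fC], dtype=float)


def load_band_params(path: Union[str, Path, None] = None) -> dict[str, list[tuple[float, float, float]]]:
    """Read Gaussian band components: lines of ``state center width amplitude``."""
    if path is None:
        text = resources.files("gammatail.data").joinpath("cd_basis_bands.txt").read_text()
    else:
        text = Path(path).read_text()
    params: dict[str, list[tuple[float, float, float]]] = {s: [] for s in STATES}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4 or parts[0] not in STATES:
            raise InvalidConfigError(f"bad band line {lineno}: {raw!r}")
        state, center, width, amp = parts[0], float(parts[1]), float(parts[2]), float(parts[3])
        if width <= 0:
            raise InvalidConfigError(f"nonpositive width on line {lineno}")
        params[state].append((center, width, amp))
    if any(not v for v in params.values()):
        raise InvalidConfigError("every state (H, E, C) needs at least one component")
    return params


def make_basis(
    grid: Sequence[float],
    band_params: Optional[Mapping[str, Sequence[tuple[float, float, float]]]] = None,
) -> BasisSet:
    """Evaluate the Gaussian-component bands on ``grid``.

    Each band is ``sum_k amp_k * exp(-(wl - center_k)^2 / (2 width_k^2))``.
    Sign constraints of the canonical band shapes are enforced by the
    :class:`BasisSet` constructor.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise InvalidInputError("grid must be a strictly increasing 1-D array")
    lo, hi = WAVELENGTH_RANGE
    if grid[0] < lo or grid[-1] > hi:
        raise InvalidInputError(f"grid must lie within [{lo}, {hi}] nm")
    if band_params is None:
        band_params = load_band_params()
    bands = {}
    for state in STATES:
        y = np.zeros_like(grid)
        for center, width, amp in band_params[state]:
            y = y + amp * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
        bands[state] = y
    return BasisSet(grid, bands)


def _solve_affine(G: np.ndarray, b: np.ndarray, idx: tuple[int, ...]) -> Optional[np.ndarray]:
    """Minimise f'Gf - 2b'f subject to sum(f)=1, f=0 off ``idx`` (KKT system)."""
    k = len(idx)
    Gs = G[np.ix_(idx, idx)]
    bs = b[list(idx)]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * Gs
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * bs, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        return None
    f = np.zeros(3)
    f[list(idx)] = sol[:k]
    return f


def fit_fractions(
    spectrum: CDSpectrum,
    basis: BasisSet,
    fit_scale: bool = False,
) -> tuple[StructureFractions, float]:
    """Simplex-constrained least-squares decomposition of a spectrum.

    Returns the fractions and the residual 2-norm.  The spectrum is
    linearly interpolated onto the basis grid; extrapolation is refused.
    The minimiser over the simplex is found exactly by enumerating the
    seven possible active sets of the KKT conditions.  With
    ``fit_scale=True`` a free positive amplitude is co-fitted (for
    measured spectra of unknown concentration) via non-negative least
    squares followed by renormalisation.
    """
    if spectrum.wavelengths[0] - 1e-9 > basis.grid[0] or spectrum.wavelengths[-1] + 1e-9 < basis.grid[-1]:
        raise InvalidInputError(
            "spectrum does not cover the basis grid; extrapolation is not supported"
        )
    y = np.interp(basis.grid, spectrum.wavelengths, spectrum.ellipticities)
    A = basis.matrix()

    if np.linalg.matrix_rank(A, tol=1e-8 * np.abs(A).max()) < 3:
        warnings.warn(
            "basis bands are (near-)collinear; falling back to a pseudo-inverse fit",
            RuntimeWarning,
        )
        f, _ = nnls(np.vstack([A, np.full((1, 3), np.abs(A).max())]),
                    np.concatenate([y, [np.abs(A).max()]]))
        f = np.clip(f, 0.0, None)
        f = f / f.sum() if f.sum() > 0 else np.full(3, 1.0 / 3.0)
        resid = float(np.linalg.norm(A @ f - y))
        return StructureFractions(*f), resid

    if fit_scale:
        g, _ = nnls(A, y)
        total = g.sum()
        if total <= 0:
            raise InvalidInputError("spectrum has no nonnegative projection on the basis")
        f = g / total
        resid = float(np.linalg.norm(A @ g - y))
        return StructureFractions(*f), resid

    G = A.T @ A
    b = A.T @ y
    best_f, best_obj = None, np.inf
    # active-set enumeration over all nonempty supports, largest first
    supports = [(0, 1, 2)] + list(combinations(range(3), 2)) + [(i,) for i in range(3)]
    for idx in supports:
        f = _solve_affine(G, b, idx)
        if f is None or np.any(f < -1e-10):
            continue
        obj = float(f @ G @ f - 2.0 * b @ f)
        if obj < best_obj - 1e-12:
            best_f, best_obj = np.clip(f, 0.0, None), obj
    best_f = best_f / best_f.sum()
    resid = float(np.linalg.norm(A @ best_f - y))
    return StructureFractions(*best_f), resid


def relative_helix_percent(f: StructureFractions, reference: StructureFractions) -> float:
    """Helix fraction as a percentage of the reference's: 100 x fH / ref.fH."""
    if reference.fH <= 0.0:
        raise DegenerateReferenceError("reference helix fraction is zero")
    return 100.0 * f.fH / reference.fH


def read_spectrum_csv(path: Union[str, Path]) -> CDSpectrum:
    """Read a two-column CSV (``wavelength_nm``, ``ellipticity``; header required)."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "ellipticity"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing required column {col!r}")
    return CDSpectrum(df["wavelength_nm"].to_numpy(), df["ellipticity"].to_numpy())


def write_spectrum_csv(spectrum: CDSpectrum, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "ellipticity": spectrum.ellipticities}
    ).to_csv(path, index=False)
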