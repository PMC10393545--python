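"""Relative normalisation and correlation helpers.

The measured quantities in this pipeline (helix fraction, abundance,
hydrophobicity) are compared across peptide variants as percentages of a
named reference variant; the three relative columns are then correlated
pairwise.  Pearson's r is the default coefficient, with Spearman offered
for purely ordinal claims.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateReferenceError, InvalidInputError, UndefinedCorrelationError

__all__ = ["relative_percent", "pearson_r", "threeway_correlation"]


def relative_percent(
    values: Union[Mapping[str, float], pd.Series, Sequence[float]],
    reference: Union[str, int],
) -> Union[pd.Series, list[float]]:
    """Express every value as a percentage of the reference entry.

    ``values`` may be a mapping / Series keyed by variant id (reference
    selected by key) or a plain sequence (reference by index).  The
    reference entry maps to exactly 100.
    """
    if isinstance(values, pd.Series):
        ref = values[reference]
        if ref == 0:
            raise DegenerateReferenceError(f"reference {reference!r} is zero")
        return values * 100.0 / ref
    if isinstance(values, Mapping):
        ref = values[reference]
        if ref == 0:
            raise DegenerateReferenceError(f"reference {reference!r} is zero")
        return pd.Series({k: v * 100.0 / ref for k, v in values.items()})
    seq = list(values)
    ref = seq[reference]
    if ref == 0:
        raise DegenerateReferenceError(f"reference index {reference} is zero")
    return [v * 100.0 / ref for v in seq]


def pearson_r(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Sample correlation of two equal-length vectors (>= 3 points).

    ``method`` is ``"pearson"`` (default) or ``"spearman"``.  Constant
    input raises :class:`~gammatail.errors.UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise InvalidInputError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise InvalidInputError(f"unknown method {method!r}")


def threeway_correlation(table: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation matrix of a three-column measurement table.

    Rows are variants (>= 3 required); columns the three relative
    measurements.  The result is symmetric with a unit diagonal.
    """
    if table.shape[1] != 3:
        raise InvalidInputError("measurement table must have exactly 3 columns")
    if len(table) < 3:
        raise InvalidInputError("need at least 3 variants (rows)")
    if not np.all(np.isfinite(table.to_numpy(dtype=float))):
        raise InvalidInputError("measurement table contains non-finite values")
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(3), index=cols, columns=cols)
    for i in range(3):
        for j in range(i + 1, 3):
            r = pearson_r(table[cols[i]], table[cols[j]], method=method)
            out.iloc[i, j] = out.iloc[j, i] = r
    return out
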