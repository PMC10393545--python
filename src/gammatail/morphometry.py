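"""Mating-projection (shmoo) morphometry from binary cell masks.

The cell body is the largest circle inscribable in the mask (centre and
radius from the Euclidean distance transform, with everything outside
the frame counting as background).  The shmoo is the largest circle
inscribable in the part of the mask left over once the body is removed.
Shmoo length runs along the ray through the two circle centres, from the
body-circle boundary to the last foreground point before the ray exits
the mask; width is measured perpendicular to that axis at its midpoint.
The circular fraction — foreground inside the body circle over total
foreground — is 1 for a perfect disc and drops as a projection grows.

All distances are in pixels (pixel side = 1); an optional ``pixel_size``
scales the reported lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import InvalidInputError

__all__ = [
    "Circle",
    "ShmooMeasurement",
    "largest_inscribed_circle",
    "decompose_body_shmoo",
    "shmoo_length",
    "shmoo_width",
    "circular_fraction",
    "analyze_mask",
    "analyze_labels",
    "read_mask",
    "write_mask",
    "read_labels",
]

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)
RAY_STEP = 0.25  # sub-pixel march step, px
INSIDE_LEVEL = 0.5  # bilinear interpolation threshold for "inside the mask"
MIN_CELL_PIXELS = 5  # batch-mode size filter for segmentation debris


@dataclass(frozen=True)
class Circle:
    """An inscribed circle: integer pixel centre plus EDT radius."""

    row: int
    col: int
    radius: float

    @property
    def center(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class ShmooMeasurement:
    """Geometry of one cell: body/shmoo circles, length, width, circular fraction."""

    body: Circle
    shmoo: Optional[Circle]
    length: float
    width: Optional[float]
    circular_fraction: float
    degenerate_axis: bool = False


def _as_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InvalidInputError("mask must be a 2-D array")
    arr = arr != 0
    if not arr.any():
        raise InvalidInputError("mask has no foreground pixels")
    return arr


def _edt(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance transform with the frame border as background."""
    padded = np.pad(mask, 1, constant_values=False)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


def largest_inscribed_circle(mask) -> Circle:
    """Foreground pixel maximising the EDT; ties -> smallest (row, col)."""
    arr = _as_mask(mask)
    dist = _edt(arr)
    flat = np.argmax(dist)  # first occurrence = smallest (row, col) in row-major order
    row, col = np.unravel_index(flat, dist.shape)
    return Circle(int(row), int(col), float(dist[row, col]))


def decompose_body_shmoo(mask) -> tuple[Circle, Optional[Circle]]:
    """Body circle plus the inscribed circle of the largest remainder lobe.

    The remainder is every foreground pixel farther than the body radius
    from the body centre; its largest 8-connected component hosts the
    shmoo circle.  Smaller extra components are ignored (logged).
    """
    arr = _as_mask(mask)
    body = largest_inscribed_circle(arr)
    rows, cols = np.indices(arr.shape)
    dist_to_body = np.hypot(rows - body.row, cols - body.col)
    remainder = arr & (dist_to_body > body.radius)
    if not remainder.any():
        return body, None
    labels, n = ndimage.label(remainder, structure=_EIGHT)
    if n > 1:
        logger.info("remainder has %d components; keeping the largest", n)
    sizes = ndimage.sum_labels(remainder, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    shmoo = largest_inscribed_circle(labels == keep)
    return body, shmoo


def _bilinear(arr: np.ndarray, r: float, c: float) -> float:
    """Bilinear sample of the 0/1 mask at a sub-pixel point; outside -> 0."""
    n_r, n_c = arr.shape
    if r < 0 or c < 0 or r > n_r - 1 or c > n_c - 1:
        return 0.0
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, n_r - 1), min(c0 + 1, n_c - 1)
    fr, fc = r - r0, c - c0
    top = arr[r0, c0] * (1 - fc) + arr[r0, c1] * fc
    bot = arr[r1, c0] * (1 - fc) + arr[r1, c1] * fc
    return float(top * (1 - fr) + bot * fr)


def shmoo_length(mask, body: Circle, shmoo: Circle) -> tuple[float, bool]:
    """Length along the body-centre -> shmoo-centre ray.

    Start = the ray's crossing of the body-circle boundary; end = the
    last foreground point along the ray before it exits the mask
    (marched at 0.25-px steps).  Returns ``(length, degenerate)`` where
    ``degenerate`` flags coincident circle centres (length 0).
    """
    arr = _as_mask(mask).astype(float)
    dr, dc = shmoo.row - body.row, shmoo.col - body.col
    norm = float(np.hypot(dr, dc))
    if norm == 0.0:
        return 0.0, True
    ur, uc = dr / norm, dc / norm
    # march from the body centre to the frame edge, tracking the last inside point
    t_max = float(np.hypot(*arr.shape))
    t = 0.0
    t_end = None
    while t <= t_max:
        if _bilinear(arr, body.row + t * ur, body.col + t * uc) >= INSIDE_LEVEL:
            t_end = t
        t += RAY_STEP
    if t_end is None:
        return 0.0, False
    length = max(0.0, t_end - body.radius)
    return length, False


def shmoo_width(mask, body: Circle, shmoo: Circle, length: Optional[float] = None) -> Optional[float]:
    """Width perpendicular to the shmoo axis at its midpoint.

    Undefined (``None``) when the shmoo is not longer than one pixel.
    If the perpendicular line crosses the periphery on one side only,
    the width is reported as 1.
    """
    arr = _as_mask(mask).astype(float)
    if length is None:
        length, degenerate = shmoo_length(arr, body, shmoo)
        if degenerate:
            return None
    if length <= 1.0:
        return None
    dr, dc = shmoo.row - body.row, shmoo.col - body.col
    norm = float(np.hypot(dr, dc))
    ur, uc = dr / norm, dc / norm
    mid_t = body.radius + length / 2.0
    mr, mc = body.row + mid_t * ur, body.col + mid_t * uc
    pr, pc = -uc, ur  # perpendicular unit vector
    t_max = float(np.hypot(*arr.shape))

    def march(sign: float) -> Optional[float]:
        # distance from the midpoint to the periphery crossing on one side
        if _bilinear(arr, mr, mc) < INSIDE_LEVEL:
            return None
        t = 0.0
        last_inside = 0.0
        while t <= t_max:
            if _bilinear(arr, mr + sign * t * pr, mc + sign * t * pc) < INSIDE_LEVEL:
                return last_inside
            last_inside = t
            t += RAY_STEP
        return last_inside

    left, right = march(+1.0), march(-1.0)
    if left is None and right is None:
        return 1.0
    if left is None or right is None:
        return 1.0
    return left + right


def circular_fraction(mask, body: Circle) -> float:
    """Fraction of foreground whose pixel centres fall inside the body circle."""
    arr = _as_mask(mask)
    rows, cols = np.indices(arr.shape)
    inside = np.hypot(rows - body.row, cols - body.col) <= body.radius
    return float((arr & inside).sum() / arr.sum())


def analyze_mask(mask, pixel_size: float = 1.0) -> ShmooMeasurement:
    """Full geometry of a single-cell mask (lengths scaled by ``pixel_size``)."""
    arr = _as_mask(mask)
    body, shmoo = decompose_body_shmoo(arr)
    if shmoo is None:
        return ShmooMeasurement(body, None, 0.0, None, circular_fraction(arr, body))
    length, degenerate = shmoo_length(arr, body, shmoo)
    width = None if degenerate else shmoo_width(arr, body, shmoo, length)
    return ShmooMeasurement(
        body,
        shmoo,
        length * pixel_size,
        None if width is None else width * pixel_size,
        circular_fraction(arr, body),
        degenerate_axis=degenerate,
    )


def analyze_labels(labels, pixel_size: float = 1.0) -> pd.DataFrame:
    """Analyse every labelled cell independently; one row per label.

    Background is 0.  Labels smaller than 5 pixels are skipped with a
    logged warning (segmentation debris).
    """
    arr = np.asarray(labels)
    if arr.ndim != 2 or np.any(arr < 0):
        raise InvalidInputError("label image must be 2-D with nonnegative integers")
    rows = []
    for lab in np.unique(arr):
        if lab == 0:
            continue
        cell = arr == lab
        if cell.sum() < MIN_CELL_PIXELS:
            logger.warning("label %d has <%d pixels; skipped", lab, MIN_CELL_PIXELS)
            continue
        m = analyze_mask(cell, pixel_size)
        rows.append(
            {
                "label": int(lab),
                "body_r": m.body.radius,
                "body_row": m.body.row,
                "body_col": m.body.col,
                "shmoo_r": m.shmoo.radius if m.shmoo else np.nan,
                "length_px": m.length,
                "width_px": m.width if m.width is not None else np.nan,
                "circular_fraction": m.circular_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "body_r", "body_row", "body_col",
            "shmoo_r", "length_px", "width_px", "circular_fraction",
        ],
    )


# ---------------------------------------------------------------------------
# I/O


def read_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a binary mask from PNG (nonzero = foreground) or a text matrix."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("I"))
    else:
        arr = np.loadtxt(path, dtype=int)
    return _as_mask(arr)


def write_mask(mask, path: Union[str, Path]) -> None:
    """Write a binary mask as 8-bit PNG or a plain-text 0/1 matrix."""
    arr = _as_mask(mask)
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((arr * 255).astype(np.uint8)).save(path)
    else:
        np.savetxt(path, arr.astype(int), fmt="%d")


def read_labels(path: Union[str, Path]) -> np.ndarray:
    """Read a label image (16-bit PNG or text matrix of nonnegative ints)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        return np.asarray(Image.open(path), dtype=np.int64)
    return np.loadtxt(path, dtype=np.int64)
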