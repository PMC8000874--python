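"""Depth-wise ROI partitioning into equally thick superficial and deep layers.

For every image column occupied by the sample mask, the tissue height is
measured and the top half (surface side, row 0 upward) is assigned to the
superficial layer and the bottom half to the deep layer.  Odd column heights
give the extra pixel to the superficial layer (ceil rule).  Columns are image
columns, which approximates surface-normal chords well for the near-flat
samples this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxometry import T2MapResults, DEFAULT_R2_THRESHOLD


@dataclass(frozen=True)
class RoiLayers:
    """Whole-sample mask and its superficial/deep partition.

    Invariants: ``superficial | deep == whole``, ``superficial & deep`` empty,
    and per column the two pixel counts differ by at most one.
    """

    whole: np.ndarray
    superficial: np.ndarray
    deep: np.ndarray
    column_heights: np.ndarray  # tissue pixels per image column

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"whole": self.whole, "superficial": self.superficial, "deep": self.deep}


def split_layers(mask: np.ndarray, surface_at_top: bool = True) -> RoiLayers:
    """Split a sample mask into equally thick superficial and deep layers.

    Parameters
    ----------
    mask : ndarray of bool
        Whole-sample ROI.  Within each occupied column the mask must be
        vertically contiguous.
    surface_at_top : bool
        True (default) when row 0 faces the articular surface; set False for
        data acquired with the surface at the bottom of the image.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D raster")
    if not mask.any():
        raise ValueError("mask is empty")
    if not surface_at_top:
        inner = split_layers(mask[::-1], surface_at_top=True)
        return RoiLayers(
            whole=mask,
            superficial=inner.superficial[::-1],
            deep=inner.deep[::-1],
            column_heights=inner.column_heights,
        )

    n_rows, n_cols = mask.shape
    superficial = np.zeros_like(mask)
    deep = np.zeros_like(mask)
    heights = np.zeros(n_cols, dtype=int)

    for c in range(n_cols):
        rows = np.flatnonzero(mask[:, c])
        if rows.size == 0:
            continue
        top, bottom = rows[0], rows[-1]
        if rows.size != bottom - top + 1:
            raise ValueError(
                f"mask column {c} is not vertically contiguous "
                f"(rows {top}..{bottom} contain a gap)"
            )
        h = rows.size
        n_sup = -(-h // 2)  # ceil(h/2): odd heights favour the superficial layer
        superficial[top : top + n_sup, c] = True
        deep[top + n_sup : bottom + 1, c] = True
        heights[c] = h

    return RoiLayers(whole=mask, superficial=superficial, deep=deep, column_heights=heights)


def roi_summary(
    result: T2MapResults | np.ndarray,
    roi: np.ndarray,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    name: str = "ROI",
) -> tuple[float, float, int]:
    """Mean, sample SD and pixel count of a map inside a ROI.

    Accepts either a :class:`T2MapResults` (NaN/invalid pixels excluded via
    its ``valid_mask``) or a bare raster (NaN excluded).  Raises when the ROI
    contains no usable pixels.
    """
    roi = np.asarray(roi).astype(bool)
    if isinstance(result, T2MapResults):
        usable = result.valid_mask(r2_threshold) & roi
        values = result.t2[usable]
    else:
        raster = np.asarray(result, dtype=float)
        values = raster[roi]
        values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"{name}: no valid fitted pixels inside the ROI")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return (mean, sd, int(values.size))
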