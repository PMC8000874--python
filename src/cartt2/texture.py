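"""Masked gray-level co-occurrence matrices and texture features on T2 maps.

A T2 map restricted to an ROI is uniformly quantized into ``L`` gray levels,
then symmetric GLCMs are accumulated for a one-pixel offset along the four
standard orientations 0°, 45°, 90° and 135°.  Only pixel pairs whose BOTH
members lie inside the ROI and carry a defined T2 value contribute — pairs
crossing the ROI boundary are discarded rather than padded, so no texture is
fabricated at the sample edge.

From the normalized matrix ``p(i, j)`` four features are computed:

    contrast    = sum_ij p(i,j) (i - j)^2
    homogeneity = sum_ij p(i,j) / (1 + |i - j|)
    energy      = sum_ij p(i,j)^2            (angular second moment)
    variance    = sum_ij p(i,j) (i - mu)^2,  mu = sum_ij i p(i,j)

Contrast and homogeneity respond to local pixel-to-pixel differences,
energy to the orderliness of the level distribution, and variance to spread
around the mean level.  Per-orientation feature values are arithmetic-means
into orientation-averaged values.

Quantization defaults to L = 32 levels over a fixed 0-120 ms range so that
maps remain comparable across time points; ``roi_minmax`` mode is available
when per-map normalization is wanted instead.  Variance is reported in
quantized-level units by default, with an optional ms^2 rescaling via the
bin centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relaxometry import T2MapResults, DEFAULT_R2_THRESHOLD

DEFAULT_LEVELS = 32
DEFAULT_RANGE_MS = (0.0, 120.0)
ORIENTATIONS = (0, 45, 90, 135)

#: (drow, dcol) offsets; with symmetric accumulation the sign is immaterial.
_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),      # horizontal neighbour
    45: (-1, 1),    # up-right diagonal
    90: (-1, 0),    # vertical neighbour
    135: (-1, -1),  # up-left diagonal
}


@dataclass(frozen=True)
class QuantizedMap:
    """ROI-restricted quantization of a T2 map into L gray levels.

    ``levels`` holds integers in [0, L-1] where defined and -1 elsewhere.
    ``bin_centers`` maps levels back to ms (midpoint of each bin).
    """

    levels: np.ndarray
    defined: np.ndarray
    L: int
    value_range: tuple[float, float]
    bin_centers: np.ndarray


@dataclass(frozen=True)
class Glcm:
    """Normalized symmetric co-occurrence matrix for one orientation."""

    matrix: np.ndarray
    offset: tuple[int, int]
    orientation: int
    n_pairs: int


@dataclass(frozen=True)
class GlcmFeatures:
    """Orientation-resolved and orientation-averaged texture features."""

    contrast: float
    homogeneity: float
    energy: float
    variance: float
    variance_ms2: float | None = None
    per_orientation: dict[int, dict[str, float]] = field(default_factory=dict)
    orientations_used: tuple[int, ...] = ()
    n_pairs: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "homogeneity": self.homogeneity,
            "energy": self.energy,
            "variance": self.variance,
        }


def _map_values(result: T2MapResults | np.ndarray,
                r2_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(result, T2MapResults):
        return result.t2, result.valid_mask(r2_threshold)
    raster = np.asarray(result, dtype=float)
    return raster, np.isfinite(raster)


def quantize(
    result: T2MapResults | np.ndarray,
    roi: np.ndarray,
    L: int = DEFAULT_LEVELS,
    range_mode: str = "fixed",
    value_range: tuple[float, float] = DEFAULT_RANGE_MS,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> QuantizedMap:
    """Uniformly bin a T2 map inside a ROI into L gray levels.

    ``range_mode='fixed'`` uses ``value_range`` (ms) for every map;
    ``'roi_minmax'`` stretches to the ROI's own min/max.  Values are clipped
    to the range ends; a degenerate (constant) ROI collapses to level 0.
    """
    if L < 2:
        raise ValueError(f"need at least 2 gray levels, got L={L}")
    roi = np.asarray(roi).astype(bool)
    raster, valid = _map_values(result, r2_threshold)
    defined = roi & valid
    if not defined.any():
        raise ValueError("ROI contains no defined T2 pixels")

    if range_mode == "fixed":
        lo, hi = value_range
        if not hi > lo:
            raise ValueError(f"fixed range needs max > min, got {value_range}")
    elif range_mode == "roi_minmax":
        vals = raster[defined]
        lo, hi = float(vals.min()), float(vals.max())
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")

    levels = np.full(roi.shape, -1, dtype=np.int32)
    width = (hi - lo) / L if hi > lo else 0.0
    if width == 0.0:  # constant ROI: single level by convention
        levels[defined] = 0
        centers = np.full(L, lo)
    else:
        scaled = np.floor((raster[defined] - lo) / width).astype(np.int32)
        levels[defined] = np.clip(scaled, 0, L - 1)
        centers = lo + (np.arange(L) + 0.5) * width
    return QuantizedMap(
        levels=levels, defined=defined, L=L,
        value_range=(lo, hi), bin_centers=centers,
    )


def glcm(qmap: QuantizedMap, orientation: int) -> Glcm:
    """Accumulate the symmetric one-pixel-offset GLCM for one orientation.

    Every ordered pair (p, p + offset) with both pixels defined contributes
    to (i, j) and to (j, i); the matrix is normalized to sum 1.
    """
    if orientation not in _OFFSETS:
        raise ValueError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation}"
        )
    dr, dc = _OFFSETS[orientation]
    lev, defined = qmap.levels, qmap.defined
    rows, cols = lev.shape

    # shift 'defined' and levels by the offset; valid where both ends defined
    a_sl = (slice(max(0, -dr), rows - max(0, dr)),
            slice(max(0, -dc), cols - max(0, dc)))
    b_sl = (slice(max(0, dr), rows - max(0, -dr)),
            slice(max(0, dc), cols - max(0, -dc)))
    both = defined[a_sl] & defined[b_sl]
    i = lev[a_sl][both]
    j = lev[b_sl][both]
    n_pairs = i.size
    if n_pairs == 0:
        raise ValueError(
            f"no valid pixel pairs for orientation {orientation} in this ROI"
        )
    mat = np.zeros((qmap.L, qmap.L))
    np.add.at(mat, (i, j), 1.0)
    np.add.at(mat, (j, i), 1.0)
    mat /= mat.sum()
    return Glcm(matrix=mat, offset=(dr, dc), orientation=orientation, n_pairs=n_pairs)


def features(g: Glcm, bin_centers: np.ndarray | None = None) -> dict[str, float]:
    """Contrast, homogeneity, energy and variance of one normalized GLCM.

    With ``bin_centers`` given, an additional ``variance_ms2`` key rescales
    the variance into ms^2 using the bin-center values.
    """
    p = g.matrix
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"GLCM must be normalized to sum 1 (sum = {total:g})")
    L = p.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    mu = float((i * p).sum())
    out = {
        "contrast": float((p * (i - j) ** 2).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "energy": float((p ** 2).sum()),
        "variance": float((p * (i - mu) ** 2).sum()),
    }
    if bin_centers is not None:
        c = np.asarray(bin_centers, dtype=float)
        ci = c[i]
        mu_ms = float((ci * p).sum())
        out["variance_ms2"] = float((p * (ci - mu_ms) ** 2).sum())
    return out


def orientation_averaged_features(
    qmap: QuantizedMap,
    orientations: tuple[int, ...] = ORIENTATIONS,
) -> GlcmFeatures:
    """Compute features per orientation, then arithmetic-mean each feature.

    Orientations without any valid pair are dropped (and recorded); all
    orientations empty is an error.
    """
    per: dict[int, dict[str, float]] = {}
    n_pairs: dict[int, int] = {}
    for theta in orientations:
        try:
            g = glcm(qmap, theta)
        except ValueError:
            continue
        per[theta] = features(g, qmap.bin_centers)
        n_pairs[theta] = g.n_pairs
    if not per:
        raise ValueError("no orientation produced any valid pixel pair")
    used = tuple(sorted(per))
    mean = {
        key: float(np.mean([per[t][key] for t in used]))
        for key in ("contrast", "homogeneity", "energy", "variance", "variance_ms2")
    }
    return GlcmFeatures(
        contrast=mean["contrast"],
        homogeneity=mean["homogeneity"],
        energy=mean["energy"],
        variance=mean["variance"],
        variance_ms2=mean["variance_ms2"],
        per_orientation=per,
        orientations_used=used,
        n_pairs=n_pairs,
    )


def roi_texture(
    result: T2MapResults | np.ndarray,
    roi: np.ndarray,
    L: int = DEFAULT_LEVELS,
    range_mode: str = "fixed",
    value_range: tuple[float, float] = DEFAULT_RANGE_MS,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> GlcmFeatures:
    """Quantize a map inside a ROI and return orientation-averaged features."""
    qmap = quantize(result, roi, L=L, range_mode=range_mode,
                    value_range=value_range, r2_threshold=r2_threshold)
    return orientation_averaged_features(qmap)
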