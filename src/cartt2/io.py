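"""Reading and writing image stacks, masks, T2 maps and cohort metadata.

Stacks are stored as multi-page TIFF (pages = echoes) or NIfTI (echo
dimension last), always with a JSON sidecar carrying the echo times in ms;
masks as PNG/TIFF/NIfTI with nonzero = inside; T2 maps as 32-bit float
TIFF/NIfTI plus an optional colour-coded PNG with a fixed display range.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .relaxometry import EchoSeries, T2MapResults

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def sidecar_path(stack_path) -> Path:
    p = Path(stack_path)
    name = p.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.lower().endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def write_stack(path, series: EchoSeries) -> Path:
    """Write a multi-echo stack plus its JSON echo-time sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = series.pixels.astype(np.float32)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        # TIFF pages are the leading axis; store echoes as pages
        tifffile.imwrite(path, np.moveaxis(data, -1, 0))
    meta = {
        "echo_times_ms": [float(t) for t in series.echo_times],
        "pixel_size_mm": series.pixel_size,
        "sample_id": series.sample_id,
        "time_point": series.time_point,
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_stack(path) -> EchoSeries:
    """Read a stack written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    with open(sidecar_path(path)) as fh:
        meta = json.load(fh)
    if _is_nifti(path):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    else:
        data = np.moveaxis(tifffile.imread(path).astype(float), 0, -1)
    return EchoSeries(
        pixels=data,
        echo_times=np.asarray(meta["echo_times_ms"], dtype=float),
        pixel_size=float(meta.get("pixel_size_mm", 0.23)),
        sample_id=meta.get("sample_id", ""),
        time_point=meta.get("time_point", ""),
    )


def write_mask(path, mask: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask = np.asarray(mask).astype(bool)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.astype(np.uint8) * 255)
    else:
        iio.imwrite(path, mask.astype(np.uint8) * 255)
    return path


def read_mask(path) -> np.ndarray:
    """Nonzero pixels are inside the ROI."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).dataobj)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A)
            arr = arr[..., :3].max(axis=-1)
    return np.asarray(arr) != 0


def write_t2_map(path, result: T2MapResults) -> Path:
    """32-bit float raster of T2 in ms; NaN outside the fitted region."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = result.t2.astype(np.float32)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(path, data)
    return path


def read_t2_map(path) -> np.ndarray:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return tifffile.imread(path).astype(float)


def write_t2_png(path, result: T2MapResults, vmin: float = 0.0,
                 vmax: float = 120.0, cmap: str = "jet") -> Path:
    """Colour-coded T2 map PNG with a fixed display range in ms."""
    import matplotlib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    norm = np.clip((result.t2 - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](np.nan_to_num(norm))
    rgba[~np.isfinite(result.t2)] = (0.0, 0.0, 0.0, 1.0)
    iio.imwrite(path, (rgba[..., :3] * 255).astype(np.uint8))
    return path


def write_cohort(samples, out_dir, stack_format: str = "tif") -> pd.DataFrame:
    """Write a simulated cohort to disk and return the metadata table.

    Layout: ``<out_dir>/<sample_id>/<tp>_stack.tif`` (+ sidecar),
    ``<tp>_mask.png``, ``<tp>_true_t2.tif`` and a top-level ``metadata.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for sample in samples:
        sdir = out / sample.sample_id
        for tp, series in sample.series.items():
            stack_path = write_stack(sdir / f"{tp}_stack.{stack_format}", series)
            mask_path = write_mask(sdir / f"{tp}_mask.png",
                                   sample.truths[tp].mask)
            truth_path = sdir / f"{tp}_true_t2.tif"
            tifffile.imwrite(truth_path,
                             sample.truths[tp].true_t2.astype(np.float32))
            records.append({
                "sample_id": sample.sample_id,
                "group": sample.group,
                "time_point": tp,
                "stack_path": str(stack_path.relative_to(out)),
                "mask_path": str(mask_path.relative_to(out)),
                "truth_path": str(truth_path.relative_to(out)),
                "seed": sample.config.rng_seed,
            })
    meta = pd.DataFrame.from_records(records)
    meta.to_csv(out / "metadata.csv", index=False)
    return meta
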