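"""Synthetic longitudinal multi-echo phantoms of impacted cartilage samples.

Each phantom is a single mid-sagittal cross-section of a cartilage sample,
~15 mm wide at 0.23 mm/pixel, with row 0 at the articular surface.  The true
T2 field interpolates linearly with depth from a superficial baseline down to
a deep baseline, reproducing the inherent depth-wise stratification of
healthy cartilage.  Three exposure arms evolve over four time points
(t0 = pre-exposure, t1 = immediately after, t2 = +24 h, t3 = +72 h):

CONT
    Unimpacted controls: the whole map drifts by a small multiplicative
    fraction per time point (incubation-related hydration increase).
LIMP
    Low-energy impaction (0.49 J): a band-like T2 elevation appears across
    the entire sample width, centred at mid-depth (transitional zone), with a
    Gaussian depth profile whose amplitude grows over time.
HIMP
    High-energy impaction (0.98 J): a diffuse 2D Gaussian T2 elevation centred
    on the impaction site whose radius and amplitude grow over time until it
    involves most of the cross-section.

Lesion fields are additive in ms.  Signals follow the mono-exponential decay
S(TE) = S0 exp(-TE/T2) with optional Gaussian or Rician (magnitude) noise.
All randomness flows through a single integer seed, so outputs are
bit-reproducible.

Default lesion amplitudes/radii and control drift were chosen once so that
the cohort-mean relative T2 changes have the sign and approximate magnitude
observed in drop-tower impaction experiments (controls a few percent, LIMP
~10-27%, HIMP ~15-60% by 72 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .layers import RoiLayers, split_layers
from .protocol import EchoSchedule, InvalidParameterError
from .relaxometry import EchoSeries

TIME_POINTS = ("t0", "t1", "t2", "t3")
GROUPS = ("CONT", "LIMP", "HIMP")

#: Group-wise baseline T2 means/SDs in ms (superficial, deep) used when
#: drawing per-sample baselines for a cohort.
GROUP_BASELINES: dict[str, dict[str, tuple[float, float]]] = {
    "CONT": {"superficial": (37.0, 6.4), "deep": (29.4, 5.1)},
    "LIMP": {"superficial": (38.2, 4.3), "deep": (26.1, 2.8)},
    "HIMP": {"superficial": (42.9, 5.8), "deep": (27.7, 6.0)},
}

#: Default cohort arm sizes.
DEFAULT_GROUP_SIZES: dict[str, int] = {"CONT": 7, "LIMP": 14, "HIMP": 14}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, baselines, lesion schedule and noise model of one phantom.

    Lengths are mm, T2 values ms.  ``band_*`` parameters describe the LIMP
    transitional-zone band (depth fractions: 0 = surface, 1 = deepest);
    ``diffuse_*`` parameters the HIMP lesion (lateral/depth fractions of the
    sample extent).  Per-time-point tuples are ordered (t0, t1, t2, t3).
    """

    pixel_size: float = 0.23
    sample_width: float = 15.0
    cartilage_thickness: float = 2.5
    s0: float = 1000.0
    t2_superficial_baseline: float = 39.0
    t2_deep_baseline: float = 27.5
    group: str = "CONT"
    time_points: tuple[str, ...] = TIME_POINTS
    # CONT: multiplicative drift fraction per time point
    drift: tuple[float, ...] = (0.0, 0.030, 0.067, 0.047)
    # LIMP: Gaussian depth-profile band across the full width
    band_center_frac: float = 0.5
    band_sigma_frac: float = 0.18
    band_amplitude: tuple[float, ...] = (0.0, 7.7, 18.7, 21.3)
    # HIMP: 2D Gaussian centred on the impaction site
    diffuse_center: tuple[float, float] = (0.5, 0.5)  # (lateral, depth) fractions
    diffuse_sigma: tuple[tuple[float, float], ...] = (
        (0.16, 0.20), (0.16, 0.20), (0.22, 0.26), (0.28, 0.32)
    )
    diffuse_amplitude: tuple[float, ...] = (0.0, 27.0, 30.0, 45.0)
    # acquisition noise
    noise_model: str = "rician"  # {"none", "gaussian", "rician"}
    snr: float = 50.0
    rng_seed: int = 0
    # mask shape details
    undulation_amplitude_px: int = 1
    undulation_wavelength_px: float = 31.0
    undulation_phase: float = 0.0
    padding_px: int = 3

    def __post_init__(self) -> None:
        for name in ("pixel_size", "sample_width", "cartilage_thickness", "s0",
                     "t2_superficial_baseline", "t2_deep_baseline"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.t2_superficial_baseline <= self.t2_deep_baseline:
            raise InvalidParameterError(
                "superficial baseline T2 must exceed the deep baseline "
                f"({self.t2_superficial_baseline} vs {self.t2_deep_baseline} ms)"
            )
        if self.group not in GROUPS:
            raise InvalidParameterError(f"group must be one of {GROUPS}")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise InvalidParameterError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise InvalidParameterError("snr must be > 0 when noise is enabled")
        if not (0.0 <= self.band_center_frac <= 1.0):
            raise InvalidParameterError(
                "band_center_frac places the band outside the tissue "
                f"(got {self.band_center_frac})"
            )
        if self.band_sigma_frac <= 0:
            raise InvalidParameterError("band_sigma_frac must be > 0")
        if any(a < 0 for a in self.band_amplitude + self.diffuse_amplitude):
            raise InvalidParameterError("lesion amplitudes must be >= 0")
        if not (0.0 <= self.diffuse_center[0] <= 1.0 and 0.0 <= self.diffuse_center[1] <= 1.0):
            raise InvalidParameterError("diffuse_center must lie inside the tissue")
        n_tp = len(self.time_points)
        for name in ("drift", "band_amplitude", "diffuse_amplitude", "diffuse_sigma"):
            if len(getattr(self, name)) != n_tp:
                raise InvalidParameterError(
                    f"{name} needs one entry per time point ({n_tp})"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def n_cols(self) -> int:
        return round(self.sample_width / self.pixel_size)

    @property
    def n_rows(self) -> int:
        return round(self.cartilage_thickness / self.pixel_size)

    @property
    def canvas_shape(self) -> tuple[int, int]:
        pad, amp = self.padding_px, self.undulation_amplitude_px
        return (2 * pad + 2 * amp + self.n_rows, 2 * pad + self.n_cols)

    def time_index(self, time_point: str) -> int:
        try:
            return self.time_points.index(time_point)
        except ValueError:
            raise InvalidParameterError(
                f"unknown time point {time_point!r}; expected one of {self.time_points}"
            ) from None


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth for one sample at one time point.

    ``true_t2`` is in ms inside the mask and NaN outside.  Row 0 faces the
    articular surface.  ``layers`` partitions the mask into equally thick
    superficial and deep halves.
    """

    true_t2: np.ndarray
    mask: np.ndarray
    layers: RoiLayers
    group: str
    time_point: str
    config: PhantomConfig


def _sample_mask(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Binary cross-section mask and per-column surface row.

    A mildly undulating articular surface (integer offsets up to
    ``undulation_amplitude_px``) sits over a flat deep boundary, so column
    heights vary by a pixel or two as in conservatively segmented real data.
    """
    rows, cols = config.canvas_shape
    pad, amp = config.padding_px, config.undulation_amplitude_px
    mask = np.zeros((rows, cols), dtype=bool)
    c0 = pad
    bottom = pad + 2 * amp + config.n_rows - 1
    col_idx = np.arange(config.n_cols)
    if amp > 0:
        offs = np.rint(
            amp * np.sin(2 * math.pi * col_idx / config.undulation_wavelength_px
                         + config.undulation_phase)
        ).astype(int)
    else:
        offs = np.zeros(config.n_cols, dtype=int)
    top = pad + amp + offs
    for j, c in enumerate(col_idx):
        mask[top[j]: bottom + 1, c0 + c] = True
    surface = np.full(cols, -1, dtype=int)
    surface[c0: c0 + config.n_cols] = top
    return mask, surface


def _depth_lateral_fractions(
    mask: np.ndarray, surface: np.ndarray, config: PhantomConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel depth fraction (0 surface -> 1 deep) and lateral fraction."""
    rows, cols = mask.shape
    rr, cc = np.nonzero(mask)
    depth = np.zeros(rr.size)
    lateral = np.zeros(rr.size)
    heights = mask.sum(axis=0)
    for k in range(rr.size):
        c = cc[k]
        h = heights[c]
        depth[k] = (rr[k] - surface[c]) / (h - 1) if h > 1 else 0.0
    occupied = np.flatnonzero(heights > 0)
    c_min, c_max = occupied[0], occupied[-1]
    span = max(c_max - c_min, 1)
    lateral = (cc - c_min) / span
    d_map = np.full(mask.shape, np.nan)
    x_map = np.full(mask.shape, np.nan)
    d_map[rr, cc] = depth
    x_map[rr, cc] = lateral
    return d_map, x_map


def build_true_t2(config: PhantomConfig, time_point: str) -> GroundTruth:
    """Construct the noise-free true-T2 raster for one time point.

    The base field interpolates linearly with depth between the superficial
    and deep baselines; the group-specific change (control drift, LIMP band,
    HIMP diffuse lesion) is then applied for the requested time point.
    """
    t = config.time_index(time_point)
    mask, surface = _sample_mask(config)
    d, x = _depth_lateral_fractions(mask, surface, config)

    t2 = config.t2_superficial_baseline + d * (
        config.t2_deep_baseline - config.t2_superficial_baseline
    )

    if config.group == "CONT":
        t2 = t2 * (1.0 + config.drift[t])
    elif config.group == "LIMP":
        amp = config.band_amplitude[t]
        if amp > 0:
            t2 = t2 + amp * np.exp(
                -((d - config.band_center_frac) ** 2)
                / (2.0 * config.band_sigma_frac ** 2)
            )
    else:  # HIMP
        amp = config.diffuse_amplitude[t]
        if amp > 0:
            sx, sz = config.diffuse_sigma[t]
            x0, z0 = config.diffuse_center
            t2 = t2 + amp * np.exp(
                -((x - x0) ** 2) / (2.0 * sx ** 2)
                - ((d - z0) ** 2) / (2.0 * sz ** 2)
            )

    t2 = np.where(mask, t2, np.nan)
    return GroundTruth(
        true_t2=t2,
        mask=mask,
        layers=split_layers(mask),
        group=config.group,
        time_point=time_point,
        config=config,
    )


def synthesize_echoes(
    truth: GroundTruth,
    schedule: EchoSchedule | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> EchoSeries:
    """Simulate the multi-echo magnitude stack for one ground truth.

    Noiseless signal is ``S0 exp(-TE/T2)`` inside the mask and 0 outside.
    Rician noise takes the magnitude of a complex Gaussian perturbation with
    per-channel SD ``S0/snr``; Gaussian noise adds one real channel and clips
    at zero (magnitude data are non-negative).
    """
    config = truth.config
    if schedule is None:
        schedule = EchoSchedule()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    te = np.array([n * schedule.echo_spacing for n in range(1, schedule.n_echoes + 1)])
    t2 = np.nan_to_num(truth.true_t2, nan=np.inf)
    signal = np.where(
        truth.mask[..., None],
        config.s0 * np.exp(-te[None, None, :] / t2[..., None]),
        0.0,
    )
    if config.noise_model == "rician":
        sigma = config.s0 / config.snr
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        signal = np.hypot(re, im)
    elif config.noise_model == "gaussian":
        sigma = config.s0 / config.snr
        signal = np.clip(signal + rng.normal(0.0, sigma, signal.shape), 0.0, None)
    return EchoSeries(
        pixels=signal,
        echo_times=te,
        pixel_size=config.pixel_size,
        sample_id=sample_id,
        time_point=truth.time_point,
    )


@dataclass
class PhantomSample:
    """One synthetic sample: its config and per-time-point truth and stack."""

    sample_id: str
    group: str
    config: PhantomConfig
    truths: dict[str, GroundTruth]
    series: dict[str, EchoSeries]


def _draw_baselines(
    group: str, rng: np.random.Generator,
    baselines: Mapping[str, Mapping[str, tuple[float, float]]] = GROUP_BASELINES,
) -> tuple[float, float]:
    """Draw (superficial, deep) baseline T2 for one sample.

    Rejection-samples until the superficial baseline exceeds the deep one by
    at least 2 ms and both are physiologically positive, preserving the
    depth-wise ordering invariant for every sample.
    """
    mu_s, sd_s = baselines[group]["superficial"]
    mu_d, sd_d = baselines[group]["deep"]
    for _ in range(1000):
        sup = rng.normal(mu_s, sd_s)
        deep = rng.normal(mu_d, sd_d)
        if sup - deep >= 2.0 and deep > 5.0:
            return float(sup), float(deep)
    raise RuntimeError("baseline rejection sampling failed (misconfigured SDs?)")


def simulate_cohort(
    n_per_group: Mapping[str, int] | None = None,
    rng_seed: int = 0,
    base_config: PhantomConfig | None = None,
    schedule: EchoSchedule | None = None,
    time_points: Iterable[str] | None = None,
    group_baselines: Mapping[str, Mapping[str, tuple[float, float]]] = GROUP_BASELINES,
) -> list[PhantomSample]:
    """Simulate a longitudinal cohort in memory.

    Per-sample baselines are drawn from the group-wise normal distributions in
    ``group_baselines``; each sample receives its own sub-seed derived from
    ``rng_seed``, so the cohort is bit-reproducible.  ``time_points`` can
    restrict simulation to a subset (e.g. only t3 for cross-sectional runs).
    """
    if n_per_group is None:
        n_per_group = DEFAULT_GROUP_SIZES
    if any(n < 1 for n in n_per_group.values()):
        raise InvalidParameterError("each group needs at least one sample")
    if base_config is None:
        base_config = PhantomConfig()
    if schedule is None:
        schedule = EchoSchedule()
    wanted = tuple(time_points) if time_points is not None else base_config.time_points

    master = np.random.default_rng(rng_seed)
    samples: list[PhantomSample] = []
    for group in GROUPS:
        if group not in n_per_group:
            continue
        for i in range(n_per_group[group]):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            sup, deep = _draw_baselines(group, rng, group_baselines)
            cfg = replace(
                base_config,
                group=group,
                t2_superficial_baseline=sup,
                t2_deep_baseline=deep,
                undulation_phase=float(rng.uniform(0, 2 * math.pi)),
                rng_seed=sub_seed,
            )
            sid = f"{group}{i + 1:02d}"
            truths: dict[str, GroundTruth] = {}
            series: dict[str, EchoSeries] = {}
            for tp in wanted:
                truth = build_true_t2(cfg, tp)
                truths[tp] = truth
                series[tp] = synthesize_echoes(truth, schedule, rng, sample_id=sid)
            samples.append(PhantomSample(sid, group, cfg, truths, series))
    return samples


def generate_cohort(
    out_dir,
    n_per_group: Mapping[str, int] | None = None,
    rng_seed: int = 0,
    base_config: PhantomConfig | None = None,
    schedule: EchoSchedule | None = None,
) -> pd.DataFrame:
    """Simulate a cohort and write stacks, masks, truths and a metadata table.

    Writes one multi-page TIFF stack (+ JSON echo-time sidecar), one mask PNG
    and one true-T2 TIFF per sample and time point under ``out_dir``, plus
    ``metadata.csv`` with columns sample_id, group, time_point, stack_path,
    mask_path, seed.  Returns the metadata table.
    """
    from . import io as cio  # local import: keeps phantom importable without I/O deps

    samples = simulate_cohort(n_per_group, rng_seed, base_config, schedule)
    return cio.write_cohort(samples, out_dir)
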