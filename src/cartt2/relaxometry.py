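"""Pixel-wise mono-exponential T2 mapping from multi-echo spin-echo stacks.

The signal of a multi-spin-echo acquisition decays with echo time TE as

    S(TE) = S0 * exp(-TE / T2)

per pixel.  :class:`T2Model` fits this model inside a binary ROI mask and
returns a :class:`T2MapResults` carrying per-pixel T2 [ms], S0 [a.u.], an R^2
fit-quality raster and the mask of successfully fitted pixels.

Two estimators are provided:

``loglinear`` (default)
    Ordinary least squares on ln(S) versus TE.  Deterministic, vectorised over
    all masked pixels, exact on noiseless mono-exponential data.  Pixels with a
    non-positive signal anywhere in the fit subset are marked unfittable.
``nonlinear``
    Levenberg-Marquardt least squares on the signal itself, initialised from
    the loglinear estimate.  Slower but less biased on magnitude (Rician) data.

The model is a pure mono-exponential without a noise-floor offset, so T2 is
overestimated at very low SNR where the Rician noise floor dominates; this is
a documented limitation, not corrected here.

Image convention: row 0 is the articular surface (superficial side), rows
increase toward the deep tissue.  Undefined pixels carry NaN, never 0 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .protocol import EchoSchedule, InvalidParameterError

T2_CLAMP_MS = (1.0, 300.0)
DEFAULT_R2_THRESHOLD = 0.7

FitMethod = Literal["loglinear", "nonlinear"]


@dataclass
class EchoSeries:
    """One sample's multi-echo image stack.

    Attributes
    ----------
    pixels : ndarray, shape (rows, cols, n_echoes)
        Signal magnitude in arbitrary units, echo dimension last.
    echo_times : ndarray, shape (n_echoes,)
        Echo times in ms, strictly increasing.
    pixel_size : float
        In-plane pixel edge length in mm.
    sample_id, time_point : str
        Labels carried through to downstream tables.
    """

    pixels: np.ndarray
    echo_times: np.ndarray
    pixel_size: float = 0.23
    sample_id: str = ""
    time_point: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be (rows, cols, echoes), got shape {self.pixels.shape}"
            )
        if self.pixels.shape[2] != self.echo_times.size:
            raise ValueError(
                f"{self.pixels.shape[2]} echo images but "
                f"{self.echo_times.size} echo times"
            )
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if np.any(self.pixels < 0):
            raise ValueError("signal must be non-negative (magnitude data)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _r_squared(signals: np.ndarray, predicted: np.ndarray, axis: int = -1) -> np.ndarray:
    ss_res = np.sum((signals - predicted) ** 2, axis=axis)
    ss_tot = np.sum((signals - np.mean(signals, axis=axis, keepdims=True)) ** 2, axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    # a perfect fit counts as R^2 = 1 even on constant data (zero total variance)
    r2 = np.where(ss_res <= 1e-12 * np.maximum(ss_tot, 1.0), 1.0, r2)
    return np.clip(r2, 0.0, 1.0)


def fit_t2_pixel(
    signals: np.ndarray,
    echo_times: np.ndarray,
    method: FitMethod = "loglinear",
) -> tuple[float, float, float]:
    """Fit S(TE) = S0 exp(-TE/T2) to a single pixel's echo train.

    ``signals`` and ``echo_times`` must already be subset to the echoes used
    for fitting (the caller applies ``fit_echo_indices``).  Returns
    ``(t2_ms, s0, r_squared)``; an unfittable pixel (non-positive signal in
    the subset, for the loglinear step) returns ``(nan, nan, nan)``.  T2 is
    clamped to [1, 300] ms.
    """
    signals = np.asarray(signals, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    if signals.size != echo_times.size:
        raise ValueError("signals and echo_times must have equal length")
    if signals.size < 3:
        raise ValueError("need at least 3 echoes to fit a 2-parameter decay")
    if np.any(signals <= 0):
        return (np.nan, np.nan, np.nan)

    # loglinear: ln S = ln S0 - TE/T2
    slope, intercept = np.polyfit(echo_times, np.log(signals), 1)
    s0 = float(np.exp(intercept))
    t2 = np.inf if slope >= 0 else -1.0 / slope

    if method == "nonlinear":
        p0 = (max(s0, 1e-12), float(np.clip(t2, *T2_CLAMP_MS)))
        try:
            popt, _ = curve_fit(
                lambda te, a, b: a * np.exp(-te / b),
                echo_times,
                signals,
                p0=p0,
                maxfev=200,
            )
            s0, t2 = float(popt[0]), float(popt[1])
            if t2 <= 0 or s0 <= 0:
                s0, t2 = p0  # diverged: fall back to the loglinear start
        except RuntimeError:
            s0, t2 = p0
    elif method != "loglinear":
        raise ValueError(f"unknown fit method {method!r}")

    t2 = float(np.clip(t2, *T2_CLAMP_MS))
    pred = s0 * np.exp(-echo_times / t2)
    r2 = float(_r_squared(signals, pred))
    return (t2, s0, r2)


class T2Model:
    """Mono-exponential T2 relaxation model for one multi-echo series.

    Parameters
    ----------
    series : EchoSeries
        The multi-echo stack to fit.
    mask : ndarray of bool, shape (rows, cols)
        Sample ROI; only pixels inside are fitted.
    schedule : EchoSchedule, optional
        Echo timing; its ``fit_echo_indices`` (default echoes 2-7) select the
        echoes entering the fit.  When omitted, a schedule is inferred from
        the series' echo times and all echoes are used.

    Examples
    --------
    >>> model = T2Model(series, mask)
    >>> res = model.fit()
    >>> res.t2.shape == mask.shape
    True
    """

    def __init__(
        self,
        series: EchoSeries,
        mask: np.ndarray,
        schedule: EchoSchedule | None = None,
    ) -> None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != series.shape:
            raise ValueError(
                f"mask shape {mask.shape} != image shape {series.shape}"
            )
        if not mask.any():
            raise ValueError("ROI mask is empty")
        self.series = series
        self.mask = mask
        if schedule is None:
            self.fit_indices = np.arange(series.echo_times.size)
        else:
            if max(schedule.fit_echo_indices) > series.echo_times.size:
                raise ValueError(
                    "schedule fit_echo_indices exceed the number of echoes"
                )
            self.fit_indices = np.asarray(schedule.fit_echo_indices) - 1
        if self.fit_indices.size < 3:
            raise ValueError("need at least 3 echoes in the fit subset")
        self.schedule = schedule

    def fit(self, method: FitMethod = "loglinear") -> "T2MapResults":
        """Fit every masked pixel; returns a :class:`T2MapResults`."""
        te = self.series.echo_times[self.fit_indices]
        sig = self.series.pixels[..., self.fit_indices][self.mask]  # (N, k)
        n_pix = sig.shape[0]

        fittable = np.all(sig > 0, axis=1)
        t2 = np.full(n_pix, np.nan)
        s0 = np.full(n_pix, np.nan)

        if fittable.any():
            y = np.log(sig[fittable])
            # shared design matrix -> one pseudo-inverse for all pixels
            X = np.column_stack([np.ones_like(te), -te])
            beta = np.linalg.pinv(X) @ y.T  # (2, Nf)
            s0_f = np.exp(beta[0])
            with np.errstate(divide="ignore"):
                t2_f = np.where(beta[1] > 0, 1.0 / beta[1], np.inf)

            if method == "nonlinear":
                idx = np.flatnonzero(fittable)
                for j, i in enumerate(idx):
                    p0 = (max(s0_f[j], 1e-12), float(np.clip(t2_f[j], *T2_CLAMP_MS)))
                    try:
                        popt, _ = curve_fit(
                            lambda x, a, b: a * np.exp(-x / b),
                            te, sig[i], p0=p0, maxfev=200,
                        )
                        if popt[0] > 0 and popt[1] > 0:
                            s0_f[j], t2_f[j] = popt
                    except RuntimeError:
                        pass
            elif method != "loglinear":
                raise ValueError(f"unknown fit method {method!r}")

            t2[fittable] = t2_f
            s0[fittable] = s0_f

        clamped = np.zeros(n_pix, dtype=bool)
        with np.errstate(invalid="ignore"):
            clamped[fittable] = (t2[fittable] < T2_CLAMP_MS[0]) | (
                t2[fittable] > T2_CLAMP_MS[1]
            )
        t2 = np.clip(t2, *T2_CLAMP_MS)

        pred = s0[:, None] * np.exp(-te[None, :] / t2[:, None])
        r2 = np.full(n_pix, np.nan)
        r2[fittable] = _r_squared(sig[fittable], pred[fittable])

        shape = self.mask.shape

        def scatter(vals: np.ndarray, fill=np.nan, dtype=float) -> np.ndarray:
            out = np.full(shape, fill, dtype=dtype)
            out[self.mask] = vals
            return out

        return T2MapResults(
            t2=scatter(t2),
            s0=scatter(s0),
            r_squared=scatter(r2),
            fit_mask=scatter(fittable, fill=False, dtype=bool),
            clamped=scatter(clamped, fill=False, dtype=bool),
            mask=self.mask,
            model=self,
            method=method,
            pixel_size=self.series.pixel_size,
            sample_id=self.series.sample_id,
            time_point=self.series.time_point,
        )


@dataclass
class T2MapResults:
    """Fitted T2 map.  NaN marks pixels outside the fitted region.

    ``fit_mask`` flags pixels that yielded a fit at all; ``clamped`` flags
    pixels whose raw T2 estimate fell outside the [1, 300] ms clamp.
    """

    t2: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    fit_mask: np.ndarray
    clamped: np.ndarray
    mask: np.ndarray
    model: T2Model | None = None
    method: str = "loglinear"
    pixel_size: float = 0.23
    sample_id: str = ""
    time_point: str = ""

    def valid_mask(self, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> np.ndarray:
        """Pixels acceptable for downstream ROI statistics."""
        with np.errstate(invalid="ignore"):
            ok = self.fit_mask & ~self.clamped & (
                np.nan_to_num(self.r_squared, nan=-1.0) >= r2_threshold
            )
        return ok

    def summary(self, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> str:
        """Plain-text fit report."""
        valid = self.valid_mask(r2_threshold)
        vals = self.t2[valid]
        lines = [
            "Mono-exponential T2 map",
            "=======================",
            f"sample:       {self.sample_id or '<unnamed>'}"
            + (f" @ {self.time_point}" if self.time_point else ""),
            f"method:       {self.method}",
            f"ROI pixels:   {int(self.mask.sum())}",
            f"fitted:       {int(self.fit_mask.sum())}"
            f" (clamped: {int(self.clamped.sum())})",
            f"valid (R^2>={r2_threshold:g}): {int(valid.sum())}",
        ]
        if vals.size:
            lines.append(f"T2 [ms]:      {vals.mean():.1f} +/- {vals.std(ddof=1):.1f}"
                         if vals.size > 1 else f"T2 [ms]:      {vals.mean():.1f}")
            lines.append(f"T2 range:     [{vals.min():.1f}, {vals.max():.1f}]")
        return "\n".join(lines)

    def plot(self, ax=None, vmin: float = 0.0, vmax: float = 120.0, cmap: str = "jet"):
        """Colour-coded T2 map with a fixed display range [ms]."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shown = np.ma.masked_invalid(self.t2)
        im = ax.imshow(shown, vmin=vmin, vmax=vmax, cmap=cmap, interpolation="nearest")
        ax.figure.colorbar(im, ax=ax, label="T2 [ms]")
        ax.set_title(f"{self.sample_id} {self.time_point}".strip())
        return ax


def fit_t2_map(
    series: EchoSeries,
    mask: np.ndarray,
    schedule: EchoSchedule | None = None,
    method: FitMethod = "loglinear",
) -> T2MapResults:
    """Functional shorthand for ``T2Model(series, mask, schedule).fit(method)``."""
    return T2Model(series, mask, schedule).fit(method)
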