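"""Experimental design constants: drop-tower impaction energetics and echo timing.

Cartilage samples are injured with a drop tower: a cylindrical weight of mass
``m`` falls from height ``h`` onto the sample surface, delivering kinetic energy
``E = m g h`` at impact velocity ``V = sqrt(2 g h)``.  The study arms are a
low-impact exposure (0.5 kg from 100 mm, 0.49 J) and a high-impact exposure
(1.0 kg from 100 mm, 0.98 J), plus unimpacted controls.

T2 mapping uses a multi-spin-echo acquisition with echoes at ``n * 8.38`` ms for
``n = 1..12``.  Only echoes 2-7 (all below 60 ms) enter the mono-exponential
fit: the first echo is excluded to avoid stimulated-echo artefacts and the late
echoes because of their low signal-to-noise ratio.  Echo indices are 1-based
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class InvalidParameterError(ValueError):
    """A physically meaningless protocol or phantom parameter."""


@dataclass(frozen=True)
class ImpactionSpec:
    """Drop-tower impaction parameters.

    Parameters
    ----------
    mass : float
        Drop weight in kilograms.
    drop_height : float
        Drop height in meters.
    gravity : float
        Gravitational acceleration in m/s^2 (default 9.81).
    tip_diameter_mm : float
        Diameter of the impacting tip in millimeters (informational only).
    """

    mass: float
    drop_height: float
    gravity: float = 9.81
    tip_diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise InvalidParameterError(f"mass must be >= 0 kg, got {self.mass}")
        if self.drop_height < 0:
            raise InvalidParameterError(
                f"drop_height must be >= 0 m, got {self.drop_height}"
            )
        if self.gravity <= 0:
            raise InvalidParameterError(f"gravity must be > 0, got {self.gravity}")


#: The two impaction arms of the study (controls are never impacted).
LOW_IMPACT = ImpactionSpec(mass=0.5, drop_height=0.100)
HIGH_IMPACT = ImpactionSpec(mass=1.0, drop_height=0.100)


def impact_velocity(spec: ImpactionSpec) -> float:
    """Impact velocity ``V = sqrt(2 g h)`` in m/s (independent of mass)."""
    return math.sqrt(2.0 * spec.gravity * spec.drop_height)


def impact_energy(spec: ImpactionSpec) -> float:
    """Impaction energy ``E = m g h`` in joules."""
    return spec.mass * spec.gravity * spec.drop_height


@dataclass(frozen=True)
class EchoSchedule:
    """Multi-spin-echo timing: TE_n = n * echo_spacing, 1-based echo indices.

    ``fit_echo_indices`` selects the echoes used for T2 fitting (default 2-7).
    """

    echo_spacing: float = 8.38
    n_echoes: int = 12
    fit_echo_indices: tuple[int, ...] = field(default=(2, 3, 4, 5, 6, 7))

    def __post_init__(self) -> None:
        if self.echo_spacing <= 0:
            raise InvalidParameterError(
                f"echo_spacing must be > 0 ms, got {self.echo_spacing}"
            )
        if self.n_echoes < 1:
            raise InvalidParameterError(f"n_echoes must be >= 1, got {self.n_echoes}")
        idx = tuple(int(i) for i in self.fit_echo_indices)
        if list(idx) != sorted(set(idx)):
            raise InvalidParameterError(
                f"fit_echo_indices must be strictly ascending, got {idx}"
            )
        if idx and (idx[0] < 1 or idx[-1] > self.n_echoes):
            raise InvalidParameterError(
                f"fit_echo_indices must lie in 1..{self.n_echoes}, got {idx}"
            )
        object.__setattr__(self, "fit_echo_indices", idx)


def echo_times(schedule: EchoSchedule) -> list[float]:
    """All echo times TE_n = n * echo_spacing in ms, n = 1..n_echoes."""
    return [n * schedule.echo_spacing for n in range(1, schedule.n_echoes + 1)]


def fit_echo_times(schedule: EchoSchedule) -> list[float]:
    """Echo times of the fitting subset (1-based ``fit_echo_indices``), in ms."""
    return [n * schedule.echo_spacing for n in schedule.fit_echo_indices]
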