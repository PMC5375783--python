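"""Core domain types and radiometric arithmetic.

A thermogram is an 8-bit grayscale image whose intensities encode surface
temperature.  The camera software registers the scene extremes (``t_min_c``,
``t_max_c``); the affine map

    T(g) = t_min + (g / g_max) * (t_max - t_min)

recovers a per-pixel temperature matrix, where ``g_max`` is the *observed*
maximum gray level in the image (not the nominal depth).  This makes the
calibration image-dependent by design: the hottest pixel always maps to the
scene maximum.

Also provided: per-region temperature statistics, the instantaneous
field-of-view (IFOV) spot-size arithmetic used to bound the smallest
measurable target, and a thermal-stabilization check on a cool-down series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DegenerateInputError(ValueError):
    """Input is formally valid but carries no usable signal."""


class SegmentationError(RuntimeError):
    """A pipeline stage could not produce a segmentation ("unknown" outcome)."""


@dataclass(frozen=True)
class RadiometricMeta:
    """Scene calibration recorded alongside a thermogram.

    Parameters
    ----------
    t_min_c, t_max_c:
        Minimum and maximum scene temperature (°C) registered by the camera
        software.
    emissivity:
        Surface emissivity; human skin is ~0.97.  Carried as metadata only.
    distance_m:
        Camera-to-subject distance in meters.
    ifov_mrad:
        Instantaneous field of view of the sensor, in milliradians.
    """

    t_min_c: float
    t_max_c: float
    emissivity: float = 0.97
    distance_m: float = 1.2
    ifov_mrad: float = 1.36

    def __post_init__(self) -> None:
        if not self.t_min_c < self.t_max_c:
            raise ValueError(f"t_min_c ({self.t_min_c}) must be < t_max_c ({self.t_max_c})")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")


@dataclass(frozen=True)
class Thermogram:
    """Gray-intensity matrix plus its radiometric sidecar.

    ``pixels`` holds integers in ``[0, levels-1]`` (8-bit by default);
    other depths are accepted but normalized to 8 bits on load.
    """

    pixels: np.ndarray
    meta: RadiometricMeta
    levels: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be integer gray levels")
        if px.min() < 0 or px.max() > self.levels - 1:
            raise ValueError(f"gray levels must lie in [0, {self.levels - 1}]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ThermalMatrix:
    """Per-pixel temperature in °C, same shape as the source thermogram."""

    temps: np.ndarray
    meta: RadiometricMeta

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        if t.ndim != 2 or t.size == 0:
            raise ValueError("temps must be a non-empty 2-D matrix")
        object.__setattr__(self, "temps", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RegionStats:
    """Summary temperature statistics over a masked region (°C).

    ``sd`` is the population standard deviation (divide by n).
    """

    avg: float
    max: float
    min: float
    sd: float
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count <= 0:
            raise ValueError("pixel_count must be positive")
        if not (self.min <= self.avg <= self.max) or self.sd < 0:
            raise ValueError("inconsistent statistics")


def to_thermal(thermogram: Thermogram) -> ThermalMatrix:
    """Convert gray intensities to a temperature matrix.

    The affine map sends gray 0 to ``t_min_c`` and the observed maximum gray
    level to ``t_max_c``.

    Raises
    ------
    DegenerateInputError
        If the image is all zeros (no gray dynamic to calibrate against).
    """
    px = thermogram.pixels
    tvgm = int(px.max())
    if tvgm == 0:
        raise DegenerateInputError("all-zero image: observed maximum gray level is 0")
    m = thermogram.meta
    temps = m.t_min_c + (px.astype(float) / tvgm) * (m.t_max_c - m.t_min_c)
    return ThermalMatrix(temps=temps, meta=m)


def region_stats(thermal: ThermalMatrix | np.ndarray, mask: np.ndarray) -> RegionStats:
    """Average / max / min / population-SD of temperatures under ``mask``."""
    temps = thermal.temps if isinstance(thermal, ThermalMatrix) else np.asarray(thermal, float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != temps.shape:
        raise ValueError(f"mask shape {mask.shape} != matrix shape {temps.shape}")
    vals = temps[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return RegionStats(
        avg=float(vals.mean()),
        max=float(vals.max()),
        min=float(vals.min()),
        sd=float(vals.std(ddof=0)),
        pixel_count=int(vals.size),
    )


def spot_size(ifov_mrad: float, distance_m: float, safety_factor: int = 1) -> float:
    """Smallest measurable target size (meters) at a given distance.

    ``safety_factor=1`` gives the theoretical spot size (IFOV/1000 × distance);
    ``safety_factor=3`` gives the measurement field of view (MFOV), the
    practical bound for reliable temperature readings with imperfect optics.
    """
    if ifov_mrad <= 0 or distance_m <= 0:
        raise ValueError("ifov_mrad and distance_m must be positive")
    if safety_factor < 1:
        raise ValueError("safety_factor must be >= 1")
    return safety_factor * (ifov_mrad / 1000.0) * distance_m


def stabilization_time(
    series: Sequence[tuple[float, float]], slope_tol: float = 0.05
) -> float:
    """First time (minutes) after which the cool-down curve stays flat.

    A subject entering a controlled room cools toward equilibrium; imaging
    before stabilization biases the temperature field.  A time point is stable
    when every subsequent successive slope satisfies ``|dT/dt| <= slope_tol``
    (°C/min).  Returns ``math.inf`` if the series never stabilizes.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 time points")
    times = np.asarray([t for t, _ in series], dtype=float)
    temps = np.asarray([v for _, v in series], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("series must be sorted by strictly increasing time")
    slopes = np.diff(temps) / np.diff(times)
    ok = np.abs(slopes) <= slope_tol
    # first index i such that every slope from i onward is within tolerance
    stable_from = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        stable_from = i
    if stable_from == len(ok):
        return math.inf
    return float(times[stable_from])
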