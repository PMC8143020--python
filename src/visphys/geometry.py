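"""Monitor geometry and visual-angle arithmetic.

All public angular quantities are in degrees; radians appear only inside
function bodies.  Screen coordinates are degrees of visual angle relative to
the fixation point at the monitor center, x rightward and y upward.  The
pixel-per-degree factor is treated as constant across the screen (small-angle
approximation); the exact tangent model is used only where viewing-distance
changes are analyzed (:func:`eccentricity_shift_for_depth`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import yaml

__all__ = [
    "MonitorSpec",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "frames_to_ms",
    "eccentricity_shift_for_depth",
]


@dataclass(frozen=True)
class MonitorSpec:
    """Display geometry.

    The defaults describe a 1680x1050 TFT monitor viewed from 450 mm at a
    120 Hz refresh rate, giving 27.854 pixels per degree of visual angle.
    """

    width_px: int = 1680
    height_px: int = 1050
    px_per_deg: float = 27.854
    distance_mm: float = 450.0
    refresh_hz: float = 120.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "px_per_deg", "distance_mm", "refresh_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"MonitorSpec.{name} must be strictly positive, got {v!r}")

    @property
    def width_deg(self) -> float:
        return self.width_px / self.px_per_deg

    @property
    def height_deg(self) -> float:
        return self.height_px / self.px_per_deg

    @property
    def corner_eccentricity_deg(self) -> float:
        """Eccentricity of the monitor corner, the outermost mappable point."""
        return math.hypot(self.width_px / 2.0, self.height_px / 2.0) / self.px_per_deg

    def scaled(self, factor: float) -> "MonitorSpec":
        """Return a copy with the pixel raster downscaled by ``factor``.

        The visual extent in degrees is preserved: pixel counts and the
        px/deg factor shrink together.  Used to run raster-based analyses at
        reduced resolution.
        """
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        return replace(
            self,
            width_px=max(1, round(self.width_px * factor)),
            height_px=max(1, round(self.height_px * factor)),
            px_per_deg=self.px_per_deg * factor,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MonitorSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _check_finite(value, name: str) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite")


def pixels_to_degrees(px, monitor: MonitorSpec):
    """Convert a pixel distance to degrees of visual angle."""
    _check_finite(px, "px")
    return np.asarray(px, dtype=float) / monitor.px_per_deg if np.ndim(px) else float(px) / monitor.px_per_deg


def degrees_to_pixels(deg, monitor: MonitorSpec):
    """Convert degrees of visual angle to a pixel distance."""
    _check_finite(deg, "deg")
    return np.asarray(deg, dtype=float) * monitor.px_per_deg if np.ndim(deg) else float(deg) * monitor.px_per_deg


def cartesian_to_polar(x, y):
    """Screen degrees (x right, y up) -> (eccentricity, polar angle).

    Polar angle is in [0, 360), 0 = rightward, counterclockwise positive.
    The origin maps to eccentricity 0 with polar angle 0 (tie-break).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_finite(x, "x")
    _check_finite(y, "y")
    ecc = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    # a negative angle within float epsilon of zero wraps to exactly 360.0
    ang = np.where(ang >= 360.0, 0.0, ang)
    if ecc.ndim == 0:
        return float(ecc), float(ang)
    return ecc, ang


def polar_to_cartesian(eccentricity, polar_angle_deg):
    """Inverse of :func:`cartesian_to_polar`."""
    ecc = np.asarray(eccentricity, dtype=float)
    ang = np.radians(np.asarray(polar_angle_deg, dtype=float))
    _check_finite(ecc, "eccentricity")
    _check_finite(ang, "polar_angle_deg")
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be non-negative")
    x = ecc * np.cos(ang)
    y = ecc * np.sin(ang)
    if ecc.ndim == 0:
        return float(x), float(y)
    return x, y


def frames_to_ms(n_frames, refresh_hz: float) -> float:
    """Duration of ``n_frames`` video frames in milliseconds."""
    if refresh_hz <= 0:
        raise ValueError("refresh_hz must be positive")
    if np.any(np.asarray(n_frames) < 0):
        raise ValueError("n_frames must be non-negative")
    return 1000.0 * np.asarray(n_frames, dtype=float) / refresh_hz if np.ndim(n_frames) else 1000.0 * n_frames / refresh_hz


def eccentricity_shift_for_depth(ecc_deg: float, distance_mm: float, delta_mm: float) -> float:
    """Change in angular eccentricity of a fixed on-screen point when the
    viewing distance changes by ``delta_mm``.

    A point at eccentricity ``ecc_deg`` lies ``distance_mm * tan(ecc)`` from
    the screen center; viewed from ``distance_mm + delta_mm`` its eccentricity
    becomes ``atan(distance * tan(ecc) / (distance + delta))``.  The returned
    value is the signed difference (new minus old): negative when the viewer
    moves away from the screen.
    """
    _check_finite([ecc_deg, distance_mm, delta_mm], "arguments")
    if distance_mm <= 0:
        raise ValueError("distance_mm must be positive")
    if distance_mm + delta_mm <= 0:
        raise ValueError("distance_mm + delta_mm must be positive")
    if abs(ecc_deg) >= 90.0:
        raise ValueError("eccentricity must be below 90 degrees")
    on_screen = distance_mm * math.tan(math.radians(ecc_deg))
    new_ecc = math.degrees(math.atan2(on_screen, distance_mm + delta_mm))
    return new_ecc - ecc_deg
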