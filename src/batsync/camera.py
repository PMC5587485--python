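"""Pinhole model of the thermal surveillance camera.

The world frame is camera-centered: origin at the camera, the optical axis
along +y, +x to the right, +z up, all in meters.  Pixel coordinates are
0-based with the origin at the top-left corner, rows increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel"]


@dataclass(frozen=True)
class CameraModel:
    """Thermal surveillance camera (640x480, 57 deg horizontal FOV, 30 fps).

    ``focal_px`` is derived from the sensor width and horizontal viewing
    angle; ``bat_size_m`` is the characteristic body/wing extent used to
    convert apparent pixel size into range.
    """

    width_px: int = 640
    height_px: int = 480
    hfov_deg: float = 57.0
    frame_rate: float = 30.0
    max_range_m: float = 80.0
    bat_size_m: float = 0.35

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("sensor dimensions must be positive")
        if not 0 < self.hfov_deg < 180:
            raise ValueError("hfov_deg must be in (0, 180)")
        if self.max_range_m <= 0 or self.bat_size_m <= 0 or self.frame_rate <= 0:
            raise ValueError("max_range_m, bat_size_m, frame_rate must be positive")

    @property
    def focal_px(self) -> float:
        return (self.width_px / 2.0) / math.tan(math.radians(self.hfov_deg) / 2.0)

    @property
    def vfov_deg(self) -> float:
        return math.degrees(2.0 * math.atan((self.height_px / 2.0) / self.focal_px))

    def fov_dims_at(self, distance_m: float) -> tuple[float, float]:
        """Width and height (m) of the imaged field of view at a distance."""
        w = 2.0 * distance_m * math.tan(math.radians(self.hfov_deg) / 2.0)
        h = w * self.height_px / self.width_px
        return w, h

    def project(self, xyz: np.ndarray) -> np.ndarray:
        """Project world points (..., 3) to pixel (row, col) coordinates.

        Points behind the camera (y <= 0) map to NaN.
        """
        xyz = np.asarray(xyz, dtype=float)
        x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            col = (self.width_px - 1) / 2.0 + self.focal_px * x / y
            row = (self.height_px - 1) / 2.0 - self.focal_px * z / y
        bad = y <= 0
        col = np.where(bad, np.nan, col)
        row = np.where(bad, np.nan, row)
        return np.stack([row, col], axis=-1)

    def in_frustum(self, xyz: np.ndarray, margin_px: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the viewing frustum."""
        rc = self.project(xyz)
        row, col = rc[..., 0], rc[..., 1]
        ok = np.isfinite(row) & np.isfinite(col)
        ok &= (col >= -margin_px) & (col <= self.width_px - 1 + margin_px)
        ok &= (row >= -margin_px) & (row <= self.height_px - 1 + margin_px)
        return ok

    def apparent_size_px(self, distance_m: float, size_m: float | None = None) -> float:
        """Pinhole apparent extent (px) of an object of physical size ``size_m``."""
        if size_m is None:
            size_m = self.bat_size_m
        return self.focal_px * size_m / max(distance_m, 1e-9)

    def range_from_size(self, size_px: float, size_m: float | None = None) -> float:
        """Invert :meth:`apparent_size_px`: estimated range (m) from pixel size."""
        if size_m is None:
            size_m = self.bat_size_m
        if size_px <= 0:
            return math.inf
        return self.focal_px * size_m / size_px
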