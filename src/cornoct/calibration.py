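"""Pixel/millimetre calibration, conic sag models and curvature.

All geometry downstream of apex detection is done in millimetres with the
origin at the corneal apex: lateral position ``x`` along the scanned
meridian (positive = nasal on horizontal scans of right eyes, superior on
vertical scans) and axial position ``z`` with the eye in the negative-z
direction, so deeper tissue has more negative ``z``.  Working in mm keeps
high-order polynomial fits well conditioned; pixel indices are only used
at the image-lookup boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "ScanCalibration",
    "ConicBoundary",
    "MeridianFrame",
    "px_to_mm",
    "mm_to_px",
    "conic_sag",
    "osculating_radius",
    "FlatSurfaceError",
    "DEFAULT_CALIBRATION",
]

#: Default B-scan geometry: 2048 x 1365 px covering 8.93 mm x 2.00 mm.
DEFAULT_WIDTH_PX = 2048
DEFAULT_DEPTH_PX = 1365
DEFAULT_WIDTH_MM = 8.93
DEFAULT_DEPTH_MM = 2.00


class FlatSurfaceError(ValueError):
    """Curvature requested where the surface is locally flat (z'' = 0)."""


@dataclass(frozen=True)
class ScanCalibration:
    """Physical extent of a B-scan pixel grid."""

    width_px: int = DEFAULT_WIDTH_PX
    depth_px: int = DEFAULT_DEPTH_PX
    width_mm: float = DEFAULT_WIDTH_MM
    depth_mm: float = DEFAULT_DEPTH_MM

    def __post_init__(self) -> None:
        for name in ("width_px", "depth_px", "width_mm", "depth_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def lateral_pitch_mm(self) -> float:
        """Millimetres per pixel column."""
        return self.width_mm / self.width_px

    @property
    def axial_pitch_mm(self) -> float:
        """Millimetres per pixel row."""
        return self.depth_mm / self.depth_px

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "ScanCalibration":
        """Read a JSON calibration sidecar; missing keys take the defaults."""
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            width_px=int(doc.get("width_px", DEFAULT_WIDTH_PX)),
            depth_px=int(doc.get("depth_px", DEFAULT_DEPTH_PX)),
            width_mm=float(doc.get("width_mm", DEFAULT_WIDTH_MM)),
            depth_mm=float(doc.get("depth_mm", DEFAULT_DEPTH_MM)),
        )

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "depth_px": self.depth_px,
            "width_mm": self.width_mm,
            "depth_mm": self.depth_mm,
        }


@dataclass(frozen=True)
class ConicBoundary:
    """Aspheric sag model ``z(x) = T + (sqrt(R^2 - (Q+1) x^2) - R) / (Q+1)``.

    Parameters
    ----------
    R : float
        Apical radius of curvature, mm.  Must be positive.
    Q : float
        Asphericity; ``Q = 0`` is a sphere, negative values flatten the
        surface away from the apex.  ``Q = -1`` (paraboloid limit of this
        parameterisation) is excluded.
    T : float
        Axial offset of the apex, mm.
    """

    R: float
    Q: float = 0.0
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"apical radius R must be > 0, got {self.R}")
        if self.Q == -1:
            raise ValueError("asphericity Q = -1 is outside this sag model")

    def sag(self, x):
        return conic_sag(x, self)

    @property
    def half_aperture_mm(self) -> float:
        """Largest |x| where the sag is defined (inf for Q < -1)."""
        if self.Q > -1:
            return self.R / np.sqrt(self.Q + 1.0)
        return np.inf


@dataclass(frozen=True)
class MeridianFrame:
    """Apex-anchored coordinate frame of one scanned meridian.

    ``origin`` is the apex position in (row, col) pixel coordinates; it may
    be fractional (intensity-weighted centroid).  The sign convention is
    positive x = nasal for right eyes on horizontal scans and positive
    x = superior on vertical scans.
    """

    meridian: str  # "horizontal" | "vertical"
    origin: tuple[float, float]  # (row, col), pixels
    eye: str = "OD"
    calibration: ScanCalibration = field(default_factory=ScanCalibration)

    def __post_init__(self) -> None:
        if self.meridian not in ("horizontal", "vertical"):
            raise ValueError(f"meridian must be horizontal|vertical, got {self.meridian!r}")
        r, c = self.origin
        cal = self.calibration
        if not (0 <= r < cal.depth_px and 0 <= c < cal.width_px):
            raise ValueError(f"apex origin {self.origin} lies outside the {cal.depth_px}x{cal.width_px} grid")

    @property
    def x_sign_convention(self) -> str:
        if self.meridian == "horizontal":
            return "positive x = nasal" if self.eye == "OD" else "positive x = temporal"
        return "positive x = superior"


def px_to_mm(pixel_coords, cal: ScanCalibration, frame: MeridianFrame):
    """Map (row, col) pixel coordinates to apex-centred (x_mm, z_mm).

    Columns map linearly to x; rows map linearly to z with deeper tissue at
    more negative z.  The apex maps to exactly (0, 0).
    """
    row = np.asarray(pixel_coords[0], dtype=float)
    col = np.asarray(pixel_coords[1], dtype=float)
    if np.any(row < 0) or np.any(row >= cal.depth_px) or np.any(col < 0) or np.any(col >= cal.width_px):
        raise ValueError(f"pixel {pixel_coords} outside the {cal.depth_px}x{cal.width_px} grid")
    r0, c0 = frame.origin
    x = (col - c0) * cal.lateral_pitch_mm
    z = -(row - r0) * cal.axial_pitch_mm
    if x.ndim == 0:
        return float(x), float(z)
    return x, z


def mm_to_px(xz, cal: ScanCalibration, frame: MeridianFrame):
    """Inverse of :func:`px_to_mm` (fractional row/col, not rounded)."""
    x = np.asarray(xz[0], dtype=float)
    z = np.asarray(xz[1], dtype=float)
    r0, c0 = frame.origin
    col = x / cal.lateral_pitch_mm + c0
    row = -z / cal.axial_pitch_mm + r0
    if row.ndim == 0:
        return float(row), float(col)
    return row, col


def conic_sag(x, b: ConicBoundary):
    """Axial height of a conic surface at lateral position(s) ``x`` (mm).

    ``z(x) = T + (sqrt(R^2 - (Q+1) x^2) - R) / (Q+1)``; at the apex the sag
    is exactly ``T`` and the function is even in ``x``.
    """
    x_arr = np.asarray(x, dtype=float)
    p = b.Q + 1.0
    disc = b.R**2 - p * x_arr**2
    if np.any(disc < 0):
        bad = np.atleast_1d(x_arr)[np.atleast_1d(disc) < 0]
        raise ValueError(
            f"conic sag undefined at x={bad[0]:.4f} mm (requires (Q+1) x^2 <= R^2 with R={b.R}, Q={b.Q})"
        )
    z = b.T + (np.sqrt(disc) - b.R) / p
    return float(z) if z.ndim == 0 else z


def osculating_radius(fit_coeffs, x) -> float:
    """Radius of the osculating circle of a polynomial z(x) at ``x`` (mm).

    ``rho = (1 + z'(x)^2)^(3/2) / |z''(x)|``.  For an exact circle of radius
    R the result is R at every point where the fit is faithful.

    Parameters
    ----------
    fit_coeffs : array-like
        Polynomial coefficients in ascending order (mm units).
    x : float
        Evaluation position, mm.

    Raises
    ------
    FlatSurfaceError
        If the second derivative vanishes at ``x`` (infinite radius).
    """
    c = np.asarray(fit_coeffs, dtype=float)
    d1 = npoly.polyval(x, npoly.polyder(c, 1))
    d2 = npoly.polyval(x, npoly.polyder(c, 2))
    if abs(d2) < 1e-12:  # straight to numerical precision: infinite radius
        raise FlatSurfaceError(f"surface is flat at x={x} mm (z'' = 0): radius of curvature is infinite")
    return float((1.0 + d1**2) ** 1.5 / abs(d2))


DEFAULT_CALIBRATION = ScanCalibration()
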