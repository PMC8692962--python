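"""Thickness profiles, zone summaries and central radii from surface fits.

Thickness is measured axially (along z at fixed x), matching the Z-line
geometry of the segmentation; no surface-normal correction is applied.
An optical-to-geometric scaling by a tissue group refractive index is
available (default 1.0, i.e. no optical-path correction).

Zones follow the clinical convention: central = 0-2 mm diameter
(|x| <= 1 mm), paracentral = 2-5 mm diameter (1 < |x| <= 2.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import osculating_radius
from .segmentation import SurfaceFit, ZLineSet

__all__ = [
    "ThicknessProfile",
    "ZoneSummary",
    "CentralRadius",
    "thickness_profile",
    "harmonize_meridians",
    "zone_summary",
    "central_radius",
    "ZONES",
]

#: zone name -> (min |x|, max |x|) in mm (diameters 0-2 and 2-5 mm)
ZONES = {"central": (0.0, 1.0), "paracentral": (1.0, 2.5)}


class LayerOrderError(ValueError):
    """Upper surface not strictly above lower surface: non-positive thickness."""


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-position axial thickness of one layer along one meridian."""

    layer: str  # epithelium | stroma | cornea
    meridian: str
    x_mm: np.ndarray
    thickness_um: np.ndarray
    refractive_index_applied: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_mm, dtype=float)
        t = np.asarray(self.thickness_um, dtype=float)
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "thickness_um", t)
        if x.shape != t.shape:
            raise ValueError("x_mm and thickness_um must have the same shape")
        if np.any(t <= 0):
            bad = x[t <= 0][0]
            raise LayerOrderError(
                f"{self.layer}: non-positive thickness at x={bad:.3f} mm — "
                "surfaces cross or coincide"
            )

    def central_value(self) -> float:
        at0 = np.flatnonzero(self.x_mm == 0.0)
        if len(at0) == 0:
            raise ValueError(f"{self.layer} profile has no x = 0 sample")
        return float(self.thickness_um[at0[0]])


@dataclass(frozen=True)
class ZoneSummary:
    """Mean/SD thickness of one layer over one analysis zone."""

    zone: str
    meridian: str  # "horizontal" | "vertical" | "both"
    layer: str
    mean_um: float
    sd_um: float
    n_positions: int


@dataclass(frozen=True)
class CentralRadius:
    """Central radius of curvature of one fitted surface, mm."""

    surface: str
    meridian: str
    radius_mm: float
    method: str = "osculating"


def thickness_profile(
    upper_fit: SurfaceFit,
    lower_fit: SurfaceFit,
    zlines: ZLineSet,
    n_index: float = 1.0,
    layer: str = "cornea",
    meridian: str = "horizontal",
) -> ThicknessProfile:
    """Axial thickness ``(z_upper - z_lower) / n_index`` in um per Z-line.

    Evaluated only where both fits have inlier support (the intersection of
    their inlier spans).
    """
    lo = max(upper_fit.span_mm[0], lower_fit.span_mm[0])
    hi = min(upper_fit.span_mm[1], lower_fit.span_mm[1])
    keep = (zlines.x_mm >= lo) & (zlines.x_mm <= hi)
    if not np.any(keep):
        raise ValueError(f"{layer}: fits share no supported span")
    x = zlines.x_mm[keep]
    t_um = (upper_fit(x) - lower_fit(x)) * 1000.0 / n_index
    return ThicknessProfile(
        layer=layer,
        meridian=meridian,
        x_mm=x,
        thickness_um=t_um,
        refractive_index_applied=n_index,
    )


def harmonize_meridians(
    profile_h: ThicknessProfile, profile_v: ThicknessProfile
) -> tuple[ThicknessProfile, ThicknessProfile]:
    """Proportionally rescale two meridian profiles to a common centre value.

    The target is the mean of the two central (x = 0) thicknesses; each
    profile is multiplied by ``target / own_centre``, so profile shape
    (ratios to the centre) is preserved and both centres agree afterwards.
    """
    c_h = profile_h.central_value()
    c_v = profile_v.central_value()
    if c_h <= 0 or c_v <= 0:
        raise ValueError("central thickness must be positive for harmonization")
    target = 0.5 * (c_h + c_v)
    out_h = replace(profile_h, thickness_um=profile_h.thickness_um * (target / c_h))
    out_v = replace(profile_v, thickness_um=profile_v.thickness_um * (target / c_v))
    return out_h, out_v


def zone_summary(profile: ThicknessProfile, zone: str) -> ZoneSummary:
    """Unweighted mean and SD of thickness over the Z-lines inside a zone."""
    if zone not in ZONES:
        raise ValueError(f"zone must be one of {sorted(ZONES)}, got {zone!r}")
    lo, hi = ZONES[zone]
    ax = np.abs(profile.x_mm)
    keep = (ax > lo) & (ax <= hi) if lo > 0 else ax <= hi
    if not np.any(keep):
        raise ValueError(f"no Z-line positions inside the {zone} zone")
    vals = profile.thickness_um[keep]
    return ZoneSummary(
        zone=zone,
        meridian=profile.meridian,
        layer=profile.layer,
        mean_um=float(vals.mean()),
        sd_um=float(vals.std(ddof=0)),
        n_positions=int(keep.sum()),
    )


def central_radius(
    fit: SurfaceFit,
    meridian: str = "horizontal",
    method: str = "osculating",
    window_mm: float = 2.5,
) -> CentralRadius:
    """Central radius of curvature of a fitted surface.

    ``method="osculating"`` takes the osculating-circle radius at x = 0 of
    a polynomial refitted to the inlier points within |x| <= ``window_mm``
    (the clinically analysed central 5 mm zone): curvature read off a
    full-width fit is systematically biased by polynomial truncation of
    the aspheric profile, while the central-window refit recovers conic
    radii to well under 0.05 mm.  ``method="circle"`` least-squares fits a
    circle over |x| <= 1.5 mm as a cross-check.
    """
    if method == "osculating":
        keep = np.abs(fit.inlier_x_mm) <= window_mm
        if np.count_nonzero(keep) >= fit.order + 3:
            from numpy.polynomial import polynomial as npoly

            coeffs = npoly.polyfit(fit.inlier_x_mm[keep], fit.inlier_z_mm[keep], fit.order)
        else:  # too few central inliers: fall back to the stored fit
            coeffs = fit.coeffs
        r = osculating_radius(coeffs, 0.0)
    elif method == "circle":
        keep = np.abs(fit.inlier_x_mm) <= 1.5
        if np.count_nonzero(keep) >= 8:
            x, z = fit.inlier_x_mm[keep], fit.inlier_z_mm[keep]
        else:
            x = np.linspace(-1.5, 1.5, 61)
            z = fit(x)
        # algebraic (Kasa) circle fit: x^2 + z^2 + D x + E z + F = 0
        A = np.column_stack([x, z, np.ones_like(x)])
        b = -(x**2 + z**2)
        (D, E, F), *_ = np.linalg.lstsq(A, b, rcond=None)
        r = float(np.sqrt(D**2 / 4 + E**2 / 4 - F))
    else:
        raise ValueError(f"unknown method {method!r}")
    if r <= 0 or not np.isfinite(r):
        raise ValueError(f"{fit.surface}: non-physical central radius {r}")
    return CentralRadius(surface=fit.surface, meridian=meridian, radius_mm=float(r), method=method)
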