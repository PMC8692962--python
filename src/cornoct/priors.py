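"""Topography elevation priors for OCT surface detection.

Scheimpflug topography supplies per-meridian elevation profiles of the
corneal anterior and posterior surfaces.  Each profile is fitted to a
5th-order polynomial; the fit is accepted when its RMS residual stays
below 2.5 um (a quality flag, not a hard gate).  The fitted curve then
steers the brightest-pixel search in the OCT B-scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from .calibration import MeridianFrame

__all__ = [
    "ElevationProfile",
    "PriorCurve",
    "PriorQualityWarning",
    "read_elevation_csv",
    "fit_prior",
    "align_prior_to_scan",
    "align_prior_pair",
    "PRIOR_ORDER",
    "PRIOR_RMS_GATE_UM",
]

PRIOR_ORDER = 5
PRIOR_RMS_GATE_UM = 2.5
MIN_SAMPLES = 12
MIN_SPAN_MM = 5.0


class PriorQualityWarning(UserWarning):
    """Raised when a prior fit's RMS residual exceeds the 2.5 um gate."""


@dataclass(frozen=True)
class ElevationProfile:
    """Elevation samples (x, z) in mm of one corneal surface along one meridian."""

    surface: str  # "anterior" | "posterior"
    meridian: str  # "horizontal" | "vertical"
    x_mm: np.ndarray
    z_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.surface not in ("anterior", "posterior"):
            raise ValueError(f"surface must be anterior|posterior, got {self.surface!r}")
        if self.meridian not in ("horizontal", "vertical"):
            raise ValueError(f"meridian must be horizontal|vertical, got {self.meridian!r}")
        x = np.asarray(self.x_mm, dtype=float)
        z = np.asarray(self.z_mm, dtype=float)
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "z_mm", z)
        if x.shape != z.shape or x.ndim != 1:
            raise ValueError("x_mm and z_mm must be 1-D arrays of equal length")
        if len(x) < MIN_SAMPLES:
            raise ValueError(f"elevation profile needs >= {MIN_SAMPLES} samples, got {len(x)}")
        if np.any(np.diff(x) <= 0):
            raise ValueError("elevation x positions must be strictly increasing")
        if x[-1] - x[0] < MIN_SPAN_MM:
            raise ValueError(f"elevation span {x[-1] - x[0]:.2f} mm < required {MIN_SPAN_MM} mm")

    def __len__(self) -> int:
        return len(self.x_mm)


@dataclass(frozen=True)
class PriorCurve:
    """5th-order polynomial prior for one surface, coefficients ascending, mm."""

    surface: str
    meridian: str
    coeffs: np.ndarray
    rms_error_um: float
    n_samples: int
    quality_ok: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", c)
        if len(c) != PRIOR_ORDER + 1:
            raise ValueError(f"prior polynomial must have order {PRIOR_ORDER}")
        if self.rms_error_um < 0:
            raise ValueError("rms_error_um must be >= 0")

    def __call__(self, x):
        return npoly.polyval(np.asarray(x, dtype=float), self.coeffs)


def read_elevation_csv(path) -> ElevationProfile:
    """Parse an elevation CSV with columns x_mm, z_mm, surface, meridian.

    One surface+meridian combination per file; rows are sorted by x and
    duplicate x positions are rejected.
    """
    df = pd.read_csv(path)
    required = {"x_mm", "z_mm", "surface", "meridian"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"elevation CSV {path} missing columns: {sorted(missing)}")
    surfaces = df["surface"].unique()
    meridians = df["meridian"].unique()
    if len(surfaces) != 1 or len(meridians) != 1:
        raise ValueError(f"elevation CSV {path} must contain exactly one surface and meridian")
    df = df.sort_values("x_mm")
    x = df["x_mm"].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"elevation CSV {path} has duplicate or non-monotone x values")
    return ElevationProfile(
        surface=str(surfaces[0]),
        meridian=str(meridians[0]),
        x_mm=x,
        z_mm=df["z_mm"].to_numpy(dtype=float),
    )


def fit_prior(profile: ElevationProfile) -> PriorCurve:
    """Least-squares 5th-order polynomial fit of an elevation profile.

    Warns (``PriorQualityWarning``) when the RMS residual is at or above
    2.5 um; the fit is returned either way with ``quality_ok`` recording
    the outcome.
    """
    x, z = profile.x_mm, profile.z_mm
    if len(np.unique(x)) < PRIOR_ORDER + 1:
        raise ValueError(
            f"prior fit needs >= {PRIOR_ORDER + 1} distinct x positions, got {len(np.unique(x))}"
        )
    coeffs = npoly.polyfit(x, z, PRIOR_ORDER)
    resid_mm = z - npoly.polyval(x, coeffs)
    rms_um = float(np.sqrt(np.mean(resid_mm**2)) * 1000.0)
    ok = rms_um < PRIOR_RMS_GATE_UM
    if not ok:
        warnings.warn(
            f"{profile.surface}/{profile.meridian} prior RMS {rms_um:.2f} um >= "
            f"{PRIOR_RMS_GATE_UM} um gate; proceeding with a flagged prior",
            PriorQualityWarning,
            stacklevel=2,
        )
    return PriorCurve(
        surface=profile.surface,
        meridian=profile.meridian,
        coeffs=coeffs,
        rms_error_um=rms_um,
        n_samples=len(profile),
        quality_ok=ok,
    )


def _apex_of(curve: PriorCurve) -> tuple[float, float]:
    """Locate the apex (extremum of elevation) of a prior on a dense grid."""
    # Search the polynomial's stationary points inside a generous span;
    # the apex is the most anterior (max z) stationary point.
    d1 = npoly.polyder(curve.coeffs, 1)
    roots = npoly.polyroots(d1)
    real = roots[np.abs(roots.imag) < 1e-9].real
    if len(real) == 0:
        raise ValueError(f"{curve.surface} prior has no extremum (apex) in its span")
    z_vals = npoly.polyval(real, curve.coeffs)
    i = int(np.argmax(z_vals))
    return float(real[i]), float(z_vals[i])


def _shift(curve: PriorCurve, dx: float, dz: float) -> PriorCurve:
    """Translate a prior curve by (dx, dz): new(x) = old(x - dx) + dz."""
    shifted = npoly.polyfit(
        np.linspace(-6, 6, 2 * (PRIOR_ORDER + 1)),
        npoly.polyval(np.linspace(-6, 6, 2 * (PRIOR_ORDER + 1)) - dx, curve.coeffs) + dz,
        PRIOR_ORDER,
    )
    return replace(curve, coeffs=shifted)


def align_prior_to_scan(prior: PriorCurve, frame: MeridianFrame, z_offset: float = 0.0) -> PriorCurve:
    """Translate a prior so its apex sits at the scan origin (0, z_offset).

    Registration between topography and OCT is apex-to-apex translation
    only — no rotation or scaling.
    """
    if prior.meridian != frame.meridian:
        raise ValueError(f"prior meridian {prior.meridian!r} != scan meridian {frame.meridian!r}")
    x_apex, z_apex = _apex_of(prior)
    return _shift(prior, -x_apex, z_offset - z_apex)


def align_prior_pair(
    anterior: PriorCurve, posterior: PriorCurve, frame: MeridianFrame
) -> tuple[PriorCurve, PriorCurve]:
    """Register an anterior/posterior prior pair to the scan frame.

    Both profiles come from the same topographer frame, so the translation
    that brings the anterior apex to the scan origin is applied to both —
    preserving the anterior-posterior depth separation the posterior search
    window depends on.
    """
    if anterior.surface != "anterior" or posterior.surface != "posterior":
        raise ValueError("align_prior_pair expects (anterior, posterior) priors in that order")
    x_apex, z_apex = _apex_of(anterior)
    return (
        _shift(anterior, -x_apex, -z_apex),
        _shift(posterior, -x_apex, -z_apex),
    )
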