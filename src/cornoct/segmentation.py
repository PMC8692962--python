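"""Automatic corneal surface segmentation of OCT B-scans.

The pipeline detects the corneal apex as the brightest region of the scan,
masks image content outside a pair of aspheric exclusion boundaries, and
then traces each interface (corneal anterior, epithelial posterior,
corneal posterior) by searching, along 129 evenly spaced depth columns
("Z-lines"), for the brightest pixel within +/-10 um of a guiding curve —
a topography-derived prior for the outer surfaces, a 4th-order base curve
through operator seed points for the epithelial posterior surface.  The
candidates are fitted to a 5th-order polynomial with iterative rejection
of points further than 7 um from the fit, repeated until no outlier
remains.

The high-level entry point is :class:`CornealSegmentationModel`, whose
``fit()`` returns a :class:`SegmentationResult` carrying the three
converged surface fits and per-surface diagnostics.  The individual steps
are exposed as module functions for testing and reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import ndimage
from skimage import measure

from .calibration import ConicBoundary, MeridianFrame, ScanCalibration, conic_sag

__all__ = [
    "BScan",
    "ZLineSet",
    "CandidatePoints",
    "SurfaceFit",
    "SeedPoints",
    "ApexDetectionError",
    "TraceFailureError",
    "ConvergenceError",
    "detect_apex",
    "apply_boundary_mask",
    "sample_zlines",
    "trace_surface",
    "robust_polyfit",
    "detect_epithelium",
    "render_overlay",
    "CornealSegmentationModel",
    "SegmentationResult",
    "DEFAULT_UPPER_BOUNDARY",
    "DEFAULT_LOWER_BOUNDARY",
]

#: Exclusion boundary defaults: a flat wide conic just above the anterior
#: surface and a steep conic well below the posterior surface.
DEFAULT_UPPER_BOUNDARY = ConicBoundary(R=10.0, Q=-0.2, T=0.01)
DEFAULT_LOWER_BOUNDARY = ConicBoundary(R=5.0, Q=-0.1, T=-0.8)

N_ZLINES = 129
SEARCH_WINDOW_UM = 10.0
OUTLIER_TOL_UM = 7.0
FIT_ORDER = 5
SEED_BASE_ORDER = 4
MIN_SEEDS = 5
MIN_INLIERS = 8
APEX_SMOOTH_SIGMA_MM = 0.025
APEX_THRESHOLD_PERCENTILE = 99.5
MAX_INVALID_FRACTION = 0.5
MIN_CANDIDATE_BRIGHTNESS = 1.0  # below one 8-bit grey level counts as empty


class ApexDetectionError(RuntimeError):
    pass


class TraceFailureError(RuntimeError):
    """Too few Z-lines produced a candidate — the scan is too blurry to segment."""


class ConvergenceError(RuntimeError):
    """Robust fitting discarded too many points to keep the fit overdetermined."""


@dataclass
class BScan:
    """A calibrated grayscale OCT cross-section.

    ``image`` is row-major with row 0 the shallowest (most anterior) depth;
    intensities are on the 0-255 scale regardless of source bit depth.
    ``frame`` is populated by apex detection.
    """

    image: np.ndarray
    calibration: ScanCalibration
    meridian: str = "horizontal"
    eye: str = "OD"
    subject: str = ""
    visit: str = ""
    frame: MeridianFrame | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError(f"B-scan image must be 2-D, got shape {img.shape}")
        if img.shape != (self.calibration.depth_px, self.calibration.width_px):
            raise ValueError(
                f"image shape {img.shape} does not match calibration "
                f"({self.calibration.depth_px}, {self.calibration.width_px})"
            )
        if not np.all(np.isfinite(img)) or np.any(img < 0):
            raise ValueError("B-scan intensities must be finite and non-negative")
        self.image = img


@dataclass(frozen=True)
class ZLineSet:
    """Lateral positions (mm, apex-centred) of the surface-detection columns."""

    x_mm: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_mm, dtype=float)
        object.__setattr__(self, "x_mm", x)
        if len(x) % 2 == 0:
            raise ValueError(f"Z-line count must be odd so x=0 is included, got {len(x)}")
        if not np.any(x == 0.0):
            raise ValueError("Z-line set must contain x = 0")
        spacings = np.diff(x)
        if not np.allclose(spacings, spacings[0]):
            raise ValueError("Z-lines must be evenly spaced")

    @property
    def count(self) -> int:
        return len(self.x_mm)

    @property
    def spacing_mm(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0])

    def columns(self, frame: MeridianFrame) -> np.ndarray:
        """Nearest pixel column of each Z-line in the given frame."""
        cal = frame.calibration
        return np.rint(self.x_mm / cal.lateral_pitch_mm + frame.origin[1]).astype(int)


@dataclass(frozen=True)
class CandidatePoints:
    """Per-Z-line brightest-pixel candidates for one surface."""

    surface: str
    x_mm: np.ndarray
    z_mm: np.ndarray
    brightness: np.ndarray
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass(frozen=True)
class SurfaceFit:
    """Converged robust polynomial fit of one corneal interface.

    ``coeffs`` are ascending-order polynomial coefficients in mm.  The
    inlier record retains the candidate points that survived outlier
    rejection; all inlier residuals are within the outlier tolerance.
    """

    surface: str
    order: int
    coeffs: np.ndarray
    inlier_x_mm: np.ndarray
    inlier_z_mm: np.ndarray
    iterations: int
    max_abs_residual_um: float
    rms_residual_um: float

    def __call__(self, x):
        return npoly.polyval(np.asarray(x, dtype=float), self.coeffs)

    @property
    def n_inliers(self) -> int:
        return len(self.inlier_x_mm)

    @property
    def span_mm(self) -> tuple[float, float]:
        return float(self.inlier_x_mm.min()), float(self.inlier_x_mm.max())

    def to_dict(self) -> dict:
        return {
            "surface": self.surface,
            "order": self.order,
            "coeffs_mm": [float(c) for c in self.coeffs],
            "inlier_x_mm": [round(float(v), 6) for v in self.inlier_x_mm],
            "iterations": self.iterations,
            "rms_um": round(self.rms_residual_um, 3),
            "max_abs_residual_um": round(self.max_abs_residual_um, 3),
        }


@dataclass(frozen=True)
class SeedPoints:
    """Operator-selected points on the epithelial posterior surface (mm)."""

    x_mm: np.ndarray
    z_mm: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_mm, dtype=float)
        z = np.asarray(self.z_mm, dtype=float)
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "z_mm", z)
        if len(x) < MIN_SEEDS:
            raise ValueError(f"at least {MIN_SEEDS} seed points are required, got {len(x)}")
        if np.any(np.diff(x) <= 0):
            raise ValueError("seed x positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x_mm)


def detect_apex(scan: BScan) -> MeridianFrame:
    """Locate the corneal apex on the anterior interface of the brightest region.

    Lateral localisation: the image is Gaussian-smoothed (sigma = 25 um in
    both axes), thresholded at the 99.5th intensity percentile, and the
    apex column is the intensity-weighted column centroid of the largest
    connected super-threshold component (ties on component size go to the
    component reaching the smaller column index).  Axial localisation: the
    apex row is the centroid of the first (shallowest) intensity band at
    that column, measured on a laterally-smoothed-only image so the closely
    spaced interface bands are not merged axially.  This puts the origin on
    the anterior surface itself, which the prior registration and the
    exclusion boundaries both assume.
    """
    img = scan.image
    if float(img.std()) == 0.0:
        raise ApexDetectionError("image has zero intensity variance: no brightest region")
    cal = scan.calibration
    sig_r = APEX_SMOOTH_SIGMA_MM / cal.axial_pitch_mm
    sig_c = APEX_SMOOTH_SIGMA_MM / cal.lateral_pitch_mm
    smooth = ndimage.gaussian_filter(img, sigma=(sig_r, sig_c))
    thresh = np.percentile(smooth, APEX_THRESHOLD_PERCENTILE)
    bright = smooth >= thresh
    labels = measure.label(bright, connectivity=2)
    if labels.max() == 0:
        raise ApexDetectionError("no super-threshold region found")
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie on size: the component reaching the smaller column index wins
        min_cols = [np.min(np.nonzero(labels == lab)[1]) for lab in best]
        lab = int(best[int(np.argmin(min_cols))])
    else:
        lab = int(best[0])
    rows, cols = np.nonzero(labels == lab)
    w = smooth[rows, cols] - thresh  # pedestal-subtracted weights
    c0 = float(np.sum(cols * w) / np.sum(w))
    # axial: centroid of the brightest band of the lateral-only smoothed
    # column at c0 (full-width-at-half-maximum support)
    lat = ndimage.gaussian_filter1d(img, sigma=sig_c, axis=1)
    profile = lat[:, int(round(c0))]
    peak = int(np.argmax(profile))
    half = profile[peak] / 2.0
    lo = peak
    while lo > 0 and profile[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < len(profile) - 1 and profile[hi + 1] >= half:
        hi += 1
    band = np.arange(lo, hi + 1)
    r0 = float(np.sum(band * profile[band]) / np.sum(profile[band]))
    return MeridianFrame(meridian=scan.meridian, origin=(r0, c0), eye=scan.eye, calibration=cal)


def apply_boundary_mask(
    scan: BScan,
    upper: ConicBoundary = DEFAULT_UPPER_BOUNDARY,
    lower: ConicBoundary = DEFAULT_LOWER_BOUNDARY,
) -> tuple[BScan, float]:
    """Zero out pixels outside the aspheric exclusion boundaries.

    Pixels with z above the upper conic or below the lower conic are set to
    zero; everything between is untouched.  Returns the masked scan and the
    fraction of pixels zeroed.  Columns beyond a boundary's lateral domain
    are left unmasked by that boundary.
    """
    if scan.frame is None:
        raise ValueError("apex frame must be set before masking (run detect_apex)")
    cal, frame = scan.calibration, scan.frame
    cols = np.arange(cal.width_px)
    rows = np.arange(cal.depth_px)
    x = (cols - frame.origin[1]) * cal.lateral_pitch_mm
    z = -(rows - frame.origin[0]) * cal.axial_pitch_mm

    def _sag(b: ConicBoundary, fill: float) -> np.ndarray:
        out = np.full_like(x, fill)
        inside = (b.Q + 1.0) * x**2 <= b.R**2 if b.Q > -1 else np.ones_like(x, bool)
        out[inside] = conic_sag(x[inside], b)
        return out

    zu = _sag(upper, np.inf)
    zl = _sag(lower, -np.inf)
    overlap = zu <= zl
    if np.any(overlap):
        xo = x[overlap][0]
        raise ValueError(
            f"exclusion boundaries intersect at x={xo:.3f} mm (upper sag <= lower sag): "
            "check boundary parameters"
        )
    outside = (z[:, None] > zu[None, :]) | (z[:, None] < zl[None, :])
    masked_img = np.where(outside, 0.0, scan.image)
    masked = replace(scan, image=masked_img)
    return masked, float(outside.mean())


def sample_zlines(
    cal: ScanCalibration, n: int = N_ZLINES, span_mm: float | None = None
) -> ZLineSet:
    """Evenly spaced Z-line positions, symmetric about the apex (x = 0).

    ``n`` must be odd so one line is aligned with the origin.  The default
    span is the full scan width; the spacing is ``span / (n - 1)``.
    """
    if n % 2 == 0:
        raise ValueError(f"Z-line count must be odd, got {n}")
    if n < 3:
        raise ValueError("need at least 3 Z-lines")
    span = cal.width_mm if span_mm is None else float(span_mm)
    if span > cal.width_mm + 1e-9:
        raise ValueError(f"Z-line span {span} mm exceeds scan width {cal.width_mm} mm")
    half = span / 2.0
    x = np.linspace(-half, half, n)
    x[n // 2] = 0.0  # exact origin line
    return ZLineSet(x_mm=x)


def _guided_candidates(
    masked: BScan,
    guide,
    zlines: ZLineSet,
    window_um: float,
    surface: str,
    x_limits: tuple[float, float] | None = None,
    max_z_mm: np.ndarray | None = None,
) -> CandidatePoints:
    """Brightest unmasked pixel within +/-window of a guide curve per Z-line."""
    cal, frame = masked.calibration, masked.frame
    r0 = frame.origin[0]
    win_mm = window_um / 1000.0
    cols = zlines.columns(frame)
    xs = zlines.x_mm
    z_out = np.zeros_like(xs)
    b_out = np.zeros_like(xs)
    valid = np.zeros(len(xs), dtype=bool)
    z_guide = np.asarray(guide(xs), dtype=float)
    for i, (x, col) in enumerate(zip(xs, cols)):
        if col < 0 or col >= cal.width_px:
            continue
        if x_limits is not None and not (x_limits[0] <= x <= x_limits[1]):
            continue
        zg = z_guide[i]
        row_lo = int(np.floor(-(zg + win_mm) / cal.axial_pitch_mm + r0))
        row_hi = int(np.ceil(-(zg - win_mm) / cal.axial_pitch_mm + r0))
        row_lo = max(row_lo, 0)
        row_hi = min(row_hi, cal.depth_px - 1)
        if row_hi < row_lo:
            continue
        rows = np.arange(row_lo, row_hi + 1)
        z_px = -(rows - r0) * cal.axial_pitch_mm
        keep = np.abs(z_px - zg) <= win_mm
        if max_z_mm is not None:
            keep &= z_px < max_z_mm[i]
        if not np.any(keep):
            continue
        rows, z_px = rows[keep], z_px[keep]
        vals = masked.image[rows, col]
        if vals.max() < MIN_CANDIDATE_BRIGHTNESS:
            continue  # window fully masked or dark
        top = np.flatnonzero(vals == vals.max())
        if len(top) > 1:
            # tie: nearest the guide wins; then the shallower (greater z) pixel
            d = np.abs(z_px[top] - zg)
            top = top[d == d.min()]
            top = top[np.argmax(z_px[top])] if len(top) > 1 else top[0]
        j = int(np.atleast_1d(top)[0])
        # sub-pixel refinement: parabolic vertex through the peak pixel and
        # its axial neighbours (clamped to half a pixel, so the candidate
        # stays within half an axial pixel of the brightest pixel)
        row_j = rows[j]
        frac = 0.0
        if 0 < row_j < cal.depth_px - 1:
            i_s = masked.image[row_j - 1, col]  # shallower neighbour
            i_c = vals[j]
            i_d = masked.image[row_j + 1, col]  # deeper neighbour
            denom = 2.0 * i_c - i_s - i_d
            if denom > 0:
                frac = float(np.clip((i_d - i_s) / (2.0 * denom), -0.5, 0.5))
        z_out[i] = z_px[j] - frac * cal.axial_pitch_mm
        b_out[i] = vals[j]
        valid[i] = True
    return CandidatePoints(surface=surface, x_mm=xs, z_mm=z_out, brightness=b_out, valid=valid)


def trace_surface(
    masked: BScan,
    prior,
    zlines: ZLineSet,
    window_um: float = SEARCH_WINDOW_UM,
    surface: str | None = None,
) -> CandidatePoints:
    """Per Z-line, the brightest pixel within +/-``window_um`` of the prior.

    Z-lines with no unmasked pixel in the window are flagged invalid rather
    than fabricated; if more than half the lines are invalid a
    :class:`TraceFailureError` is raised (the scan counts as too blurry,
    mirroring the clinical exclusion of unsegmentable images).
    """
    name = surface or getattr(prior, "surface", "surface")
    cand = _guided_candidates(masked, prior, zlines, window_um, name)
    invalid_frac = 1.0 - cand.n_valid / zlines.count
    if invalid_frac > MAX_INVALID_FRACTION:
        raise TraceFailureError(
            f"{name}: {invalid_frac:.0%} of Z-lines had no candidate within "
            f"+/-{window_um} um of the prior — image too blurry to segment"
        )
    return cand


def robust_polyfit(
    points: CandidatePoints,
    order: int = FIT_ORDER,
    outlier_tol_um: float = OUTLIER_TOL_UM,
    min_inliers: int = MIN_INLIERS,
) -> SurfaceFit:
    """Iterative least-squares polynomial fit with hard outlier rejection.

    Each round fits all current points and removes every point whose
    residual exceeds ``outlier_tol_um``; the loop stops when no point is
    removed.  Termination is guaranteed because the point set strictly
    shrinks.  Falling below ``min_inliers`` points (keeping the order-5 fit
    overdetermined) raises :class:`ConvergenceError`.
    """
    x = points.x_mm[points.valid]
    z = points.z_mm[points.valid]
    if len(x) < min_inliers:
        raise ConvergenceError(
            f"{points.surface}: only {len(x)} valid candidates (< {min_inliers})"
        )
    tol_mm = outlier_tol_um / 1000.0
    iterations = 0
    while True:
        coeffs = npoly.polyfit(x, z, order)
        resid = z - npoly.polyval(x, coeffs)
        iterations += 1
        out = np.abs(resid) > tol_mm
        if not np.any(out):
            break
        x, z = x[~out], z[~out]
        if len(x) < min_inliers:
            raise ConvergenceError(
                f"{points.surface}: inliers fell to {len(x)} (< {min_inliers}) "
                f"after {iterations} iterations"
            )
    return SurfaceFit(
        surface=points.surface,
        order=order,
        coeffs=coeffs,
        inlier_x_mm=x,
        inlier_z_mm=z,
        iterations=iterations,
        max_abs_residual_um=float(np.max(np.abs(resid)) * 1000.0),
        rms_residual_um=float(np.sqrt(np.mean(resid**2)) * 1000.0),
    )


def detect_epithelium(
    masked: BScan,
    seeds: SeedPoints,
    zlines: ZLineSet,
    anterior_fit: SurfaceFit,
    window_um: float = SEARCH_WINDOW_UM,
    outlier_tol_um: float = OUTLIER_TOL_UM,
) -> SurfaceFit:
    """Detect the epithelial posterior surface from operator seed points.

    A 4th-order base curve through the seeds guides the brightest-pixel
    search, restricted to Z-lines between the seed endpoints and to pixels
    strictly deeper than the fitted anterior surface; the candidates then go
    through the same iterative quintic / 7 um-tolerance robust fit.
    """
    if len(np.unique(seeds.x_mm)) < SEED_BASE_ORDER + 1:
        raise ValueError(
            f"epithelium base curve needs >= {SEED_BASE_ORDER + 1} distinct seed x positions"
        )
    base = npoly.polyfit(seeds.x_mm, seeds.z_mm, SEED_BASE_ORDER)
    x_lim = (float(seeds.x_mm.min()), float(seeds.x_mm.max()))
    anterior_z = anterior_fit(zlines.x_mm)
    cand = _guided_candidates(
        masked,
        lambda x: npoly.polyval(np.asarray(x, dtype=float), base),
        zlines,
        window_um,
        "epithelial-posterior",
        x_limits=x_lim,
        max_z_mm=anterior_z,
    )
    in_span = (zlines.x_mm >= x_lim[0]) & (zlines.x_mm <= x_lim[1])
    n_span = int(np.count_nonzero(in_span))
    if n_span and (1.0 - cand.n_valid / n_span) > MAX_INVALID_FRACTION:
        raise TraceFailureError(
            "epithelial-posterior: over half the Z-lines between the seed endpoints "
            "had no candidate — epithelium too blurry"
        )
    return robust_polyfit(cand, order=FIT_ORDER, outlier_tol_um=outlier_tol_um)


_OVERLAY_COLORS = {
    "anterior": (255, 64, 64),
    "epithelial-posterior": (64, 255, 64),
    "posterior": (64, 128, 255),
}


def render_overlay(scan: BScan, fits, out_path) -> Path:
    """Write a PNG of the B-scan with the fitted surfaces drawn over it.

    Curves are rasterised directly into the image array (no plotting
    backend), so output bytes are deterministic for identical inputs.
    """
    fits = [f for f in fits if f is not None]
    if not fits:
        raise ValueError("render_overlay needs at least one surface fit")
    if scan.frame is None:
        raise ValueError("scan has no apex frame")
    cal, frame = scan.calibration, scan.frame
    base = np.clip(scan.image, 0, 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    for fit in fits:
        color = _OVERLAY_COLORS.get(fit.surface, (255, 255, 0))
        lo, hi = fit.span_mm
        cols = np.arange(
            max(0, int(lo / cal.lateral_pitch_mm + frame.origin[1])),
            min(cal.width_px, int(hi / cal.lateral_pitch_mm + frame.origin[1]) + 1),
        )
        x = (cols - frame.origin[1]) * cal.lateral_pitch_mm
        rows = np.rint(-fit(x) / cal.axial_pitch_mm + frame.origin[0]).astype(int)
        ok = (rows >= 0) & (rows < cal.depth_px)
        rgb[rows[ok], cols[ok]] = color
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, rgb, extension=".png")
    return out_path


# ---------------------------------------------------------------------------
# Model / Results presentation


@dataclass
class SegmentationResult:
    """Converged segmentation of one B-scan.

    Carries the three surface fits, the apex frame, and per-surface
    diagnostics (iterations, inlier counts, residuals).  Thickness and
    curvature readouts live in :mod:`cornoct.profiling` and are reachable
    through :meth:`thickness_profile` and :meth:`central_radius`.
    """

    scan: BScan
    frame: MeridianFrame
    anterior: SurfaceFit
    posterior: SurfaceFit
    epithelial_posterior: SurfaceFit | None = None
    masked_fraction: float = 0.0
    zlines: ZLineSet | None = None
    n_index: float = 1.0

    @property
    def fits(self) -> dict:
        d = {"anterior": self.anterior, "posterior": self.posterior}
        if self.epithelial_posterior is not None:
            d["epithelial-posterior"] = self.epithelial_posterior
        return d

    def check_surface_order(self, x=None) -> bool:
        """anterior(x) > epithelial-posterior(x) > posterior(x) on the common span."""
        if x is None:
            lo = max(f.span_mm[0] for f in self.fits.values())
            hi = min(f.span_mm[1] for f in self.fits.values())
            x = np.linspace(lo, hi, 101)
        a = self.anterior(x)
        p = self.posterior(x)
        if self.epithelial_posterior is None:
            return bool(np.all(a > p))
        e = self.epithelial_posterior(x)
        return bool(np.all(a > e) and np.all(e > p))

    def thickness_profile(self, layer: str):
        from . import profiling

        pairs = {
            "cornea": (self.anterior, self.posterior),
            "epithelium": (self.anterior, self.epithelial_posterior),
            "stroma": (self.epithelial_posterior, self.posterior),
        }
        if layer not in pairs:
            raise ValueError(f"layer must be one of {sorted(pairs)}, got {layer!r}")
        upper, lower = pairs[layer]
        if upper is None or lower is None:
            raise ValueError(f"{layer}: epithelial surface was not segmented")
        return profiling.thickness_profile(
            upper, lower, self.zlines, n_index=self.n_index, layer=layer,
            meridian=self.frame.meridian,
        )

    def central_radius(self, surface: str):
        from . import profiling

        return profiling.central_radius(self.fits[surface], meridian=self.frame.meridian)

    def overlay(self, out_path) -> Path:
        return render_overlay(self.scan, list(self.fits.values()), out_path)

    def summary(self) -> str:
        lines = [
            "Corneal OCT segmentation",
            "=" * 60,
            f"subject: {self.scan.subject or '-'}  visit: {self.scan.visit or '-'}  "
            f"meridian: {self.frame.meridian}  eye: {self.frame.eye}",
            f"apex (row, col): ({self.frame.origin[0]:.1f}, {self.frame.origin[1]:.1f})"
            f"   masked fraction: {self.masked_fraction:.1%}",
            "-" * 60,
            f"{'surface':<22}{'inliers':>8}{'iters':>7}{'rms (um)':>10}{'max|r| (um)':>13}",
        ]
        for name, fit in self.fits.items():
            lines.append(
                f"{name:<22}{fit.n_inliers:>8}{fit.iterations:>7}"
                f"{fit.rms_residual_um:>10.2f}{fit.max_abs_residual_um:>13.2f}"
            )
        lines.append("-" * 60)
        try:
            from . import profiling

            for name, fit in self.fits.items():
                r = profiling.central_radius(fit, meridian=self.frame.meridian)
                lines.append(f"central radius {name:<22}{r.radius_mm:>8.3f} mm")
        except Exception:  # pragma: no cover - flat fits only
            pass
        ordered = self.check_surface_order()
        lines.append(f"surface ordering (ant > epi > post): {'OK' if ordered else 'VIOLATED'}")
        return "\n".join(lines)


class CornealSegmentationModel:
    """Segmentation model for one corneal B-scan.

    Parameters
    ----------
    scan : BScan
        Calibrated B-scan; the apex frame is detected during ``fit``.
    anterior_prior, posterior_prior : PriorCurve
        Topography-derived 5th-order priors in the topographer frame; they
        are apex-registered to the scan as a pair during ``fit``.
    seeds : SeedPoints, optional
        Epithelial posterior seed points (scan frame, mm).  Without seeds
        only the two outer surfaces are segmented.
    """

    def __init__(
        self,
        scan: BScan,
        anterior_prior,
        posterior_prior,
        seeds: SeedPoints | None = None,
        *,
        n_zlines: int = N_ZLINES,
        span_mm: float | None = None,
        window_um: float = SEARCH_WINDOW_UM,
        outlier_tol_um: float = OUTLIER_TOL_UM,
        upper_boundary: ConicBoundary = DEFAULT_UPPER_BOUNDARY,
        lower_boundary: ConicBoundary = DEFAULT_LOWER_BOUNDARY,
        n_index: float = 1.0,
    ) -> None:
        self.scan = scan
        self.anterior_prior = anterior_prior
        self.posterior_prior = posterior_prior
        self.seeds = seeds
        self.n_zlines = n_zlines
        self.span_mm = span_mm
        self.window_um = window_um
        self.outlier_tol_um = outlier_tol_um
        self.upper_boundary = upper_boundary
        self.lower_boundary = lower_boundary
        self.n_index = n_index

    def fit(self) -> SegmentationResult:
        from .priors import align_prior_pair

        scan = self.scan
        scan.frame = detect_apex(scan)
        masked, frac = apply_boundary_mask(scan, self.upper_boundary, self.lower_boundary)
        zlines = sample_zlines(scan.calibration, self.n_zlines, self.span_mm)
        ant_prior, post_prior = align_prior_pair(
            self.anterior_prior, self.posterior_prior, scan.frame
        )
        ant_fit = robust_polyfit(
            trace_surface(masked, ant_prior, zlines, self.window_um, surface="anterior"),
            outlier_tol_um=self.outlier_tol_um,
        )
        post_fit = robust_polyfit(
            trace_surface(masked, post_prior, zlines, self.window_um, surface="posterior"),
            outlier_tol_um=self.outlier_tol_um,
        )
        epi_fit = None
        if self.seeds is not None:
            epi_fit = detect_epithelium(
                masked, self.seeds, zlines, ant_fit, self.window_um, self.outlier_tol_um
            )
        return SegmentationResult(
            scan=scan,
            frame=scan.frame,
            anterior=ant_fit,
            posterior=post_fit,
            epithelial_posterior=epi_fit,
            masked_fraction=frac,
            zlines=zlines,
            n_index=self.n_index,
        )
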