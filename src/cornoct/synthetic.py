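"""Synthetic corneal B-scans with known ground truth.

Generates conic corneal geometries, renders them into OCT-like images
(bright Gaussian interface bands over a speckled stromal background),
emits matching topography elevation profiles and epithelial seed points,
and simulates paired pre/post cohorts for end-to-end validation of the
segmentation and statistics pipeline.

Defaults encode a typical young orthokeratology cohort: anterior apical
radius 7.86 mm (horizontal) / 7.60 mm (vertical), epithelium 53.6 um,
stroma 515.7 um, 45 subjects, central epithelial thinning of 12.8 um
(zone mean) after one month of lens wear.

The configured epithelial/stromal change is interpreted as the induced
*central-zone mean* change (|x| <= 1 mm); the Gaussian-bump peak applied
to the thickness profile is scaled accordingly, so manifest truth means
equal the configured change exactly on the detection grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import ConicBoundary, ScanCalibration, conic_sag
from .priors import ElevationProfile
from .segmentation import BScan, SeedPoints, sample_zlines

__all__ = [
    "ThicknessSpec",
    "GroundTruth",
    "RenderSpec",
    "ChangeModel",
    "CohortSpec",
    "make_ground_truth",
    "render_bscan",
    "make_priors_and_seeds",
    "simulate_cohort",
    "SimulatedCohort",
    "half_resolution",
]

# cohort-level defaults (um / mm)
EPI_BASELINE_UM = 53.6
EPI_BASELINE_SD_UM = 4.2
STROMA_BASELINE_UM = 515.7
STROMA_BASELINE_SD_UM = 28.1
EPI_CHANGE_UM = -12.8
EPI_CHANGE_SD_UM = 6.0
STROMA_CHANGE_UM = 4.8
STROMA_CHANGE_SD_UM = 16.1
ANTERIOR_R_MM = {"horizontal": 7.86, "vertical": 7.60}
ANTERIOR_R_SD_MM = 0.27
ANTERIOR_R_CHANGE_MM = {"horizontal": 0.24, "vertical": 0.34}
ANTERIOR_Q = -0.2
N_SUBJECTS = 45
VALID_HALF_SPAN_MM = 4.465  # half the 8.93 mm scan width


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ThicknessSpec:
    """Layer thickness profile: baseline plus an optional central Gaussian bump.

    ``t(x) = baseline + amplitude * exp(-x^2 / (2 width^2))`` (um; negative
    amplitude thins the layer at the centre).
    """

    baseline_um: float
    bump_amplitude_um: float = 0.0
    bump_width_mm: float = 1.0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        t = self.baseline_um + self.bump_amplitude_um * np.exp(
            -(x**2) / (2.0 * self.bump_width_mm**2)
        )
        return float(t) if t.ndim == 0 else t


@dataclass(frozen=True)
class GroundTruth:
    """Known corneal geometry of one meridian.

    Surfaces are derived axially from the anterior conic: the epithelial
    posterior sits ``t_epi(x)`` below the anterior sag, the corneal
    posterior ``t_epi(x) + t_str(x)`` below — consistent with the axial
    thickness definition used by the profiling stage.
    """

    anterior: ConicBoundary
    t_epi: ThicknessSpec
    t_str: ThicknessSpec
    meridian: str = "horizontal"

    def anterior_z(self, x):
        return conic_sag(x, self.anterior)

    def epithelial_posterior_z(self, x):
        return self.anterior_z(x) - np.asarray(self.t_epi(x)) / 1000.0

    def posterior_z(self, x):
        return self.anterior_z(x) - (np.asarray(self.t_epi(x)) + np.asarray(self.t_str(x))) / 1000.0

    def surface_z(self, surface: str, x):
        return {
            "anterior": self.anterior_z,
            "epithelial-posterior": self.epithelial_posterior_z,
            "posterior": self.posterior_z,
        }[surface](x)


def make_ground_truth(
    anterior: ConicBoundary | None = None,
    t_epi: ThicknessSpec | float = EPI_BASELINE_UM,
    t_str: ThicknessSpec | float = STROMA_BASELINE_UM,
    meridian: str = "horizontal",
) -> GroundTruth:
    """Assemble a ground-truth geometry, validating layer positivity.

    Raises :class:`GeometryError` if either layer's thickness is
    non-positive anywhere on the scanned half-span (crossing surfaces).
    """
    if anterior is None:
        anterior = ConicBoundary(R=ANTERIOR_R_MM["horizontal"], Q=ANTERIOR_Q, T=0.0)
    if not isinstance(t_epi, ThicknessSpec):
        t_epi = ThicknessSpec(baseline_um=float(t_epi))
    if not isinstance(t_str, ThicknessSpec):
        t_str = ThicknessSpec(baseline_um=float(t_str))
    x = np.linspace(-VALID_HALF_SPAN_MM, VALID_HALF_SPAN_MM, 257)
    for name, spec in (("epithelium", t_epi), ("stroma", t_str)):
        t = spec(x)
        if np.any(t <= 0):
            raise GeometryError(
                f"{name} thickness becomes non-positive (min {np.min(t):.1f} um): "
                "surfaces would cross"
            )
    return GroundTruth(anterior=anterior, t_epi=t_epi, t_str=t_str, meridian=meridian)


@dataclass(frozen=True)
class RenderSpec:
    """How a ground-truth geometry is rasterised into an OCT-like image.

    Interface reflectivity ordering mimics anterior-segment OCT contrast:
    the anterior band is brightest (with a specular highlight at the apex),
    the posterior band intermediate, the epithelial posterior band dimmest
    — making the epithelial step genuinely the hardest, as in clinical
    scans.  ``band_sigma_um`` defaults to the instrument's 3 um axial
    resolution.  ``speckle_shape`` is the gamma shape of multiplicative
    speckle (None disables); ``additive_sigma`` is grey-level Gaussian
    noise (0 disables).
    """

    calibration: ScanCalibration = field(default_factory=ScanCalibration)
    peak_anterior: float = 235.0
    peak_epithelial: float = 110.0
    peak_posterior: float = 170.0
    band_sigma_um: float = 3.0
    background: float = 55.0
    speckle_shape: float | None = 4.0
    additive_sigma: float = 2.0
    apex_row_frac: float = 0.12
    apex_highlight_amp: float = 2.0
    apex_highlight_width_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_sigma_um <= 0:
            raise ValueError("band_sigma_um must be > 0")
        for v in (self.peak_anterior, self.peak_epithelial, self.peak_posterior):
            if not 0 < v <= 255:
                raise ValueError("band peak intensities must lie in (0, 255]")


def noise_free(spec: RenderSpec) -> RenderSpec:
    return replace(spec, speckle_shape=None, additive_sigma=0.0)


def half_resolution(cal: ScanCalibration | None = None) -> ScanCalibration:
    """Half-pixel-count calibration over the same physical extent."""
    cal = cal or ScanCalibration()
    return ScanCalibration(
        width_px=cal.width_px // 2,
        depth_px=cal.depth_px // 2,
        width_mm=cal.width_mm,
        depth_mm=cal.depth_mm,
    )


def render_bscan(
    gt: GroundTruth, spec: RenderSpec, subject: str = "", visit: str = ""
) -> tuple[BScan, dict]:
    """Rasterise a ground-truth geometry into a B-scan plus truth sidecar.

    Each interface is drawn as a Gaussian axial intensity band centred on
    the true surface; the stroma between the outer surfaces is filled at
    the background level.  Raises if the apex falls outside the axial field
    of view.  All noise flows from ``spec.seed``.
    """
    cal = spec.calibration
    r0 = int(round(spec.apex_row_frac * cal.depth_px))
    c0 = cal.width_px // 2
    cols = np.arange(cal.width_px)
    rows = np.arange(cal.depth_px)
    x = (cols - c0) * cal.lateral_pitch_mm
    z = -(rows - r0) * cal.axial_pitch_mm
    z_a = np.asarray(gt.anterior_z(x))
    z_e = np.asarray(gt.epithelial_posterior_z(x))
    z_p = np.asarray(gt.posterior_z(x))
    if z_a[c0] > z.max() or z_a[c0] < z.min():
        raise GeometryError("anterior apex outside the axial field of view")
    sigma_mm = spec.band_sigma_um / 1000.0
    zz = z[:, None]
    img = np.where((zz <= z_a[None, :]) & (zz >= z_p[None, :]), spec.background, 0.0)
    highlight = 1.0 + spec.apex_highlight_amp * np.exp(
        -(x**2) / (2.0 * spec.apex_highlight_width_mm**2)
    )
    # interface bands dominate tissue scatter locally (max compositing), so
    # the axial brightness peak sits exactly on the true surface
    for z_s, peak in (
        (z_a, spec.peak_anterior * highlight),
        (z_e, spec.peak_epithelial),
        (z_p, spec.peak_posterior),
    ):
        band = peak * np.exp(-((zz - z_s[None, :]) ** 2) / (2.0 * sigma_mm**2))
        img = np.maximum(img, band)
    rng = np.random.default_rng(spec.seed)
    if spec.speckle_shape is not None:
        img *= rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, img.shape)
    if spec.additive_sigma > 0:
        img += rng.normal(0.0, spec.additive_sigma, img.shape)
    img = np.clip(img, 0.0, 255.0)
    scan = BScan(
        image=img, calibration=cal, meridian=gt.meridian, subject=subject, visit=visit
    )
    zl = sample_zlines(cal)
    truth = {
        "apex_row": r0,
        "apex_col": c0,
        "anterior": {"R": gt.anterior.R, "Q": gt.anterior.Q, "T": gt.anterior.T},
        "t_epi": vars(gt.t_epi).copy(),
        "t_str": vars(gt.t_str).copy(),
        "meridian": gt.meridian,
        "zline_x_mm": zl.x_mm.tolist(),
        "zline_anterior_z_mm": np.asarray(gt.anterior_z(zl.x_mm)).tolist(),
        "zline_epithelial_z_mm": np.asarray(gt.epithelial_posterior_z(zl.x_mm)).tolist(),
        "zline_posterior_z_mm": np.asarray(gt.posterior_z(zl.x_mm)).tolist(),
    }
    return scan, truth


def make_priors_and_seeds(
    gt: GroundTruth,
    noise_um: float = 1.0,
    n_seeds: int = 5,
    seed: int = 0,
    prior_span_mm: float = 8.0,
    prior_step_mm: float = 0.25,
    seed_span_mm: float = 5.0,
    seed_jitter_um: float = 3.0,
) -> tuple[ElevationProfile, ElevationProfile, SeedPoints]:
    """Emulated topography elevation profiles and epithelial seed points.

    Elevations are the true anterior/posterior surfaces sampled on a
    regular grid with Gaussian noise (default 1 um).  Seeds sit on the true
    epithelial posterior surface at the two ends of the visible span plus
    evenly spaced interior points, each displaced by at most
    ``seed_jitter_um``.
    """
    if n_seeds < 5:
        raise ValueError(f"at least 5 seed points are required, got {n_seeds}")
    rng = np.random.default_rng(seed)
    half = prior_span_mm / 2.0
    xs = np.arange(-half, half + prior_step_mm / 2, prior_step_mm)
    profiles = []
    for surface, fn in (("anterior", gt.anterior_z), ("posterior", gt.posterior_z)):
        zs = np.asarray(fn(xs)) + rng.normal(0.0, noise_um / 1000.0, xs.shape)
        profiles.append(
            ElevationProfile(surface=surface, meridian=gt.meridian, x_mm=xs, z_mm=zs)
        )
    sx = np.linspace(-seed_span_mm / 2.0, seed_span_mm / 2.0, n_seeds)
    jitter = rng.uniform(-seed_jitter_um, seed_jitter_um, n_seeds) / 1000.0
    sz = np.asarray(gt.epithelial_posterior_z(sx)) + jitter
    return profiles[0], profiles[1], SeedPoints(x_mm=sx, z_mm=sz)


@dataclass(frozen=True)
class ChangeModel:
    """Per-subject pre-to-post change: fixed, or drawn N(mean, sd)."""

    mean: float
    sd: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return self.mean
        return float(rng.normal(self.mean, self.sd))


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a simulated pre/post cohort.

    Baselines and changes default to a typical one-month orthokeratology
    cohort: 45 subjects, epithelium 53.6 +/- 4.2 um thinning by
    12.8 +/- 6.0 um (central-zone mean), stroma 515.7 +/- 28.1 um changing
    by +4.8 um, anterior radius 7.86/7.60 mm (h/v) increasing by
    0.24/0.34 mm.  Set a change model's sd to 0 for a fixed-change cohort.
    """

    n_subjects: int = N_SUBJECTS
    epi_baseline: ChangeModel = ChangeModel(EPI_BASELINE_UM, EPI_BASELINE_SD_UM)
    stroma_baseline: ChangeModel = ChangeModel(STROMA_BASELINE_UM, STROMA_BASELINE_SD_UM)
    epi_change: ChangeModel = ChangeModel(EPI_CHANGE_UM, EPI_CHANGE_SD_UM)
    stroma_change: ChangeModel = ChangeModel(STROMA_CHANGE_UM, STROMA_CHANGE_SD_UM)
    radius_change_h: ChangeModel = ChangeModel(ANTERIOR_R_CHANGE_MM["horizontal"], 0.0)
    radius_change_v: ChangeModel = ChangeModel(ANTERIOR_R_CHANGE_MM["vertical"], 0.0)
    radius_baseline_h: ChangeModel = ChangeModel(ANTERIOR_R_MM["horizontal"], ANTERIOR_R_SD_MM)
    radius_baseline_v: ChangeModel = ChangeModel(ANTERIOR_R_MM["vertical"], ANTERIOR_R_SD_MM)
    asphericity: float = ANTERIOR_Q
    epi_bump_width_mm: float = 1.0
    stroma_bump_width_mm: float = 2.0
    meridians: tuple[str, ...] = ("horizontal", "vertical")
    render: RenderSpec = field(default_factory=RenderSpec)
    n_zlines: int = 129
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs n >= 2 subjects")


def _zone_bump_factor(cal: ScanCalibration, n_zlines: int, width_mm: float) -> float:
    """Mean of the unit Gaussian bump over the central-zone Z-lines."""
    zl = sample_zlines(cal, n_zlines)
    x = zl.x_mm[np.abs(zl.x_mm) <= 1.0]
    return float(np.mean(np.exp(-(x**2) / (2.0 * width_mm**2))))


@dataclass
class SubjectRecord:
    subject: str
    truths: dict  # (meridian, visit) -> GroundTruth
    scans: dict  # (meridian, visit) -> BScan
    priors: dict  # (meridian, visit) -> (anterior ElevationProfile, posterior ElevationProfile)
    seeds: dict  # (meridian, visit) -> SeedPoints


@dataclass
class SimulatedCohort:
    """A rendered pre/post cohort plus its ground-truth manifest."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    manifest: pd.DataFrame

    def write(self, out_dir) -> Path:
        """Persist scans (TIFF), priors/seeds (CSV) and the manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in self.subjects:
            for (meridian, visit), scan in rec.scans.items():
                stem = f"{rec.subject}_{visit}_{meridian}"
                tifffile.imwrite(out / f"{stem}.tiff", scan.image.astype(np.uint8))
                with open(out / f"{stem}.json", "w") as fh:
                    json.dump(
                        scan.calibration.to_dict()
                        | {"meridian": meridian, "eye": "OD", "subject": rec.subject, "visit": visit},
                        fh,
                        indent=1,
                    )
                ant, post = rec.priors[(meridian, visit)]
                for prof, tag in ((ant, "anterior"), (post, "posterior")):
                    pd.DataFrame(
                        {
                            "x_mm": prof.x_mm,
                            "z_mm": prof.z_mm,
                            "surface": prof.surface,
                            "meridian": prof.meridian,
                        }
                    ).to_csv(out / f"{stem}_{tag}.csv", index=False)
                sp = rec.seeds[(meridian, visit)]
                pd.DataFrame({"x_mm": sp.x_mm, "z_mm": sp.z_mm}).to_csv(
                    out / f"{stem}_seeds.csv", index=False
                )
        self.manifest.to_csv(out / "manifest.csv", index=False)
        return out


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw, build and render a paired pre/post cohort.

    Per subject: baseline thicknesses and per-meridian anterior radii are
    drawn, the change models produce the post-wear truth (central
    epithelial/stromal Gaussian-bump change calibrated to the configured
    zone-mean, anterior radius shift), and all meridian x visit scans are
    rendered with subject-specific seeds derived from ``spec.seed``.
    The manifest records the true central-zone changes per subject.
    """
    master = np.random.SeedSequence(spec.seed)
    subject_seeds = master.spawn(spec.n_subjects)
    cal = spec.render.calibration
    f_epi = _zone_bump_factor(cal, spec.n_zlines, spec.epi_bump_width_mm)
    f_str = _zone_bump_factor(cal, spec.n_zlines, spec.stroma_bump_width_mm)
    subjects: list[SubjectRecord] = []
    rows = []
    for i, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        sid = f"S{i + 1:03d}"
        epi0 = spec.epi_baseline.draw(rng)
        str0 = spec.stroma_baseline.draw(rng)
        d_epi = spec.epi_change.draw(rng)
        d_str = spec.stroma_change.draw(rng)
        r0 = {"horizontal": spec.radius_baseline_h.draw(rng), "vertical": spec.radius_baseline_v.draw(rng)}
        dr = {"horizontal": spec.radius_change_h.draw(rng), "vertical": spec.radius_change_v.draw(rng)}
        truths, scans, priors, seeds = {}, {}, {}, {}
        for meridian in spec.meridians:
            for visit in ("pre", "post"):
                change = visit == "post"
                gt = make_ground_truth(
                    anterior=ConicBoundary(
                        R=r0[meridian] + (dr[meridian] if change else 0.0),
                        Q=spec.asphericity,
                        T=0.0,
                    ),
                    t_epi=ThicknessSpec(
                        epi0,
                        bump_amplitude_um=(d_epi / f_epi) if change else 0.0,
                        bump_width_mm=spec.epi_bump_width_mm,
                    ),
                    t_str=ThicknessSpec(
                        str0,
                        bump_amplitude_um=(d_str / f_str) if change else 0.0,
                        bump_width_mm=spec.stroma_bump_width_mm,
                    ),
                    meridian=meridian,
                )
                render_seed = int(rng.integers(0, 2**31 - 1))
                scan, _ = render_bscan(
                    gt, replace(spec.render, seed=render_seed), subject=sid, visit=visit
                )
                ant, post, sp = make_priors_and_seeds(
                    gt, seed=int(rng.integers(0, 2**31 - 1))
                )
                truths[(meridian, visit)] = gt
                scans[(meridian, visit)] = scan
                priors[(meridian, visit)] = (ant, post)
                seeds[(meridian, visit)] = sp
        subjects.append(SubjectRecord(sid, truths, scans, priors, seeds))
        rows.append(
            {
                "subject": sid,
                "epi_baseline_um": epi0,
                "stroma_baseline_um": str0,
                "epi_change_central_um": d_epi,
                "stroma_change_central_um": d_str,
                "radius_h_pre_mm": r0["horizontal"],
                "radius_v_pre_mm": r0["vertical"],
                "radius_h_change_mm": dr["horizontal"],
                "radius_v_change_mm": dr["vertical"],
            }
        )
    return SimulatedCohort(spec=spec, subjects=subjects, manifest=pd.DataFrame(rows))
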