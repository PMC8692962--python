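"""End-to-end workflows: simulate -> segment -> profile -> cohort.

`analyze_cohort` drives the full measurement chain over a simulated (or
loaded) cohort in memory; `run_pipeline` is the configuration-driven
variant behind the command line, writing artifacts to disk.  Scans whose
trace or fit fails are excluded and counted — mirroring the clinical
practice of dropping unsegmentable images — never silently imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import profiling
from .cohort import CohortTable, PairedCohort, PairedCohortResult
from .priors import fit_prior
from .segmentation import (
    ConvergenceError,
    CornealSegmentationModel,
    SegmentationResult,
    TraceFailureError,
)
from .synthetic import CohortSpec, SimulatedCohort, simulate_cohort

log = logging.getLogger("cornoct")

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort", "CohortAnalysis"]

LAYERS = ("epithelium", "stroma", "cornea")
SURFACES = ("anterior", "epithelial-posterior", "posterior")


@dataclass
class RunConfig:
    """One config object holding every tunable constant of the pipeline.

    Algorithm parameters default to the published operating point:
    129 Z-lines, +/-10 um search window, 7 um outlier tolerance, 2.5 um
    prior RMS gate, upper boundary (R 10 mm, Q -0.2, T 0.01 mm), lower
    boundary (R 5 mm, Q -0.1, T -0.8 mm), refractive index 1.0.
    """

    out_dir: str = "cornoct_out"
    n_subjects: int = 45
    n_zlines: int = 129
    window_um: float = 10.0
    outlier_tol_um: float = 7.0
    prior_rms_gate_um: float = 2.5
    upper_boundary: tuple[float, float, float] = (10.0, -0.2, 0.01)  # R, Q, T
    lower_boundary: tuple[float, float, float] = (5.0, -0.1, -0.8)
    n_index: float = 1.0
    half_resolution: bool = False
    render_noise: bool = True
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_zlines % 2 == 0:
            raise ValueError("n_zlines must be odd")
        for name in ("window_um", "outlier_tol_um", "prior_rms_gate_um", "n_index"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("upper_boundary", "lower_boundary"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")  # where results land does not change what they are
        doc.pop("verbosity")
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CohortAnalysis:
    """Measured cohort: tidy table, per-layer profiles, fit diagnostics."""

    table: CohortTable
    profiles: dict  # (layer, meridian, visit) -> {subject: ThicknessProfile}
    results: dict  # (subject, meridian, visit) -> SegmentationResult
    excluded: list  # (subject, meridian, visit, reason)
    cohort_result: PairedCohortResult | None = None

    def fit_cohort(self) -> PairedCohortResult:
        self.cohort_result = PairedCohort(self.table).fit()
        return self.cohort_result


def _segment_one(rec, meridian, visit, cfg: RunConfig | None = None) -> SegmentationResult:
    from .calibration import ConicBoundary

    kwargs = {}
    if cfg is not None:
        kwargs = dict(
            n_zlines=cfg.n_zlines,
            window_um=cfg.window_um,
            outlier_tol_um=cfg.outlier_tol_um,
            upper_boundary=ConicBoundary(*cfg.upper_boundary),
            lower_boundary=ConicBoundary(*cfg.lower_boundary),
            n_index=cfg.n_index,
        )
    ant_prof, post_prof = rec.priors[(meridian, visit)]
    model = CornealSegmentationModel(
        rec.scans[(meridian, visit)],
        fit_prior(ant_prof),
        fit_prior(post_prof),
        seeds=rec.seeds[(meridian, visit)],
        **kwargs,
    )
    return model.fit()


def analyze_cohort(sim: SimulatedCohort, cfg: RunConfig | None = None) -> CohortAnalysis:
    """Segment every scan of a cohort and assemble the paired-stats table.

    Per subject and visit the two meridian thickness profiles are
    harmonized at the centre, central-zone values are pooled across
    meridians, paracentral summaries stay per meridian, and central radii
    are taken per surface and meridian.  Subjects losing any scan to a
    trace/convergence failure are excluded from the affected measures.
    """
    rows = []
    profiles: dict = {}
    results: dict = {}
    excluded = []
    for rec in sim.subjects:
        seg: dict = {}
        failed = False
        for (meridian, visit) in rec.scans:
            try:
                seg[(meridian, visit)] = _segment_one(rec, meridian, visit, cfg)
            except (TraceFailureError, ConvergenceError, ValueError) as exc:
                excluded.append((rec.subject, meridian, visit, str(exc)))
                log.warning("excluding %s %s/%s: %s", rec.subject, meridian, visit, exc)
                failed = True
        if failed:
            continue
        results.update({(rec.subject, m, v): s for (m, v), s in seg.items()})
        meridians = sorted({m for (m, _) in seg})
        for visit in ("pre", "post"):
            layer_profiles = {}
            for layer in LAYERS:
                per_meridian = {m: seg[(m, visit)].thickness_profile(layer) for m in meridians}
                if len(meridians) == 2:
                    h, v = per_meridian["horizontal"], per_meridian["vertical"]
                    h, v = profiling.harmonize_meridians(h, v)
                    per_meridian = {"horizontal": h, "vertical": v}
                layer_profiles[layer] = per_meridian
                for m, prof in per_meridian.items():
                    profiles.setdefault((layer, m, visit), {})[rec.subject] = prof
                # central zone: pool both meridians' positions
                vals = np.concatenate(
                    [
                        prof.thickness_um[np.abs(prof.x_mm) <= 1.0]
                        for prof in per_meridian.values()
                    ]
                )
                rows.append(
                    {
                        "subject": rec.subject,
                        "visit": visit,
                        "kind": "thickness",
                        "name": layer,
                        "meridian": "both",
                        "zone": "central",
                        "value": float(vals.mean()),
                    }
                )
                for m, prof in per_meridian.items():
                    zs = profiling.zone_summary(prof, "paracentral")
                    rows.append(
                        {
                            "subject": rec.subject,
                            "visit": visit,
                            "kind": "thickness",
                            "name": layer,
                            "meridian": m,
                            "zone": "paracentral",
                            "value": zs.mean_um,
                        }
                    )
            for m in meridians:
                for surface in SURFACES:
                    r = seg[(m, visit)].central_radius(surface)
                    rows.append(
                        {
                            "subject": rec.subject,
                            "visit": visit,
                            "kind": "radius",
                            "name": surface,
                            "meridian": m,
                            "zone": "",
                            "value": r.radius_mm,
                        }
                    )
    if not rows:
        raise RuntimeError("every subject failed segmentation — nothing to analyse")
    table = CohortTable(pd.DataFrame(rows))
    return CohortAnalysis(table=table, profiles=profiles, results=results, excluded=excluded)


def run_pipeline(config: RunConfig) -> Path:
    """Configuration-driven end-to-end run writing artifacts to disk.

    Simulates a cohort under the configured conditions, segments every
    scan, and writes the manifest, per-scan fits, cohort table and summary
    tables (tagged with the config hash) under ``config.out_dir``.
    """
    from .io import write_fit_json
    from .synthetic import RenderSpec, half_resolution

    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    render = RenderSpec()
    if config.half_resolution:
        render = dataclasses.replace(render, calibration=half_resolution())
    if not config.render_noise:
        render = dataclasses.replace(render, speckle_shape=None, additive_sigma=0.0)
    spec = CohortSpec(
        n_subjects=config.n_subjects, render=render, n_zlines=config.n_zlines, seed=config.seed
    )
    sim = simulate_cohort(spec)
    try:
        analysis = analyze_cohort(sim, config)
    except RuntimeError as exc:
        (out / "FAILED").write_text(str(exc))
        raise
    sim.manifest.to_csv(out / "manifest.csv", index=False)
    for (subject, meridian, visit), seg in analysis.results.items():
        write_fit_json(
            list(seg.fits.values()), out / "fits" / f"{subject}_{visit}_{meridian}.json"
        )
        log.info(
            "%s %s/%s: inliers %s, iterations %s",
            subject,
            meridian,
            visit,
            {k: f.n_inliers for k, f in seg.fits.items()},
            {k: f.iterations for k, f in seg.fits.items()},
        )
    analysis.table.data.assign(config_hash=chash).to_csv(out / "cohort.csv", index=False)
    res = analysis.fit_cohort()
    for name, frame in res.tables.items():
        frame.assign(config_hash=chash).to_csv(out / f"table_{name}.csv", index=False)
    (out / "summary.txt").write_text(res.summary() + "\n")
    if analysis.excluded:
        pd.DataFrame(
            analysis.excluded, columns=["subject", "meridian", "visit", "reason"]
        ).to_csv(out / "excluded.csv", index=False)
        log.warning("%d scan(s) excluded", len(analysis.excluded))
    return out
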