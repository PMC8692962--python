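"""Readers and writers for scans, seeds, fits and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import ScanCalibration
from .segmentation import BScan, SeedPoints, SurfaceFit

__all__ = ["read_bscan", "read_seeds_csv", "write_fit_json", "read_fit_json", "write_results"]


def read_bscan(path, sidecar=None) -> BScan:
    """Load a single-channel 8/16-bit TIFF or PNG as a calibrated B-scan.

    16-bit input is linearly rescaled to the 0-255 working range; RGB and
    float images are rejected.  ``sidecar`` is the JSON calibration file
    (defaults to ``<path stem>.json`` next to the image, or the nominal
    2048x1365 / 8.93x2.00 mm calibration if absent).
    """
    path = Path(path)
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {img.shape}")
    if img.dtype == np.uint8:
        data = img.astype(float)
    elif img.dtype == np.uint16:
        data = img.astype(float) * (255.0 / 65535.0)
    else:
        raise ValueError(f"{path}: unsupported dtype {img.dtype} (need uint8 or uint16)")
    meta = {}
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if sidecar.exists():
        cal = ScanCalibration.from_sidecar(sidecar)
        with open(sidecar) as fh:
            meta = json.load(fh)
    else:
        cal = ScanCalibration()
    return BScan(
        image=data,
        calibration=cal,
        meridian=meta.get("meridian", "horizontal"),
        eye=meta.get("eye", "OD"),
        subject=meta.get("subject", ""),
        visit=meta.get("visit", ""),
    )


def read_seeds_csv(path) -> SeedPoints:
    """Seed CSV with columns x_mm, z_mm (sorted by x on read)."""
    df = pd.read_csv(path)
    missing = {"x_mm", "z_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"seeds CSV {path} missing columns: {sorted(missing)}")
    df = df.sort_values("x_mm")
    return SeedPoints(x_mm=df["x_mm"].to_numpy(float), z_mm=df["z_mm"].to_numpy(float))


def write_fit_json(fits, path) -> Path:
    """Serialise surface fits to a JSON document (mm, 6-decimal x grid)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {f.surface: f.to_dict() for f in fits if f is not None}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    return path


def read_fit_json(path) -> dict[str, SurfaceFit]:
    with open(path) as fh:
        doc = json.load(fh)
    out = {}
    for surface, d in doc.items():
        x = np.asarray(d["inlier_x_mm"], dtype=float)
        coeffs = np.asarray(d["coeffs_mm"], dtype=float)
        from numpy.polynomial import polynomial as npoly

        out[surface] = SurfaceFit(
            surface=d["surface"],
            order=d["order"],
            coeffs=coeffs,
            inlier_x_mm=x,
            inlier_z_mm=npoly.polyval(x, coeffs),
            iterations=d["iterations"],
            max_abs_residual_um=d["max_abs_residual_um"],
            rms_residual_um=d["rms_um"],
        )
    return out


def write_results(out_dir, fits=None, profiles=None, summaries=None, radii=None, stem="scan"):
    """Write the per-scan result set: fit JSON plus profile/summary/radii CSVs.

    Column orders and numeric formatting are fixed (6-decimal mm, 2-decimal
    um) so rewrites are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if fits:
        written.append(write_fit_json(fits, out / f"{stem}_fits.json"))
    if profiles:
        rows = [
            {
                "layer": p.layer,
                "meridian": p.meridian,
                "x_mm": round(float(x), 6),
                "thickness_um": round(float(t), 2),
            }
            for p in profiles
            for x, t in zip(p.x_mm, p.thickness_um)
        ]
        f = out / f"{stem}_profiles.csv"
        pd.DataFrame(rows, columns=["layer", "meridian", "x_mm", "thickness_um"]).to_csv(
            f, index=False
        )
        written.append(f)
    if summaries:
        rows = [
            {
                "zone": s.zone,
                "meridian": s.meridian,
                "layer": s.layer,
                "mean_um": round(s.mean_um, 2),
                "sd_um": round(s.sd_um, 2),
                "n_positions": s.n_positions,
            }
            for s in summaries
        ]
        f = out / f"{stem}_zones.csv"
        pd.DataFrame(rows, columns=["zone", "meridian", "layer", "mean_um", "sd_um", "n_positions"]).to_csv(
            f, index=False
        )
        written.append(f)
    if radii:
        rows = [
            {"surface": r.surface, "meridian": r.meridian, "radius_mm": round(r.radius_mm, 6)}
            for r in radii
        ]
        f = out / f"{stem}_radii.csv"
        pd.DataFrame(rows, columns=["surface", "meridian", "radius_mm"]).to_csv(f, index=False)
        written.append(f)
    return written
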