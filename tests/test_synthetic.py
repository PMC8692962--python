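"""Ground-truth geometries, B-scan rendering and cohort simulation."""

from dataclasses import replace

import numpy as np
import pytest

from cornoct.calibration import ConicBoundary
from cornoct.priors import fit_prior
from cornoct.synthetic import (
    ChangeModel,
    CohortSpec,
    GeometryError,
    RenderSpec,
    ThicknessSpec,
    half_resolution,
    make_ground_truth,
    make_priors_and_seeds,
    render_bscan,
    simulate_cohort,
)


class TestGroundTruth:
    def test_baseline_corneal_thickness(self):
        """Uniform 53.6 um epithelium + 515.7 um stroma: 569.3 um cornea everywhere."""
        gt = make_ground_truth()
        x = np.linspace(-3, 3, 41)
        total = (np.asarray(gt.anterior_z(x)) - np.asarray(gt.posterior_z(x))) * 1000
        np.testing.assert_allclose(total, 569.3, atol=1e-9)

    def test_crossing_surfaces_rejected(self):
        with pytest.raises(GeometryError):
            make_ground_truth(t_epi=ThicknessSpec(53.6, bump_amplitude_um=-60.0))

    def test_zero_perturbation_is_identity(self):
        gt0 = make_ground_truth(t_epi=ThicknessSpec(53.6))
        gt1 = make_ground_truth(t_epi=ThicknessSpec(53.6, bump_amplitude_um=0.0))
        x = np.linspace(-4, 4, 21)
        np.testing.assert_allclose(gt0.epithelial_posterior_z(x), gt1.epithelial_posterior_z(x))

    def test_surface_ordering(self):
        gt = make_ground_truth(t_epi=ThicknessSpec(53.6, bump_amplitude_um=-15.0))
        x = np.linspace(-4, 4, 81)
        assert np.all(np.asarray(gt.anterior_z(x)) > np.asarray(gt.epithelial_posterior_z(x)))
        assert np.all(
            np.asarray(gt.epithelial_posterior_z(x)) > np.asarray(gt.posterior_z(x))
        )


class TestRenderBScan:
    def test_noise_free_argmax_on_surface(self, clean_spec):
        """Column-wise brightest pixel within half an axial pixel of the anterior truth.

        The apex reflex is disabled: its saturated plateau ties the argmax
        across several rows, which is a display artifact, not a surface shift.
        """
        gt = make_ground_truth()
        scan, truth = render_bscan(gt, replace(clean_spec, apex_highlight_amp=0.0))
        cal = scan.calibration
        x = np.array(truth["zline_x_mm"])
        cols = np.rint(x / cal.lateral_pitch_mm + truth["apex_col"]).astype(int)
        ok = (cols >= 0) & (cols < cal.width_px)
        # truth evaluated at the snapped column's exact lateral position
        x_col = (cols[ok] - truth["apex_col"]) * cal.lateral_pitch_mm
        z_true = np.asarray(gt.anterior_z(x_col))
        rows = np.argmax(scan.image[:, cols[ok]], axis=0)
        z_px = -(rows - truth["apex_row"]) * cal.axial_pitch_mm
        err = np.abs(z_px - z_true)
        assert np.max(err) <= cal.axial_pitch_mm / 2 + 1e-12

    def test_same_seed_identical_images(self, default_truth):
        spec = replace(RenderSpec(calibration=half_resolution()), seed=5)
        a, _ = render_bscan(default_truth, spec)
        b, _ = render_bscan(default_truth, spec)
        np.testing.assert_array_equal(a.image, b.image)

    def test_different_seed_differs(self, default_truth):
        spec = RenderSpec(calibration=half_resolution())
        a, _ = render_bscan(default_truth, replace(spec, seed=1))
        b, _ = render_bscan(default_truth, replace(spec, seed=2))
        assert not np.array_equal(a.image, b.image)

    def test_apex_outside_fov_rejected(self, clean_spec):
        gt = make_ground_truth(anterior=ConicBoundary(R=7.86, Q=-0.2, T=-3.0))
        with pytest.raises(GeometryError, match="field of view"):
            render_bscan(gt, clean_spec)

    def test_truth_sidecar_additivity(self, clean_scan):
        _, truth = clean_scan
        ant = np.array(truth["zline_anterior_z_mm"])
        epi = np.array(truth["zline_epithelial_z_mm"])
        post = np.array(truth["zline_posterior_z_mm"])
        x = np.array(truth["zline_x_mm"])
        gt = make_ground_truth()
        np.testing.assert_allclose((ant - epi) * 1000, gt.t_epi(x), atol=1e-12)
        np.testing.assert_allclose((epi - post) * 1000, gt.t_str(x), atol=1e-12)


class TestPriorsAndSeeds:
    def test_noise_free_priors_fit_exactly(self, default_truth):
        ant, post, _ = make_priors_and_seeds(default_truth, noise_um=0.0, seed=0)
        assert fit_prior(ant).rms_error_um < 0.5  # conic-vs-quintic truncation only
        assert fit_prior(post).rms_error_um < 0.5

    def test_seed_endpoints_at_span_ends(self, default_truth):
        _, _, seeds = make_priors_and_seeds(default_truth, n_seeds=5, seed=0)
        assert seeds.x_mm[0] == -2.5
        assert seeds.x_mm[-1] == 2.5
        assert len(seeds) == 5

    def test_seeds_within_jitter_of_truth(self, default_truth):
        _, _, seeds = make_priors_and_seeds(default_truth, seed=3)
        z_true = np.asarray(default_truth.epithelial_posterior_z(seeds.x_mm))
        assert np.max(np.abs(seeds.z_mm - z_true)) * 1000 <= 3.0

    def test_deterministic_for_fixed_seed(self, default_truth):
        a = make_priors_and_seeds(default_truth, seed=9)
        b = make_priors_and_seeds(default_truth, seed=9)
        np.testing.assert_array_equal(a[0].z_mm, b[0].z_mm)
        np.testing.assert_array_equal(a[2].z_mm, b[2].z_mm)

    def test_too_few_seeds_rejected(self, default_truth):
        with pytest.raises(ValueError, match="5 seed"):
            make_priors_and_seeds(default_truth, n_seeds=4)


def tiny_cohort_spec(**kw):
    defaults = dict(
        n_subjects=2,
        render=replace(
            RenderSpec(calibration=half_resolution()), speckle_shape=None, additive_sigma=0.0
        ),
        seed=4,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSimulateCohort:
    def test_fixed_change_manifest_truths_exact(self):
        sim = simulate_cohort(
            tiny_cohort_spec(epi_change=ChangeModel(-12.8, 0.0), stroma_change=ChangeModel(4.8, 0.0))
        )
        np.testing.assert_allclose(sim.manifest["epi_change_central_um"], -12.8)
        np.testing.assert_allclose(sim.manifest["stroma_change_central_um"], 4.8)
        # the configured change is the induced central-zone mean on the Z-line grid
        from cornoct.segmentation import sample_zlines

        rec = sim.subjects[0]
        zl = sample_zlines(sim.spec.render.calibration, sim.spec.n_zlines)
        x = zl.x_mm[np.abs(zl.x_mm) <= 1.0]
        pre = sim.subjects[0].truths[("horizontal", "pre")]
        post = sim.subjects[0].truths[("horizontal", "post")]
        realised = np.mean(post.t_epi(x) - pre.t_epi(x))
        assert realised == pytest.approx(-12.8, abs=1e-9)

    def test_seeded_reproducibility(self):
        a = simulate_cohort(tiny_cohort_spec())
        b = simulate_cohort(tiny_cohort_spec())
        for ra, rb in zip(a.subjects, b.subjects):
            for key in ra.scans:
                np.testing.assert_array_equal(ra.scans[key].image, rb.scans[key].image)
        assert a.manifest.equals(b.manifest)

    def test_stochastic_change_matches_reference_stream(self):
        spec = tiny_cohort_spec(epi_change=ChangeModel(-12.8, 6.0))
        sim = simulate_cohort(spec)
        # regenerate the per-subject draws from the same seed sequence
        master = np.random.SeedSequence(spec.seed)
        for rec, row, ss in zip(sim.subjects, sim.manifest.itertuples(), master.spawn(2)):
            rng = np.random.default_rng(ss)
            rng.normal(53.6, 4.2)  # epithelial baseline
            rng.normal(515.7, 28.1)  # stromal baseline
            expect = rng.normal(-12.8, 6.0)
            assert row.epi_change_central_um == pytest.approx(expect)

    def test_write_cohort_to_disk(self, tmp_path):
        sim = simulate_cohort(tiny_cohort_spec())
        out = sim.write(tmp_path / "cohort")
        tiffs = sorted(out.glob("*.tiff"))
        assert len(tiffs) == 2 * 2 * 2  # subjects x meridians x visits
        assert (out / "manifest.csv").exists()
        assert len(sorted(out.glob("*_seeds.csv"))) == 8

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            CohortSpec(n_subjects=1)


class TestTruthRoundTrip:
    def test_pipeline_recovers_configured_truths(self):
        """Noise-free simulate -> segment -> profile recovers zone means and radii."""
        from cornoct.pipeline import analyze_cohort

        spec = tiny_cohort_spec(
            epi_baseline=ChangeModel(53.6, 0.0),
            stroma_baseline=ChangeModel(515.7, 0.0),
            epi_change=ChangeModel(0.0, 0.0),
            stroma_change=ChangeModel(0.0, 0.0),
            radius_baseline_h=ChangeModel(7.86, 0.0),
            radius_baseline_v=ChangeModel(7.60, 0.0),
            radius_change_h=ChangeModel(0.0, 0.0),
            radius_change_v=ChangeModel(0.0, 0.0),
        )
        analysis = analyze_cohort(simulate_cohort(spec))
        assert not analysis.excluded
        df = analysis.table.data
        epi = df[(df.kind == "thickness") & (df.name == "epithelium") & (df.zone == "central")]
        assert epi["value"].mean() == pytest.approx(53.6, abs=0.5)
        cor = df[(df.kind == "thickness") & (df.name == "cornea") & (df.zone == "central")]
        assert cor["value"].mean() == pytest.approx(569.3, abs=0.5)
        rad = df[(df.kind == "radius") & (df.name == "anterior") & (df.meridian == "horizontal")]
        assert rad["value"].mean() == pytest.approx(7.86, abs=0.05)
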