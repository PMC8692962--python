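"""Shared fixtures: rendered synthetic scans and their segmentations.

Session-scoped because rendering and segmenting a B-scan is the expensive
step shared by many tests; everything is seeded and deterministic.
"""

from dataclasses import replace

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cornoct.priors import fit_prior
from cornoct.segmentation import CornealSegmentationModel
from cornoct.synthetic import (
    RenderSpec,
    half_resolution,
    make_ground_truth,
    make_priors_and_seeds,
    render_bscan,
)


@pytest.fixture(scope="session")
def default_truth():
    """Baseline cornea: anterior R 7.86 mm / Q -0.2, epithelium 53.6 um, stroma 515.7 um."""
    return make_ground_truth()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free half-resolution render settings."""
    return replace(
        RenderSpec(calibration=half_resolution()), speckle_shape=None, additive_sigma=0.0
    )


@pytest.fixture(scope="session")
def clean_scan(default_truth, clean_spec):
    scan, truth = render_bscan(default_truth, clean_spec)
    return scan, truth


@pytest.fixture(scope="session")
def priors_and_seeds(default_truth):
    return make_priors_and_seeds(default_truth, seed=1)


@pytest.fixture(scope="session")
def clean_segmentation(clean_scan, priors_and_seeds):
    """Full segmentation of the noise-free baseline scan."""
    scan, _ = clean_scan
    ant, post, seeds = priors_and_seeds
    model = CornealSegmentationModel(scan, fit_prior(ant), fit_prior(post), seeds=seeds)
    return model.fit()


@pytest.fixture(scope="session")
def noisy_segmentation(default_truth):
    """Segmentation of a speckled render (default noise model)."""
    spec = replace(RenderSpec(calibration=half_resolution()), seed=11)
    scan, _ = render_bscan(default_truth, spec)
    ant, post, seeds = make_priors_and_seeds(default_truth, seed=2)
    model = CornealSegmentationModel(scan, fit_prior(ant), fit_prior(post), seeds=seeds)
    return model.fit()
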