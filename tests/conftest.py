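"""Shared fixtures: small geometric fixtures and seeded synthetic leaves."""

import numpy as np
import pytest

from leafgielis import (
    GielisParameters,
    PlanarContour,
    SGEVariant,
    generate_leaf,
)
from leafgielis.contour import to_polar
from leafgielis.model import FitConfig, fit_leaf


@pytest.fixture
def square_contour() -> PlanarContour:
    """Unit square, CCW, with the point-count check relaxed."""
    pts = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    return PlanarContour.from_points(pts, leaf_id="square", min_points=3)


@pytest.fixture(scope="session")
def sge3_truth() -> GielisParameters:
    return GielisParameters.from_free("SGE3", [10.0, 0.06])


@pytest.fixture(scope="session")
def noisy_sge3_leaf(sge3_truth) -> PlanarContour:
    """One 2000-point SGE-3 leaf, 1% radial noise, rotated and translated."""
    return generate_leaf(
        sge3_truth, n_points=2000, noise_sd_rel=0.01,
        pose=(0.5, 3.0, -2.0), seed=1, leaf_id="noisy_sge3",
    )


@pytest.fixture(scope="session")
def fitted_sge3(noisy_sge3_leaf):
    """Converged SGE-3 fit plus its polar contour (reused across tests)."""
    fit = fit_leaf(noisy_sge3_leaf, variants=["SGE3"])[SGEVariant.SGE3]
    polar = to_polar(noisy_sge3_leaf, fit.pole, fit.axis_angle)
    return fit, polar


@pytest.fixture(scope="session")
def small_population_dir(tmp_path_factory):
    """Ten 400-point SGE-1 leaves on disk (pipeline-stage fixtures)."""
    from leafgielis.pipeline import stage_simulate

    path = tmp_path_factory.mktemp("leaves")
    stage_simulate(path, n_leaves=10, variant_truth="SGE1", n_points=400,
                   noise_sd_rel=0.01, seed=11)
    return path


@pytest.fixture(scope="session")
def fast_fit_config() -> FitConfig:
    """Slightly looser tolerances for structural (non-accuracy) tests."""
    return FitConfig(n_starts=2, xtol=1e-8, ftol=1e-8, max_iter=2000)
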