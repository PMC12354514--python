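"""Synthetic lanceolate leaf contours with known ground truth.

The generator emulates the study conditions the pipeline targets: 250-ish
leaves per species, ~2000 arc-length-equidistant boundary points per leaf,
and small multiplicative radial measurement noise, with each contour placed
at an arbitrary position and orientation in the plane.  Truth parameters
are drawn log-uniformly from ranges calibrated to the lanceolate regime
(numeric width-to-length ratio 0.05–0.35); draws outside that band are
rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._geometry import rotate_translate
from .contour import PlanarContour
from .superformula import (
    GielisParameters,
    SGEVariant,
    equal_arclength_theta,
    sge_radius,
)

__all__ = [
    "SimulationDesign",
    "generate_leaf",
    "generate_population",
    "write_population",
    "width_to_length_ratio",
]

# default log-uniform truth ranges (see docs/methods.md)
DEFAULT_RANGES = {
    "a": (5.0, 15.0),
    "n1": (0.02, 0.12),
    "n23": (0.5, 2.0),
}
MAX_N2_N3_LOG_RATIO = np.log(1.5)
LANCEOLATE_BAND = (0.05, 0.35)


@dataclass(frozen=True)
class SimulationDesign:
    """Reproducible recipe for one synthetic leaf population."""

    n_leaves: int
    variant_truth: SGEVariant = SGEVariant.SGE3
    parameter_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    n_points: int = 2000
    noise_sd_rel: float = 0.01
    pose_randomization: bool = True
    seed: int = 0
    shape_band: tuple[float, float] = LANCEOLATE_BAND

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "variant_truth", SGEVariant.coerce(self.variant_truth)
        )
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.n_points < 100:
            raise ValueError("n_points must be >= 100")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")


def width_to_length_ratio(params: GielisParameters, n_probe: int = 1024) -> float:
    """Bounding-box width/length of the noise-free outline (pole at origin)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_probe, endpoint=False)
    r = sge_radius(theta, params)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    length = float(x.max() - x.min())
    width = float(y.max() - y.min())
    return width / length


def generate_leaf(
    params: GielisParameters,
    n_points: int = 2000,
    noise_sd_rel: float = 0.01,
    pose: tuple[float, float, float] | None = None,
    seed: int | np.random.Generator = 0,
    leaf_id: str = "",
) -> PlanarContour:
    """One noisy contour from a known parameter vector.

    Angles are chosen so the noise-free points are equidistant along the
    perimeter (solved on the true curve, so without noise every point lies
    exactly on it); radii are then perturbed multiplicatively,
    ``r_i = r(theta_i) * (1 + eps_i)`` with ``eps_i ~ N(0, noise_sd_rel^2)``
    clipped at +/- 4 sd (keeps radii positive for any noise below 25%), and
    the contour is rigidly moved by ``pose = (angle, tx, ty)``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    theta = equal_arclength_theta(params, int(n_points))
    r = sge_radius(theta, params)
    if noise_sd_rel > 0:
        bound = 4.0 * noise_sd_rel
        if bound >= 1.0:
            raise ValueError(
                "noise level too large: the +/-4 sd band reaches zero "
                f"radius (noise_sd_rel={noise_sd_rel} >= 0.25)"
            )
        eps = rng.normal(0.0, noise_sd_rel, size=r.shape)
        eps = np.clip(eps, -bound, bound)
        r = r * (1.0 + eps)
        if np.any(r <= 0):
            raise ValueError(
                "noise level too large: nonpositive radius after truncation"
            )
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if pose is not None:
        angle, tx, ty = pose
        pts = rotate_translate(pts, angle, (tx, ty))
    return PlanarContour.from_points(pts, leaf_id=leaf_id)


def _draw_parameters(
    design: SimulationDesign, rng: np.random.Generator
) -> GielisParameters:
    lo_a, hi_a = design.parameter_ranges["a"]
    lo_n1, hi_n1 = design.parameter_ranges["n1"]
    a = float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
    n1 = float(np.exp(rng.uniform(np.log(lo_n1), np.log(hi_n1))))
    variant = design.variant_truth
    if variant is SGEVariant.SGE3:
        return GielisParameters.from_free(variant, [a, n1])
    lo_n, hi_n = design.parameter_ranges["n23"]
    n2 = float(np.exp(rng.uniform(np.log(lo_n), np.log(hi_n))))
    if variant is SGEVariant.SGE2:
        return GielisParameters.from_free(variant, [a, n1, n2])
    # SGE-1: mild asymmetry, |log(n3/n2)| <= log 1.5, clipped into range
    log_n3 = np.log(n2) + rng.uniform(-MAX_N2_N3_LOG_RATIO, MAX_N2_N3_LOG_RATIO)
    n3 = float(np.clip(np.exp(log_n3), lo_n, hi_n))
    return GielisParameters.from_free(variant, [a, n1, n2, n3])


def generate_population(
    design: SimulationDesign,
) -> tuple[list[PlanarContour], pd.DataFrame]:
    """A seeded population of contours plus its ground-truth table.

    Parameter draws whose noise-free outline falls outside the lanceolate
    width-to-length band are rejected and redrawn (> 1000 consecutive
    rejections raises, suggesting a range fix).
    """
    rng = np.random.default_rng(design.seed)
    contours: list[PlanarContour] = []
    rows = []
    width = len(str(design.n_leaves))
    for i in range(design.n_leaves):
        rejections = 0
        while True:
            params = _draw_parameters(design, rng)
            ratio = width_to_length_ratio(params)
            if design.shape_band[0] <= ratio <= design.shape_band[1]:
                break
            rejections += 1
            if rejections > 1000:
                raise RuntimeError(
                    "over 1000 consecutive draws outside the lanceolate "
                    "band; adjust parameter_ranges or shape_band"
                )
        if design.pose_randomization:
            pose = (
                float(rng.uniform(0.0, 2.0 * np.pi)),
                float(rng.uniform(-2.0 * params.a, 2.0 * params.a)),
                float(rng.uniform(-2.0 * params.a, 2.0 * params.a)),
            )
        else:
            pose = None
        leaf_id = f"leaf{i + 1:0{width}d}"
        contour = generate_leaf(
            params,
            n_points=design.n_points,
            noise_sd_rel=design.noise_sd_rel,
            pose=pose,
            seed=rng,
            leaf_id=leaf_id,
        )
        contours.append(contour)
        rows.append({
            "leaf_id": leaf_id,
            "variant": params.variant.value,
            "a": params.a,
            "n1": params.n1,
            "n2": params.n2,
            "n3": params.n3,
            "width_to_length": ratio,
            "noise_sd_rel": design.noise_sd_rel,
            "seed": design.seed,
        })
    return contours, pd.DataFrame(rows)


def write_population(
    contours: list[PlanarContour], truth: pd.DataFrame, directory
) -> Path:
    """Write per-leaf coordinate CSVs plus ``truth.csv``; returns the dir."""
    from .contour import write_contour

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for contour in contours:
        write_contour(contour, directory / f"{contour.leaf_id}.csv")
    truth.to_csv(directory / "truth.csv", index=False, float_format="%.10g")
    return directory
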