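"""Least-squares fitting of simplified Gielis equations to leaf contours.

Each variant is fitted to the polar radii of one leaf by minimising the
residual sum of squares

    RSS = sum_i (r_i - r_hat(theta_i; a, n1, n2, n3))^2

with multi-start Nelder–Mead.  The optimiser runs in log-parameter space
(positivity without constraints); everything reported is back-transformed.
Goodness of fit is summarised by RMSE = sqrt(RSS / (N - P)) and by a full
Gaussian-likelihood AIC.

The pole position and axis rotation of the polar frame are, by default,
co-optimised with the shape parameters as nuisance coordinates: the Gielis
pole lies strictly inside the outline (at distance r(pi) from the base), so
no pole fixed from the raw geometry alone can reproduce an exact fit.  The
nuisance coordinates are excluded from the parameter count P used by RMSE,
AIC and the curvature diagnostics.  ``co_optimize_pose=False`` selects the
pure two-stage mode (pole fixed at the better maximal-chord endpoint).

The object-oriented surface mirrors the familiar Model / Results pattern:
:class:`GielisLeafModel` wraps one leaf's contour; ``.fit(variant)`` returns
a :class:`GielisFitResults` carrying the estimates, fit statistics and a
``summary()`` table, with nonlinearity diagnostics available via
``.diagnose()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .contour import PlanarContour, PolarContour, estimate_pole_and_axis, to_polar
from .superformula import GielisParameters, SGEVariant, _radius_from_cs, sge_radius

__all__ = [
    "FitConfig",
    "FitResult",
    "rss",
    "aic",
    "fit_sge",
    "fit_leaf",
    "default_start_grid",
    "GielisLeafModel",
    "GielisFitResults",
]

VARIANT_ORDER = (SGEVariant.SGE3, SGEVariant.SGE2, SGEVariant.SGE1)

# large finite penalty for out-of-basin parameters (inf upsets the simplex
# convergence test)
_PENALTY = 1e50


@dataclass(frozen=True)
class FitConfig:
    """Optimisation settings for :func:`fit_sge`.

    The start grid is a deterministic lattice (see
    :func:`default_start_grid`); the objective is screened at every lattice
    point and full Nelder–Mead runs are launched from the ``n_starts`` best,
    plus any warm starts handed in from a nested simpler variant.  With a
    fixed grid the whole procedure is deterministic.
    """

    n_starts: int = 3
    start_grid: tuple | None = None
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_iter: int = 5000
    seed: int = 0
    co_optimize_pose: bool = True

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.xtol <= 0 or self.ftol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class FitResult:
    """One leaf x one variant least-squares fit."""

    leaf_id: str
    variant: SGEVariant
    estimate: GielisParameters
    pole: np.ndarray
    axis_angle: float
    rss: float
    rmse: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    best_start_index: int
    n_function_evals: int

    @property
    def free_values(self) -> np.ndarray:
        return self.estimate.free_values

    def predicted(self, theta) -> np.ndarray:
        return sge_radius(theta, self.estimate)

    def to_record(self) -> dict:
        e = self.estimate
        return {
            "leaf_id": self.leaf_id,
            "variant": self.variant.value,
            "a": e.a,
            "n1": e.n1,
            "n2": e.n2,
            "n3": e.n3,
            "pole_x": float(self.pole[0]),
            "pole_y": float(self.pole[1]),
            "axis_angle": self.axis_angle,
            "rss": self.rss,
            "rmse": self.rmse,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
        }


def rss(polar: PolarContour, params: GielisParameters) -> float:
    """Residual sum of squares over the polar radii.

    Raises if the model radius is non-finite at any observed angle.
    """
    r_hat = sge_radius(polar.theta, params)
    bad = ~np.isfinite(r_hat)
    if np.any(bad):
        theta_bad = polar.theta[bad][0]
        raise FloatingPointError(
            f"non-finite model radius at theta = {theta_bad:.6g}"
        )
    return float(np.sum((polar.r - r_hat) ** 2))


def aic(rss_value: float, n: int, p: int) -> float:
    """Gaussian least-squares AIC, counting the error variance as a parameter.

    ``AIC = N ln(2 pi) + N ln(RSS / N) + N + 2 (P + 1)``.  The additive
    constants cancel in within-leaf comparisons; keeping them makes values
    comparable across tools.  RSS = 0 returns ``-inf`` with a warning.
    """
    if n <= p:
        raise ValueError(f"need N > P, got N={n}, P={p}")
    if rss_value < 0:
        raise ValueError("RSS must be nonnegative")
    if rss_value == 0:
        warnings.warn("perfect fit (RSS = 0); AIC is -inf", RuntimeWarning)
        return float("-inf")
    return float(
        n * np.log(2.0 * np.pi) + n * np.log(rss_value / n) + n + 2.0 * (p + 1)
    )


def default_start_grid(variant: SGEVariant, r_max: float) -> list[np.ndarray]:
    """Deterministic lattice of initial free-parameter vectors.

    ``a`` spans {0.5, 1.0, 1.5} x max observed radius; ``n1`` spans
    {0.01, 0.05, 0.1, 0.5}; ``n2`` (and ``n3`` for SGE-1) span {0.5, 1, 2}.
    12, 36 or 108 lattice points for SGE-3/2/1.
    """
    a_vals = [0.5 * r_max, 1.0 * r_max, 1.5 * r_max]
    n1_vals = [0.01, 0.05, 0.1, 0.5]
    n23_vals = [0.5, 1.0, 2.0]
    grid = []
    if variant is SGEVariant.SGE3:
        for a in a_vals:
            for n1 in n1_vals:
                grid.append(np.array([a, n1]))
    elif variant is SGEVariant.SGE2:
        for a in a_vals:
            for n1 in n1_vals:
                for n2 in n23_vals:
                    grid.append(np.array([a, n1, n2]))
    else:
        for a in a_vals:
            for n1 in n1_vals:
                for n2 in n23_vals:
                    for n3 in n23_vals:
                        grid.append(np.array([a, n1, n2, n3]))
    return grid


def _run_nelder_mead(objective, x0, config: FitConfig, max_rounds: int = 4):
    """Nelder–Mead with restart rounds from the incumbent best vertex.

    Restarting re-inflates the simplex, which recovers from premature
    collapse; rounds stop as soon as the objective no longer improves
    meaningfully.  Returns ``(best OptimizeResult, total nfev)``.
    """
    opts = dict(
        xatol=config.xtol, fatol=config.ftol, maxiter=config.max_iter,
        maxfev=4 * config.max_iter,
    )
    best = None
    nfev = 0
    x = np.asarray(x0, dtype=float)
    for _ in range(max_rounds):
        res = minimize(objective, x, method="Nelder-Mead", options=opts)
        nfev += res.nfev
        if best is None:
            best = res
        elif res.fun < best.fun:
            improvement = best.fun - res.fun
            best = res
            if improvement <= config.ftol * max(1.0, abs(best.fun)):
                break
        else:
            break
        x = best.x
    return best, nfev


def _objective_factory(polar: PolarContour, variant: SGEVariant):
    c = np.abs(np.cos(polar.theta / 4.0))
    s = np.abs(np.sin(polar.theta / 4.0))
    r_obs = polar.r
    p = variant.n_parameters

    r_cap = 5.0 * float(np.max(r_obs))

    def objective(log_free: np.ndarray) -> float:
        free = np.exp(log_free)
        if not np.all(np.isfinite(free)) or free[0] > r_cap:
            return _PENALTY
        a, n1 = free[0], free[1]
        n2 = free[2] if p >= 3 else 1.0
        n3 = free[3] if p == 4 else n2
        r_hat = _radius_from_cs(c, s, a, n1, n2, n3)
        with np.errstate(over="ignore", invalid="ignore"):
            resid = r_obs - r_hat
            val = np.dot(resid, resid)
        return val if np.isfinite(val) else _PENALTY

    return objective


def fit_sge(
    polar: PolarContour,
    variant: SGEVariant | str,
    config: FitConfig | None = None,
    warm_starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Fit one variant to one polar contour by multi-start Nelder–Mead.

    ``warm_starts`` are extra initial free-parameter vectors (in the
    original scale), typically the optimum of the nested simpler variant;
    including them makes the nested-RSS inequality hold exactly because
    Nelder–Mead never returns a point worse than its start.  All-start
    failure yields ``converged=False`` with diagnostics, not an exception.
    """
    variant = SGEVariant.coerce(variant)
    config = config or FitConfig()
    p = variant.n_parameters
    n = len(polar)
    if n <= p + 10:
        raise ValueError(f"need N > P + 10 data points, got N={n}, P={p}")

    objective = _objective_factory(polar, variant)
    r_max = float(np.max(polar.r))
    grid = (
        [np.asarray(g, dtype=float) for g in config.start_grid]
        if config.start_grid is not None
        else default_start_grid(variant, r_max)
    )

    # screen the lattice, keep the n_starts best as NM launch points
    scores = np.array([objective(np.log(g)) for g in grid])
    order = np.argsort(scores, kind="stable")[: config.n_starts]
    starts = [(int(i), np.log(grid[int(i)])) for i in order
              if scores[i] < _PENALTY]
    for w in warm_starts or []:
        w = np.asarray(w, dtype=float)
        if len(w) != p or np.any(w <= 0):
            raise ValueError(f"warm start must be {p} positive values")
        starts.append((-1, np.log(w)))
    if not starts:
        starts = [(0, np.log(grid[0]))]

    best = None
    nfev = 0
    for idx, x0 in starts:
        res, nf = _run_nelder_mead(objective, x0, config, max_rounds=1)
        nfev += nf
        if best is None or res.fun < best[1].fun:
            best = (idx, res)
    idx, res0 = best
    # restart from the best vertex until no further improvement
    # (guards against simplex collapse)
    res, nf = _run_nelder_mead(objective, res0.x, config)
    nfev += nf
    if res0.fun < res.fun:
        res = res0
    converged = bool(res.success)

    estimate = GielisParameters.from_free(variant, np.exp(res.x))
    rss_value = rss(polar, estimate)
    rmse = float(np.sqrt(rss_value / (n - p)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aic_value = aic(rss_value, n, p) if rss_value > 0 else float("-inf")
    return FitResult(
        leaf_id=polar.leaf_id,
        variant=variant,
        estimate=estimate,
        pole=np.asarray(polar.pole, dtype=float),
        axis_angle=polar.axis_angle,
        rss=rss_value,
        rmse=rmse,
        aic=aic_value,
        n_obs=n,
        n_params=p,
        converged=converged,
        best_start_index=idx,
        n_function_evals=nfev,
    )


def _warm_start_chain(variant: SGEVariant, fits: dict) -> list[np.ndarray]:
    """Warm starts for ``variant`` from already-fitted simpler variants."""
    warm = []
    if variant is SGEVariant.SGE2 and SGEVariant.SGE3 in fits:
        e = fits[SGEVariant.SGE3].estimate
        warm.append(np.array([e.a, e.n1, 1.0]))
    if variant is SGEVariant.SGE1:
        if SGEVariant.SGE2 in fits:
            e = fits[SGEVariant.SGE2].estimate
            warm.append(np.array([e.a, e.n1, e.n2, e.n2]))
        if SGEVariant.SGE3 in fits:
            e = fits[SGEVariant.SGE3].estimate
            warm.append(np.array([e.a, e.n1, 1.0, 1.0]))
    return warm


def _pose_objective_factory(pts: np.ndarray, variant: SGEVariant):
    """RSS as a function of (log free parameters, pole_x, pole_y, axis).

    The search is confined to the physically meaningful basin: the scale
    parameter cannot exceed a few contour diameters and the pole cannot
    leave the contour's neighbourhood.  Outside it the model degenerates
    (a and n1 become confounded on a nearly flat radius profile) and the
    optimiser can otherwise stall in rank-deficient corners.
    """
    p = variant.n_parameters
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    diameter = float(np.hypot(*(hi - lo)))
    centroid = pts.mean(axis=0)

    def objective(z: np.ndarray) -> float:
        free = np.exp(z[:p])
        if not np.all(np.isfinite(free)):
            return _PENALTY
        if free[0] > 3.0 * diameter:
            return _PENALTY
        if np.hypot(z[p] - centroid[0], z[p + 1] - centroid[1]) > 1.5 * diameter:
            return _PENALTY
        delta_x = pts[:, 0] - z[p]
        delta_y = pts[:, 1] - z[p + 1]
        r_obs = np.hypot(delta_x, delta_y)
        if np.any(r_obs < 1e-12):
            return _PENALTY
        # wrap to [0, 2*pi): r(theta) is only 4*pi-periodic when n2 != n3,
        # so the branch must match the to_polar convention exactly
        theta = np.mod(np.arctan2(delta_y, delta_x) - z[p + 2], 2.0 * np.pi)
        c = np.abs(np.cos(theta / 4.0))
        s = np.abs(np.sin(theta / 4.0))
        a, n1 = free[0], free[1]
        n2 = free[2] if p >= 3 else 1.0
        n3 = free[3] if p == 4 else n2
        r_hat = _radius_from_cs(c, s, a, n1, n2, n3)
        with np.errstate(over="ignore", invalid="ignore"):
            resid = r_obs - r_hat
            val = np.dot(resid, resid)
        return val if np.isfinite(val) else _PENALTY

    return objective


def _pose_z(free: np.ndarray, pole, axis_angle: float) -> np.ndarray:
    return np.concatenate([np.log(free), np.asarray(pole, float),
                           [float(axis_angle)]])


def _result_from_pose_fit(
    contour: PlanarContour, variant: SGEVariant, res, nfev: int,
    start_index: int,
) -> FitResult:
    p = variant.n_parameters
    estimate = GielisParameters.from_free(variant, np.exp(res.x[:p]))
    pole = np.asarray(res.x[p : p + 2], dtype=float)
    axis = float(res.x[p + 2])
    polar = to_polar(contour, pole, axis)
    rss_value = rss(polar, estimate)
    n = len(polar)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aic_value = aic(rss_value, n, p) if rss_value > 0 else float("-inf")
    return FitResult(
        leaf_id=contour.leaf_id,
        variant=variant,
        estimate=estimate,
        pole=pole,
        axis_angle=axis,
        rss=rss_value,
        rmse=float(np.sqrt(rss_value / (n - p))),
        aic=aic_value,
        n_obs=n,
        n_params=p,
        converged=bool(res.success),
        best_start_index=start_index,
        n_function_evals=nfev,
    )


def _warm_pose_starts(variant: SGEVariant, fits: dict) -> list[np.ndarray]:
    """(parameters + pose) warm starts from already-fitted nested variants.

    Each start evaluates to exactly the source fit's RSS, so a Nelder–Mead
    run from it can only match or improve — the nested-RSS guarantee.
    """
    starts = []
    sources = {
        SGEVariant.SGE2: [SGEVariant.SGE3],
        # SGE-3 warm start is redundant for SGE-1 when SGE-2 is present
        # (SGE-2's optimum already dominates it)
        SGEVariant.SGE1: [SGEVariant.SGE2]
        if SGEVariant.SGE2 in fits
        else [SGEVariant.SGE3],
    }.get(variant, [])
    for src_variant in sources:
        if src_variant not in fits:
            continue
        src = fits[src_variant]
        e = src.estimate
        if variant is SGEVariant.SGE2:
            free = np.array([e.a, e.n1, e.n2])
        else:
            free = np.array([e.a, e.n1, e.n2, e.n3])
        starts.append(_pose_z(free, src.pole, src.axis_angle))
    return starts


def fit_leaf(
    contour: PlanarContour,
    variants=VARIANT_ORDER,
    config: FitConfig | None = None,
) -> dict[SGEVariant, FitResult]:
    """Fit the requested variants to one planar contour.

    The two maximal-chord pole candidates seed the pose; the simplest
    requested variant is fitted from both (multi-start at fixed pose, then
    pose refinement when ``co_optimize_pose`` is on) and the lower-RSS
    solution wins.  Richer variants are fitted in nesting order, each
    warm-started at its simpler predecessor's full solution, which makes
    RSS(SGE-1) <= RSS(SGE-2) <= RSS(SGE-3) hold exactly.
    """
    config = config or FitConfig()
    variants = [SGEVariant.coerce(v) for v in variants]
    variants = [v for v in VARIANT_ORDER if v in variants]
    if not variants:
        raise ValueError("no variants requested")
    _, _, candidates = estimate_pole_and_axis(contour)
    pts = np.asarray(contour.points, dtype=float)

    probe_variant = variants[0]
    cand_fits = []
    for cand in candidates:
        polar = to_polar(contour, cand.pole, cand.axis_angle)
        cand_fits.append((fit_sge(polar, probe_variant, config), cand))

    if not config.co_optimize_pose:
        cand_fits.sort(key=lambda t: t[0].rss)
        best_fit, best_cand = cand_fits[0]
        polar = to_polar(contour, best_cand.pole, best_cand.axis_angle)
        fits = {probe_variant: best_fit}
        for variant in variants[1:]:
            fits[variant] = fit_sge(
                polar, variant, config,
                warm_starts=_warm_start_chain(variant, fits),
            )
        return fits

    objective = _pose_objective_factory(pts, probe_variant)
    # refine pose from the better chord end; only bother with the other end
    # when the fixed-pose fits are close (base/apex genuinely ambiguous)
    cand_fits.sort(key=lambda t: t[0].rss)
    ambiguous = cand_fits[1][0].rss < 4.0 * cand_fits[0][0].rss
    best = None
    nfev = 0
    for fixed_fit, cand in cand_fits[: 2 if ambiguous else 1]:
        z0 = _pose_z(fixed_fit.free_values, cand.pole, cand.axis_angle)
        res, nf = _run_nelder_mead(objective, z0, config)
        nfev += nf + fixed_fit.n_function_evals
        if best is None or res.fun < best.fun:
            best = res
    fits = {probe_variant: _result_from_pose_fit(contour, probe_variant,
                                                 best, nfev, 0)}

    prev = fits[probe_variant]
    for variant in variants[1:]:
        polar = to_polar(contour, prev.pole, prev.axis_angle)
        fixed_fit = fit_sge(
            polar, variant, config,
            warm_starts=_warm_start_chain(variant, fits),
        )
        objective = _pose_objective_factory(pts, variant)
        z_starts = [
            _pose_z(fixed_fit.free_values, prev.pole, prev.axis_angle),
        ]
        z_starts.extend(_warm_pose_starts(variant, fits))
        best = None
        nfev = fixed_fit.n_function_evals
        for z0 in z_starts:
            res, nf = _run_nelder_mead(objective, z0, config)
            nfev += nf
            if best is None or res.fun < best.fun:
                best = res
        fits[variant] = _result_from_pose_fit(contour, variant, best, nfev, 0)
        prev = fits[variant]
    return fits


class GielisLeafModel:
    """Simplified-Gielis-equation regression model for one leaf contour.

    Parameters
    ----------
    contour : PlanarContour
        The leaf boundary (any pose; the pole and axis are estimated).

    Examples
    --------
    >>> model = GielisLeafModel.from_xy(x, y, leaf_id="leaf01")  # doctest: +SKIP
    >>> res = model.fit("SGE3")                                  # doctest: +SKIP
    >>> print(res.summary())                                     # doctest: +SKIP
    """

    def __init__(self, contour: PlanarContour):
        self.contour = contour

    @classmethod
    def from_xy(cls, x, y, leaf_id: str = "", min_points: int = 50):
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        return cls(PlanarContour.from_points(pts, leaf_id=leaf_id,
                                             min_points=min_points))

    @classmethod
    def from_file(cls, path, dialect=None):
        from .contour import read_contour

        return cls(read_contour(path, dialect=dialect))

    def fit(self, variant="SGE3", config: FitConfig | None = None
            ) -> "GielisFitResults":
        variant = SGEVariant.coerce(variant)
        fits = fit_leaf(self.contour, variants=[variant], config=config)
        return GielisFitResults(self, fits[variant])

    def fit_all(self, config: FitConfig | None = None
                ) -> dict[SGEVariant, "GielisFitResults"]:
        """Fit all three variants with shared pole and nested warm starts."""
        fits = fit_leaf(self.contour, config=config)
        return {v: GielisFitResults(self, f) for v, f in fits.items()}


class GielisFitResults:
    """Results wrapper: estimates, fit statistics, diagnostics, summary."""

    def __init__(self, model: GielisLeafModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    # -- convenience accessors ------------------------------------------
    @property
    def params(self) -> GielisParameters:
        return self.fit_result.estimate

    @property
    def variant(self) -> SGEVariant:
        return self.fit_result.variant

    @property
    def rss(self) -> float:
        return self.fit_result.rss

    @property
    def rmse(self) -> float:
        return self.fit_result.rmse

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def nobs(self) -> int:
        return self.fit_result.n_obs

    def predict(self, theta) -> np.ndarray:
        return self.fit_result.predicted(theta)

    @property
    def polar(self) -> PolarContour:
        return to_polar(self.model.contour, self.fit_result.pole,
                        self.fit_result.axis_angle)

    def diagnose(self, alpha: float = 0.05):
        """Bates–Watts curvatures, critical curvature and Box bias."""
        from .diagnostics import diagnose

        return diagnose(self.polar, self.fit_result, alpha=alpha)

    def summary(self) -> str:
        f = self.fit_result
        e = f.estimate
        lines = [
            "Simplified Gielis Equation Fit",
            "=" * 46,
            f"leaf_id:   {f.leaf_id or '<unnamed>'}",
            f"variant:   {f.variant.value}  (P = {f.n_params})",
            f"N obs:     {f.n_obs}",
            f"converged: {f.converged}",
            "-" * 46,
            f"a   = {e.a:.6g}",
            f"n1  = {e.n1:.6g}",
        ]
        if f.variant is not SGEVariant.SGE3:
            lines.append(f"n2  = {e.n2:.6g}")
        if f.variant is SGEVariant.SGE1:
            lines.append(f"n3  = {e.n3:.6g}")
        lines += [
            "-" * 46,
            f"RSS  = {f.rss:.6g}",
            f"RMSE = {f.rmse:.6g}",
            f"AIC  = {f.aic:.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_curve: int = 720):
        """Overlay the fitted outline on the observed contour."""
        import matplotlib.pyplot as plt

        from ._geometry import rotate_translate
        from .superformula import sample_curve

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        obs = np.asarray(self.model.contour.points)
        ax.plot(obs[:, 0], obs[:, 1], ".", ms=1, color="0.4", label="observed")
        curve = sample_curve(self.params, n_curve)
        f = self.fit_result
        curve = rotate_translate(curve, f.axis_angle, f.pole)
        ax.plot(curve[:, 0], curve[:, 1], "-", color="C3",
                label=f"{self.variant.value} fit")
        ax.set_aspect("equal")
        ax.legend(frameon=False, fontsize=8)
        return ax
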