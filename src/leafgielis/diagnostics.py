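"""Bates–Watts curvature measures and Box bias for nonlinear least squares.

Least-squares inference in nonlinear regression rests on a local linear
approximation of the expectation surface.  Two curvature summaries quantify
how far a fitted model sits from that ideal at the estimate:

* the root-mean-square relative *intrinsic* curvature ``gamma_N`` — bending
  of the solution locus out of its tangent plane (violation of the planar
  assumption; invariant under reparameterisation);
* the root-mean-square relative *parameter-effects* curvature ``gamma_T`` —
  non-uniformity of the parameter lines within the tangent plane (violation
  of the uniform-coordinate assumption; parameterisation dependent).

Both are judged against the critical curvature ``K_c = 1 / sqrt(F(P, N-P;
alpha))``; a curvature below ``K_c`` means the corresponding assumption is
acceptable at level ``alpha``.  Box's second-order bias approximation
complements the global measures per parameter: a percentage bias ``|P_b| <
1%`` flags close-to-linear behaviour of that parameter's estimator.

Derivatives are taken by central finite differences in the ORIGINAL
parameters — the close-to-linear question concerns ``(a, n1, n2, n3)``
themselves, even though fitting runs in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr as _qr
from scipy.linalg import solve_triangular
from scipy.stats import f as f_dist

from .contour import PolarContour
from .model import FitResult
from .superformula import GielisParameters, SGEVariant, sge_radius

__all__ = [
    "DerivativeArrays",
    "NonlinearityReport",
    "finite_difference_derivatives",
    "model_derivatives",
    "curvature_faces",
    "rms_relative_curvatures",
    "critical_curvature",
    "box_bias",
    "diagnose",
]

# relative step scales for central differences (first / second derivatives)
FD_EPS_FIRST = 1e-5
FD_EPS_SECOND = 1e-3
KINK_TOL = 1e-9


@dataclass(frozen=True)
class DerivativeArrays:
    """Local linearisation of the model at the estimate.

    ``V`` (N x P) holds first derivatives of the fitted values with respect
    to the parameters (velocity matrix), ``W`` (N x P x P) the second
    derivatives (acceleration array, symmetrised), and ``s`` the residual
    standard error sqrt(RSS / (N - P)).
    """

    V: np.ndarray
    W: np.ndarray
    s: float

    def __post_init__(self) -> None:
        n, p = self.V.shape
        if self.W.shape != (n, p, p):
            raise ValueError("W must be (N, P, P) matching V")
        asym = np.abs(self.W - np.swapaxes(self.W, 1, 2))
        scale = np.max(np.abs(self.W)) or 1.0
        if np.max(asym) > 1e-6 * scale:
            raise ValueError("acceleration array is not symmetric")
        sv = np.linalg.svd(self.V, compute_uv=False)
        if sv[0] <= 0 or sv[-1] / sv[0] <= 1e-10:
            # name the most collinear column pair for the error message
            Vn = self.V / np.linalg.norm(self.V, axis=0)
            corr = np.abs(Vn.T @ Vn - np.eye(p))
            j, k = np.unravel_index(int(np.argmax(corr)), corr.shape)
            raise np.linalg.LinAlgError(
                f"velocity matrix is rank deficient (near-collinear "
                f"parameter columns {j} and {k})"
            )

    @property
    def n_obs(self) -> int:
        return self.V.shape[0]

    @property
    def n_params(self) -> int:
        return self.V.shape[1]


def _fd_steps(phi: np.ndarray, eps: float) -> np.ndarray:
    return np.maximum(np.abs(phi), 0.01) * eps


def finite_difference_derivatives(predict, phi) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference velocity matrix and acceleration array.

    ``predict(phi) -> (N,) fitted values``; steps are
    ``max(|phi_j|, 0.01) * 1e-5`` for first and ``* 1e-3`` for second
    derivatives.  The returned ``W`` is symmetrised.
    """
    phi = np.asarray(phi, dtype=float)
    p = len(phi)
    f0 = np.asarray(predict(phi), dtype=float)
    n = len(f0)

    h1 = _fd_steps(phi, FD_EPS_FIRST)
    V = np.empty((n, p))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h1[j]
        V[:, j] = (predict(phi + e) - predict(phi - e)) / (2.0 * h1[j])

    h2 = _fd_steps(phi, FD_EPS_SECOND)
    W = np.empty((n, p, p))
    for j in range(p):
        ej = np.zeros(p)
        ej[j] = h2[j]
        W[:, j, j] = (predict(phi + ej) - 2.0 * f0 + predict(phi - ej)) / h2[j] ** 2
        for k in range(j + 1, p):
            ek = np.zeros(p)
            ek[k] = h2[k]
            mixed = (
                predict(phi + ej + ek)
                - predict(phi + ej - ek)
                - predict(phi - ej + ek)
                + predict(phi - ej - ek)
            ) / (4.0 * h2[j] * h2[k])
            W[:, j, k] = mixed
            W[:, k, j] = mixed
    W = 0.5 * (W + np.swapaxes(W, 1, 2))
    return V, W


def _kink_mask(theta: np.ndarray) -> np.ndarray:
    """Angles where |cos(theta/4)| or |sin(theta/4)| vanish.

    ``|x|^n`` is non-differentiable at x = 0; those observations are
    excluded from the derivative arrays (and N reduced accordingly).
    """
    c = np.abs(np.cos(theta / 4.0))
    s = np.abs(np.sin(theta / 4.0))
    return (c >= KINK_TOL) & (s >= KINK_TOL)


def model_derivatives(
    polar: PolarContour, estimate: GielisParameters
) -> tuple[DerivativeArrays, np.ndarray]:
    """Derivative arrays of the SGE model at a converged estimate.

    Returns ``(arrays, mask)`` where ``mask`` marks the retained angles.
    ``s`` is recomputed from the retained residuals.
    """
    mask = _kink_mask(polar.theta)
    theta = polar.theta[mask]
    r_obs = polar.r[mask]
    variant = estimate.variant
    p = variant.n_parameters
    n = len(theta)
    if n <= p:
        raise ValueError("too few retained observations for diagnostics")

    def predict(free):
        return sge_radius(theta, GielisParameters.from_free(variant, free,
                                                            strict=False))

    phi = estimate.free_values
    V, W = finite_difference_derivatives(predict, phi)
    resid = r_obs - predict(phi)
    s = float(np.sqrt(np.dot(resid, resid) / (n - p)))
    return DerivativeArrays(V=V, W=W, s=s), mask


def curvature_faces(
    D: DerivativeArrays,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Relative-curvature faces in the orthonormalised parameterisation.

    Computes the thin QR of V, transforms the acceleration array on both
    parameter indices by ``R^{-1}``, splits each face's observation vector
    into tangent coordinates (on Q) and normal coordinates (on an
    orthonormal basis of the residual span), and scales by the standard
    radius ``rho = s * sqrt(P)``.  Returns ``(tangent_faces, normal_faces,
    rho)``; tangent faces are P symmetric P x P matrices, normal faces at
    most P(P+1)/2 of them.
    """
    n, p = D.V.shape
    Q, R = _qr(D.V, mode="economic")
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    R = R * signs[:, None]
    Rinv = solve_triangular(R, np.eye(p))
    # C[n] = Rinv.T @ W[n] @ Rinv : acceleration in orthonormal coordinates
    C = np.einsum("ji,njk,kl->nil", Rinv, D.W, Rinv)
    A_T = np.einsum("np,nij->pij", Q, C)
    C_perp = C - np.einsum("np,pij->nij", Q, A_T)
    M = C_perp.reshape(n, p * p)
    U, sv, _ = np.linalg.svd(M, full_matrices=False)
    if sv.size and sv[0] > 0:
        rank = int(np.sum(sv > sv[0] * 1e-12))
    else:
        rank = 0
    A_N = np.einsum("nm,nij->mij", U[:, :rank], C_perp)
    rho = D.s * np.sqrt(p)
    return rho * A_T, rho * A_N, rho


def _gamma_rms_from_faces(faces: np.ndarray, p: int) -> float:
    # E_d[(d'Ad)^2] over the unit sphere = (2 tr(A^2) + (tr A)^2) / (P(P+2))
    if faces.size == 0:
        return 0.0
    tr = np.trace(faces, axis1=1, axis2=2)
    tr_sq = np.einsum("mij,mji->m", faces, faces)
    total = float(np.sum(2.0 * tr_sq + tr**2))
    return float(np.sqrt(total / (p * (p + 2.0))))


def rms_relative_curvatures(
    D: DerivativeArrays, n: int | None = None, p: int | None = None
) -> tuple[float, float]:
    """Root-mean-square relative intrinsic and parameter-effects curvatures.

    Closed form of the sphere average of the squared directional relative
    curvature.  Returns ``(gamma_N, gamma_T)``.  With N = P the normal
    space is zero-dimensional and ``gamma_N`` is returned as 0 with a
    warning.
    """
    n = D.n_obs if n is None else n
    p = D.n_params if p is None else p
    A_T, A_N, _ = curvature_faces(D)
    gamma_T = _gamma_rms_from_faces(A_T, p)
    if n == p:
        warnings.warn("N = P: normal space is empty, gamma_N set to 0",
                      RuntimeWarning)
        return 0.0, gamma_T
    gamma_N = _gamma_rms_from_faces(A_N, p)
    return gamma_N, gamma_T


def critical_curvature(n: int, p: int, alpha: float = 0.05) -> float:
    """Critical curvature ``K_c = 1 / sqrt(F(P, N-P; alpha))``.

    ``F(P, N-P; alpha)`` is the upper-``alpha`` quantile of the F
    distribution with (P, N-P) degrees of freedom; alpha defaults to 0.05.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n <= p or p < 1:
        raise ValueError(f"invalid degrees of freedom: P={p}, N-P={n - p}")
    q = f_dist.ppf(1.0 - alpha, p, n - p)
    return float(1.0 / np.sqrt(q))


def box_bias(
    D: DerivativeArrays,
    estimate,
    n: int | None = None,
    p: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Box's second-order bias approximation and percentage bias.

    ``bias = -(s^2 / 2) (V'V)^{-1} sum_i v_i tr[(V'V)^{-1} W_i]`` and
    ``P_b_j = 100 * bias_j / phi_hat_j``.  ``estimate`` may be a
    :class:`GielisParameters` or a plain parameter vector.
    """
    phi = (
        estimate.free_values
        if isinstance(estimate, GielisParameters)
        else np.asarray(estimate, dtype=float)
    )
    if np.any(phi == 0):
        raise ValueError("percentage bias undefined for zero-valued estimate")
    V, W, s = D.V, D.W, D.s
    G = V.T @ V
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("V'V is singular") from exc
    t = np.einsum("jk,nkj->n", Ginv, W)
    bias = -0.5 * s**2 * (Ginv @ (V.T @ t))
    p_b = 100.0 * bias / phi
    return bias, p_b


@dataclass(frozen=True)
class NonlinearityReport:
    """Assembled nonlinearity diagnostics for one fitted leaf x variant."""

    leaf_id: str
    variant: SGEVariant
    gamma_N: float
    gamma_T: float
    K_c: float
    alpha: float
    planar_ok: bool
    uniform_ok: bool
    bias: np.ndarray
    P_b: np.ndarray
    close_to_linear_params: np.ndarray
    n_used: int
    n_params: int
    s: float
    bias_threshold_pct: float = 1.0

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.variant.parameter_names

    def to_record(self) -> dict:
        rec = {
            "leaf_id": self.leaf_id,
            "variant": self.variant.value,
            "gamma_N": self.gamma_N,
            "gamma_T": self.gamma_T,
            "K_c": self.K_c,
            "alpha": self.alpha,
            "planar_ok": self.planar_ok,
            "uniform_ok": self.uniform_ok,
            "n_used": self.n_used,
            "s": self.s,
        }
        for name in ("a", "n1", "n2", "n3"):
            if name in self.parameter_names:
                j = self.parameter_names.index(name)
                rec[f"bias_{name}"] = float(self.bias[j])
                rec[f"Pb_{name}"] = float(self.P_b[j])
                rec[f"close_{name}"] = bool(self.close_to_linear_params[j])
            else:
                rec[f"bias_{name}"] = np.nan
                rec[f"Pb_{name}"] = np.nan
                rec[f"close_{name}"] = np.nan
        return rec


def diagnose(
    polar: PolarContour,
    fit: FitResult,
    alpha: float = 0.05,
    bias_threshold_pct: float = 1.0,
) -> NonlinearityReport:
    """Full nonlinearity report at a converged fit.

    Composes :func:`model_derivatives`, :func:`rms_relative_curvatures`,
    :func:`critical_curvature` and :func:`box_bias`.  ``N`` is the number of
    retained (kink-free) observations.
    """
    try:
        D, mask = model_derivatives(polar, fit.estimate)
        n_used = int(np.sum(mask))
        p = fit.variant.n_parameters
        gamma_N, gamma_T = rms_relative_curvatures(D, n_used, p)
        k_c = critical_curvature(n_used, p, alpha)
        bias, p_b = box_bias(D, fit.estimate, n_used, p)
    except Exception as exc:
        raise type(exc)(
            f"diagnostics failed for leaf '{fit.leaf_id}' "
            f"({fit.variant.value}): {exc}"
        ) from exc
    return NonlinearityReport(
        leaf_id=fit.leaf_id,
        variant=fit.variant,
        gamma_N=gamma_N,
        gamma_T=gamma_T,
        K_c=k_c,
        alpha=alpha,
        planar_ok=bool(gamma_N < k_c),
        uniform_ok=bool(gamma_T < k_c),
        bias=bias,
        P_b=p_b,
        close_to_linear_params=np.abs(p_b) < bias_threshold_pct,
        n_used=n_used,
        n_params=p,
        s=D.s,
        bias_threshold_pct=bias_threshold_pct,
    )
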