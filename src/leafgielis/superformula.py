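"""The Gielis superformula and its simplified variants.

The Gielis equation generalises the superellipse to polar coordinates,

    r(theta) = a * (|cos(m*theta/4)|^n2 + |(1/k) sin(m*theta/4)|^n3)^(-1/n1),

and generates a large family of closed natural shapes.  Lanceolate leaf
outlines are well described by the ``k = m = 1`` specialisation, of which
three nested variants are used here:

* SGE-1 — four free parameters ``(a, n1, n2, n3)``;
* SGE-2 — three parameters, tying ``n3 = n2`` (bilaterally symmetric);
* SGE-3 — two parameters ``(a, n1)``, additionally setting ``n2 = n3 = 1``.

``a`` sets the overall scale (length units of the contour); ``n1`` is the
principal shape exponent (small ``n1`` gives long, narrow outlines); ``n2``
and ``n3`` control the symmetry of the two flanks.  All functions accept
scalar or array ``theta`` and broadcast; ``theta`` is understood on
``[0, 2*pi)`` with the curve closing at ``theta = 0 == 2*pi`` (wrapping is
the caller's responsibility).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SGEVariant",
    "GielisParameters",
    "gielis_radius_general",
    "sge_radius",
    "sample_curve",
    "equal_arclength_theta",
]


class SGEVariant(enum.Enum):
    """The three simplified Gielis equations, by free-parameter count."""

    SGE1 = "SGE1"
    SGE2 = "SGE2"
    SGE3 = "SGE3"

    @property
    def n_parameters(self) -> int:
        """Number of free parameters P (4, 3 or 2)."""
        return {SGEVariant.SGE1: 4, SGEVariant.SGE2: 3, SGEVariant.SGE3: 2}[self]

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return ("a", "n1", "n2", "n3")[: self.n_parameters]

    @classmethod
    def coerce(cls, value: "SGEVariant | str") -> "SGEVariant":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper().replace("-", ""))


# Frozen constants of the parent form used by every simplified variant.
GIELIS_K = 1.0
GIELIS_M = 1.0


@dataclass(frozen=True)
class GielisParameters:
    """Parameter vector ``(a, n1, n2, n3)`` with its variant tag.

    Variant tying rules are enforced at construction: SGE-2 requires
    ``n3 == n2`` exactly, SGE-3 requires ``n2 == n3 == 1`` exactly.
    Positivity of all four components is enforced by default; pass
    ``strict=False`` to relax (exploratory use only).
    """

    a: float
    n1: float
    n2: float = 1.0
    n3: float = 1.0
    variant: SGEVariant = SGEVariant.SGE1
    strict: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", SGEVariant.coerce(self.variant))
        vals = (self.a, self.n1, self.n2, self.n3)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite Gielis parameters: {vals}")
        if self.strict and not all(v > 0 for v in vals):
            raise ValueError(
                f"Gielis parameters must be positive, got a={self.a}, "
                f"n1={self.n1}, n2={self.n2}, n3={self.n3}"
            )
        if self.variant is SGEVariant.SGE2 and self.n3 != self.n2:
            raise ValueError("SGE-2 requires n3 == n2 exactly")
        if self.variant is SGEVariant.SGE3 and not (self.n2 == self.n3 == 1.0):
            raise ValueError("SGE-3 requires n2 == n3 == 1 exactly")

    @classmethod
    def from_free(
        cls,
        variant: SGEVariant | str,
        values,
        strict: bool = True,
    ) -> "GielisParameters":
        """Build from the variant's free-parameter vector.

        ``values`` is ``(a, n1)`` for SGE-3, ``(a, n1, n2)`` for SGE-2 and
        ``(a, n1, n2, n3)`` for SGE-1; tied components are filled in.
        """
        variant = SGEVariant.coerce(variant)
        values = [float(v) for v in np.asarray(values, dtype=float)]
        if len(values) != variant.n_parameters:
            raise ValueError(
                f"{variant.value} takes {variant.n_parameters} free parameters, "
                f"got {len(values)}"
            )
        if variant is SGEVariant.SGE3:
            a, n1 = values
            return cls(a, n1, 1.0, 1.0, variant, strict=strict)
        if variant is SGEVariant.SGE2:
            a, n1, n2 = values
            return cls(a, n1, n2, n2, variant, strict=strict)
        a, n1, n2, n3 = values
        return cls(a, n1, n2, n3, variant, strict=strict)

    @property
    def free_values(self) -> np.ndarray:
        """The variant's free-parameter vector as an array."""
        return np.array((self.a, self.n1, self.n2, self.n3)[: self.variant.n_parameters])

    def with_variant(self, variant: SGEVariant | str) -> "GielisParameters":
        return replace(self, variant=SGEVariant.coerce(variant))


def gielis_radius_general(theta, a, k, m, n1, n2, n3):
    """Polar radius of the full Gielis superformula.

    ``r(theta) = a * (|cos(m*theta/4)|^n2 + |(1/k) sin(m*theta/4)|^n3)^(-1/n1)``

    Broadcasts over array ``theta``.  Raises on non-finite inputs or
    ``a <= 0``, ``k <= 0``, ``n1 == 0``.
    """
    theta = np.asarray(theta, dtype=float)
    scalars = np.array([a, k, m, n1, n2, n3], dtype=float)
    if not (np.all(np.isfinite(scalars)) and np.all(np.isfinite(theta))):
        raise ValueError("non-finite input to gielis_radius_general")
    if a <= 0 or k <= 0 or n1 == 0:
        raise ValueError(f"require a > 0, k > 0, n1 != 0; got a={a}, k={k}, n1={n1}")
    c = np.abs(np.cos(m * theta / 4.0))
    s = np.abs(np.sin(m * theta / 4.0)) / k
    bracket = c**n2 + s**n3
    return a * bracket ** (-1.0 / n1)


def sge_radius(theta, params: GielisParameters):
    """Polar radius of a simplified Gielis equation (k = m = 1).

    Equivalent to :func:`gielis_radius_general` with the variant's tying
    rules applied; vectorises over ``theta``.
    """
    if not isinstance(params, GielisParameters):
        raise TypeError("params must be a GielisParameters instance")
    return gielis_radius_general(
        theta, params.a, GIELIS_K, GIELIS_M, params.n1, params.n2, params.n3
    )


def _radius_from_cs(c, s, a, n1, n2, n3):
    # Fast inner kernel for fitting: c = |cos(theta/4)|, s = |sin(theta/4)|
    # precomputed once per contour.  Returns +inf-safe values for the
    # optimiser rather than raising.
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if n2 == 1.0 and n3 == 1.0:
            bracket = c + s
        else:
            bracket = c**n2 + s**n3
        return a * bracket ** (-1.0 / n1)


def equal_arclength_theta(
    params: GielisParameters, n_points: int, oversample: int = 16
) -> np.ndarray:
    """Angles whose curve points are equidistant along the perimeter.

    The cumulative arc length is tabulated on an ``oversample * n_points``
    theta grid and inverted by interpolation, so the returned points lie
    exactly ON the curve (no polygon interpolation) while their spacing is
    equal to well under 0.1%.  The first angle is 0 (the apex).
    """
    n_fine = int(oversample) * int(n_points)
    theta_fine = np.linspace(0.0, 2.0 * np.pi, n_fine + 1)
    r = sge_radius(theta_fine, params)
    pts = np.column_stack([r * np.cos(theta_fine), r * np.sin(theta_fine)])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, cum[-1], int(n_points), endpoint=False)
    return np.interp(target, cum, theta_fine)


def sample_curve(
    params: GielisParameters,
    n_points: int,
    closed: bool = True,
    equal_arclength: bool = False,
) -> np.ndarray:
    """Cartesian sample of the curve, ordered by theta over ``[0, 2*pi)``.

    Returns an ``(n_points, 2)`` array.  With ``equal_arclength=True`` the
    angles are chosen so the points are equally spaced along the perimeter
    (first point, at theta = 0, preserved; points remain exactly on the
    curve).
    """
    n_points = int(n_points)
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if equal_arclength:
        theta = equal_arclength_theta(params, n_points)
    else:
        theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=not closed)
    r = sge_radius(theta, params)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
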