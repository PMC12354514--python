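"""Reading, normalising and polar-converting planar leaf-boundary contours.

Input files are plain two-column tables of boundary coordinates (comma, tab
or whitespace delimited, optional header), one file per leaf — the layout in
which digitised leaf boundaries are commonly deposited (roughly 2000
arc-length-equidistant points per leaf).  This module validates such files,
normalises traversal to counter-clockwise, places the polar point (pole) at
an end of the maximal chord, and converts to the ``(theta_i, r_i)`` form the
regression consumes.

Coordinate convention: y grows upward, angles counter-clockwise, theta
wrapped to ``[0, 2*pi)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from ._geometry import (
    max_chord_endpoints,
    polygon_signed_area,
    resample_closed_polyline,
)

__all__ = [
    "PlanarContour",
    "PolarContour",
    "PoleCandidate",
    "ReadDialect",
    "ContourError",
    "ContourParseError",
    "EmptyContourError",
    "TooFewPointsError",
    "PoleOnBoundaryError",
    "read_contour",
    "write_contour",
    "estimate_pole_and_axis",
    "to_polar",
    "from_polar",
    "resample_equidistant",
    "read_contour_directory",
]

TWO_PI = 2.0 * np.pi


class ContourError(ValueError):
    """Base class for contour input problems."""


class EmptyContourError(ContourError):
    pass


class ContourParseError(ContourError):
    pass


class TooFewPointsError(ContourError):
    pass


class PoleOnBoundaryError(ContourError):
    pass


@dataclass(frozen=True)
class ReadDialect:
    """Format options for :func:`read_contour`.

    ``delimiter=None`` auto-splits on commas, tabs or runs of whitespace;
    ``min_points`` is the validation floor (50 for real leaf data; test
    fixtures may lower it).
    """

    delimiter: str | None = None
    min_points: int = 50


@dataclass(frozen=True)
class PlanarContour:
    """An ordered closed planar boundary, normalised to CCW traversal."""

    points: np.ndarray
    leaf_id: str = ""
    is_closed: bool = True

    @classmethod
    def from_points(
        cls,
        points,
        leaf_id: str = "",
        is_closed: bool = True,
        min_points: int = 50,
    ) -> "PlanarContour":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError(f"expected an (N, 2) array, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ContourError("non-finite coordinates in contour")
        # drop consecutive duplicates (including a repeated closing point)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        pts = pts[keep]
        if len(pts) > 1 and np.all(pts[0] == pts[-1]):
            pts = pts[:-1]
        if len(pts) < min_points:
            raise TooFewPointsError(
                f"contour '{leaf_id}' has {len(pts)} points; need >= {min_points}"
            )
        if is_closed and len(pts) >= 3 and polygon_signed_area(pts) < 0:
            pts = pts[::-1].copy()
        pts.setflags(write=False)
        return cls(points=pts, leaf_id=leaf_id, is_closed=is_closed)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)


class PoleCandidate(NamedTuple):
    pole: np.ndarray        # nudged slightly off the boundary
    axis_angle: float       # direction of theta = 0, pointing along the chord
    endpoint: np.ndarray    # the raw contour point at this end of the chord


@dataclass(frozen=True)
class PolarContour:
    """Polar form of a contour about a chosen pole and axis.

    ``theta`` is sorted ascending in ``[0, 2*pi)``; ``r`` are the Euclidean
    distances from the pole.  ``pole_inside`` is False when theta was not
    monotone in traversal order (pole outside the outline)."""

    pole: np.ndarray
    axis_angle: float
    theta: np.ndarray
    r: np.ndarray
    leaf_id: str = ""
    pole_inside: bool = True

    def __post_init__(self) -> None:
        if len(self.theta) != len(self.r):
            raise ContourError("theta and r must have equal length")
        if np.any(self.r < 0):
            raise ContourError("negative polar radius")

    def __len__(self) -> int:
        return len(self.theta)

    def to_planar(self) -> np.ndarray:
        """Cartesian points; inverse of :func:`to_polar` up to ordering."""
        ang = self.theta + self.axis_angle
        return np.column_stack(
            [
                self.pole[0] + self.r * np.cos(ang),
                self.pole[1] + self.r * np.sin(ang),
            ]
        )


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str, delimiter: str | None) -> list[str]:
    if delimiter is not None:
        return [f.strip() for f in line.split(delimiter)]
    return [f for f in re.split(r"[,\t;]+|\s+", line.strip()) if f]


def read_contour(
    path, dialect: ReadDialect | None = None, leaf_id: str | None = None
) -> PlanarContour:
    """Read one leaf boundary from a two-column coordinate file.

    An optional single header row (non-numeric fields) is skipped.  Distinct
    errors are raised for an empty file, a non-numeric data row (named by
    line number) and too few points.
    """
    dialect = dialect or ReadDialect()
    path = Path(path)
    if leaf_id is None:
        leaf_id = path.stem
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_started = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = _split_row(line, dialect.delimiter)
        numeric = all(_NUMERIC_RE.match(f) for f in fields)
        if not numeric:
            if not data_started:
                continue  # header row
            raise ContourParseError(
                f"{path}: non-numeric row at line {lineno}: {line!r}"
            )
        if len(fields) < 2:
            raise ContourParseError(
                f"{path}: expected two columns at line {lineno}: {line!r}"
            )
        rows.append((float(fields[0]), float(fields[1])))
        data_started = True
    if not rows:
        raise EmptyContourError(f"{path}: no coordinate data found")
    return PlanarContour.from_points(
        rows, leaf_id=leaf_id, min_points=dialect.min_points
    )


def write_contour(contour: PlanarContour, path) -> None:
    """Write a contour back to a two-column CSV (header ``x,y``)."""
    arr = np.asarray(contour.points)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x,y\n")
        for x, y in arr:
            fh.write(f"{x:.10g},{y:.10g}\n")


def read_contour_directory(
    directory,
    dialect: ReadDialect | None = None,
    pattern: str = "*.csv",
    exclude: tuple[str, ...] = ("truth",),
) -> list[PlanarContour]:
    """Read every matching file in a directory; leaf_id = file stem.

    File stems in ``exclude`` (metadata tables such as ``truth.csv``) are
    skipped.
    """
    paths = sorted(Path(directory).glob(pattern))
    return [
        read_contour(p, dialect=dialect)
        for p in paths
        if p.stem not in exclude
    ]


def estimate_pole_and_axis(
    contour: PlanarContour, nudge_frac: float = 1e-6
) -> tuple[np.ndarray, float, list[PoleCandidate]]:
    """Candidate poles at the two endpoints of the maximal chord.

    For a lanceolate outline the natural pole sits near one end of the long
    axis; rather than classifying base vs apex, both chord endpoints are
    returned and the caller keeps the one whose fit attains the lower RSS.
    Each candidate pole is nudged inward along the chord (toward the other
    endpoint) by ``nudge_frac * chord_length`` so it never coincides with a
    boundary point and nearby boundary points are seen at theta near pi,
    matching the model's geometry (the Gielis pole lies inside the outline).
    Returns ``(pole, axis_angle, candidates)`` with the first candidate as
    the default.
    """
    pts = np.asarray(contour.points, dtype=float)
    # degenerate (collinear) check via singular values of centred points
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[0] <= 0 or sv[1] / sv[0] < 1e-9:
        raise ContourError("degenerate contour: points are collinear")
    i, j = max_chord_endpoints(pts)
    candidates = []
    for p_idx, q_idx in ((i, j), (j, i)):
        p, q = pts[p_idx], pts[q_idx]
        chord = q - p
        length = float(np.hypot(*chord))
        unit = chord / length
        pole = p + nudge_frac * length * unit
        axis = float(math.atan2(unit[1], unit[0]))
        candidates.append(PoleCandidate(pole=pole, axis_angle=axis, endpoint=p))
    return candidates[0].pole, candidates[0].axis_angle, candidates


def to_polar(
    contour: PlanarContour, pole, axis_angle: float, min_distance: float = 1e-12
) -> PolarContour:
    """Convert a planar contour to ``(theta, r)`` about ``pole``.

    theta is the angle of ``point - pole`` measured CCW from ``axis_angle``,
    wrapped to ``[0, 2*pi)``; r is the Euclidean distance.  Points are sorted
    by theta.  Raises :class:`PoleOnBoundaryError` when the pole lies within
    ``min_distance`` of a boundary point (perturb the pole and retry).
    """
    pole = np.asarray(pole, dtype=float)
    delta = contour.points - pole
    r = np.hypot(delta[:, 0], delta[:, 1])
    if np.any(r < min_distance):
        raise PoleOnBoundaryError(
            "pole coincides with a boundary point; perturb the pole slightly "
            "off the contour and retry"
        )
    theta = np.mod(np.arctan2(delta[:, 1], delta[:, 0]) - axis_angle, TWO_PI)
    # monotone in traversal order (up to one wrap) iff the pole is inside
    dtheta = np.diff(theta)
    wraps = int(np.sum(dtheta < 0)) if len(theta) > 2 else 0
    pole_inside = wraps <= 1
    order = np.argsort(theta, kind="stable")
    return PolarContour(
        pole=pole,
        axis_angle=float(axis_angle),
        theta=theta[order],
        r=r[order],
        leaf_id=contour.leaf_id,
        pole_inside=pole_inside,
    )


def from_polar(polar: PolarContour, min_points: int = 3) -> PlanarContour:
    """Rebuild a planar contour from polar form (round-trip inverse)."""
    return PlanarContour.from_points(
        polar.to_planar(), leaf_id=polar.leaf_id, min_points=min_points
    )


def resample_equidistant(contour: PlanarContour, n: int) -> PlanarContour:
    """Resample a closed contour to ``n`` equal-arc-length points.

    The first point is preserved and the perimeter changes by < 0.1% for
    reasonable ``n``.  Raises on open contours.
    """
    if not contour.is_closed:
        raise ContourError("resampling requires a closed contour")
    pts = resample_closed_polyline(contour.points, n)
    return PlanarContour.from_points(
        pts, leaf_id=contour.leaf_id, min_points=min(n, 3)
    )
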