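"""Small planar-geometry helpers shared by contour handling and simulation."""

from __future__ import annotations

import numpy as np


def polygon_signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (CCW positive)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(points: np.ndarray, closed: bool = True) -> float:
    d = np.diff(points, axis=0)
    per = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if closed:
        per += float(np.hypot(*(points[0] - points[-1])))
    return per


def resample_closed_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` points at equal arc-length spacing.

    The first input point is preserved as the first output point; traversal
    direction is preserved.
    """
    n = int(n)
    if n < 3:
        raise ValueError("n must be >= 3")
    pts = np.asarray(points, dtype=float)
    ring = np.vstack([pts, pts[:1]])
    seg = np.hypot(*(np.diff(ring, axis=0).T))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polygon with zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, cum, ring[:, 0])
    y = np.interp(target, cum, ring[:, 1])
    return np.column_stack([x, y])


def is_simple_polygon(points: np.ndarray) -> bool:
    """Brute-force segment-intersection test for polygon simplicity.

    O(n^2); intended for test fixtures and validity scans on modest n.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n)]

    def _ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        a1, a2 = segs[i]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            b1, b2 = segs[j]
            d1 = _ccw(b1, b2, a1)
            d2 = _ccw(b1, b2, a2)
            d3 = _ccw(a1, a2, b1)
            d4 = _ccw(a1, a2, b2)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return False
    return True


def max_chord_endpoints(points: np.ndarray) -> tuple[int, int]:
    """Indices of the two points realising the maximal chord (diameter).

    Uses the convex hull to restrict the O(n^2) pair search; the diameter of
    a point set is attained on its hull.
    """
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(points, dtype=float)
    try:
        hull_idx = np.asarray(ConvexHull(pts).vertices)
    except QhullError as exc:  # collinear / degenerate input
        raise ValueError(f"degenerate contour (convex hull failed): {exc}") from exc
    hp = pts[hull_idx]
    d2 = np.sum((hp[:, None, :] - hp[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    return int(hull_idx[i]), int(hull_idx[j])


def rotate_translate(points: np.ndarray, angle: float, offset) -> np.ndarray:
    """Rigid motion: rotate CCW by ``angle`` about the origin, then translate."""
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    return points @ rot.T + np.asarray(offset, dtype=float)
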