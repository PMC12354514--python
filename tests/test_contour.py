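"""Contour I/O, pole estimation, polar conversion and resampling."""

import numpy as np
import pytest

from leafgielis import (
    GielisParameters,
    PlanarContour,
    ReadDialect,
    estimate_pole_and_axis,
    generate_leaf,
    read_contour,
    resample_equidistant,
    to_polar,
)
from leafgielis._geometry import polygon_perimeter, polygon_signed_area
from leafgielis.contour import (
    ContourParseError,
    EmptyContourError,
    PoleOnBoundaryError,
    TooFewPointsError,
    from_polar,
    write_contour,
)

TEST_DIALECT = ReadDialect(min_points=4)


class TestReadContour:
    def test_small_square_file(self, tmp_path):
        path = tmp_path / "sq.csv"
        path.write_text("0,0\n1,0\n1,1\n0,1\n")
        c = read_contour(path, dialect=TEST_DIALECT)
        assert len(c) == 4
        assert polygon_signed_area(c.points) > 0  # CCW

    def test_header_then_data(self, tmp_path):
        path = tmp_path / "leaf.csv"
        rows = "\n".join(
            f"{np.cos(t):.8f},{np.sin(t):.8f}"
            for t in np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        )
        path.write_text("x,y\n" + rows + "\n")
        c = read_contour(path)
        assert len(c) == 2000
        assert c.leaf_id == "leaf"

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0,0\n1,0\na,b\n0,1\n")
        with pytest.raises(ContourParseError, match="line 3"):
            read_contour(path, dialect=TEST_DIALECT)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("\n")
        with pytest.raises(EmptyContourError):
            read_contour(path, dialect=TEST_DIALECT)

    def test_too_few_points(self, tmp_path):
        path = tmp_path / "few.csv"
        path.write_text("0,0\n1,0\n1,1\n0,1\n")
        with pytest.raises(TooFewPointsError):
            read_contour(path)  # default floor of 50

    @pytest.mark.parametrize("sep", [",", "\t", " "])
    def test_delimiters(self, tmp_path, sep):
        path = tmp_path / "d.csv"
        path.write_text(f"0{sep}0\n1{sep}0\n1{sep}1\n0{sep}1\n")
        assert len(read_contour(path, dialect=TEST_DIALECT)) == 4

    def test_duplicate_and_closing_points_dropped(self):
        pts = [(0, 0), (1, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        c = PlanarContour.from_points(pts, min_points=3)
        assert len(c) == 4

    def test_roundtrip_write_read(self, tmp_path, square_contour):
        path = tmp_path / "out.csv"
        write_contour(square_contour, path)
        back = read_contour(path, dialect=TEST_DIALECT)
        np.testing.assert_allclose(back.points, square_contour.points)


class TestPoleEstimation:
    def test_square_diagonal_endpoints(self, square_contour):
        _, _, cands = estimate_pole_and_axis(square_contour)
        # brute force over all point pairs
        pts = square_contour.points
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        expected = {tuple(pts[i]), tuple(pts[j])}
        got = {tuple(c.endpoint) for c in cands}
        assert got == expected

    def test_recovers_pose_of_synthetic_leaf(self):
        params = GielisParameters.from_free("SGE3", [10.0, 0.05])
        pose = (np.deg2rad(30.0), 5.0, -2.0)
        leaf = generate_leaf(params, 2000, 0.0, pose, seed=0)
        _, _, cands = estimate_pole_and_axis(leaf)
        true_pole = np.array([5.0, -2.0])
        length = polygon_perimeter(leaf.points)
        dists = [np.linalg.norm(c.pole - true_pole) for c in cands]
        best = int(np.argmin(dists))
        assert dists[best] < 0.02 * length
        axis_err = np.abs(
            np.angle(np.exp(1j * (cands[best].axis_angle - pose[0]))))
        assert axis_err < np.deg2rad(2.0)

    def test_collinear_contour_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 60), np.zeros(60)])
        c = PlanarContour(points=pts, leaf_id="line", is_closed=False)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            estimate_pole_and_axis(c)

    def test_circle_degenerate_but_usable(self):
        t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        c = PlanarContour.from_points(np.column_stack([np.cos(t), np.sin(t)]))
        _, _, cands = estimate_pole_and_axis(c)
        assert len(cands) == 2  # any diameter is acceptable


class TestToPolar:
    def test_square_angles_about_centroid(self, square_contour):
        polar = to_polar(square_contour, (0.5, 0.5), 0.0)
        expected = np.array([1, 3, 5, 7]) * np.pi / 4.0
        np.testing.assert_allclose(np.sort(polar.theta), expected, atol=1e-12)
        np.testing.assert_allclose(polar.r, np.sqrt(0.5))

    def test_round_trip(self, square_contour):
        polar = to_polar(square_contour, (0.4, 0.3), 0.7)
        back = polar.to_planar()
        orig = sorted(map(tuple, square_contour.points))
        got = sorted(map(tuple, np.round(back, 12)))
        np.testing.assert_allclose(got, orig, atol=1e-9)
        rebuilt = from_polar(polar)
        assert len(rebuilt) == len(square_contour)

    def test_pole_on_boundary_raises(self, square_contour):
        with pytest.raises(PoleOnBoundaryError):
            to_polar(square_contour, (0.0, 0.0), 0.0)

    def test_pole_outside_sets_flag(self, square_contour):
        polar = to_polar(square_contour, (5.0, 5.0), 0.0)
        assert not polar.pole_inside
        assert np.all(polar.r > 0)

    def test_pose_equivariance(self):
        params = GielisParameters.from_free("SGE3", [8.0, 0.06])
        base = generate_leaf(params, 800, 0.005, None, seed=4)
        moved_pts = base.points @ np.array(
            [[np.cos(1.1), -np.sin(1.1)], [np.sin(1.1), np.cos(1.1)]]
        ).T + [7.0, -3.0]
        moved = PlanarContour.from_points(moved_pts, leaf_id="moved")
        polars = []
        for contour in (base, moved):
            _, _, cands = estimate_pole_and_axis(contour)
            polars.append(to_polar(contour, cands[0].pole,
                                   cands[0].axis_angle))
        np.testing.assert_allclose(np.sort(polars[0].r),
                                   np.sort(polars[1].r), atol=1e-6)
        np.testing.assert_allclose(np.sort(polars[0].theta),
                                   np.sort(polars[1].theta), atol=1e-6)


class TestResample:
    def test_square_eight_points(self, square_contour):
        out = resample_equidistant(square_contour, 8)
        ring = np.vstack([out.points, out.points[:1]])
        seg = np.hypot(*np.diff(ring, axis=0).T)
        np.testing.assert_allclose(seg, 0.5, atol=1e-12)
        np.testing.assert_allclose(out.points[0], square_contour.points[0])

    def test_idempotent_on_equidistant_input(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        c = PlanarContour.from_points(pts, min_points=3)
        out = resample_equidistant(c, 64)
        np.testing.assert_allclose(out.points, c.points, atol=1e-9)

    def test_perimeter_preserved_on_smooth_leaf(self):
        # point-wise independent jitter at 2000-point density zigzags the
        # polyline, so perimeter preservation is a property of the smooth
        # boundary; area (below) is the robust noisy-case invariant
        params = GielisParameters.from_free("SGE3", [10.0, 0.05])
        leaf = generate_leaf(params, 2000, 0.0, None, seed=2)
        down = resample_equidistant(leaf, 500)
        p_in = polygon_perimeter(leaf.points)
        p_out = polygon_perimeter(down.points)
        assert abs(p_out - p_in) / p_in < 1e-3

    def test_area_preserved_on_synthetic_leaf(self):
        params = GielisParameters.from_free("SGE1", [9.0, 0.06, 0.8, 1.1])
        leaf = generate_leaf(params, 2000, 0.005, None, seed=3)
        down = resample_equidistant(leaf, 500)
        a_in = polygon_signed_area(leaf.points)
        a_out = polygon_signed_area(down.points)
        assert abs(a_out - a_in) / abs(a_in) < 5e-3

    def test_open_contour_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 60),
                               np.linspace(0, 1, 60) ** 2])
        c = PlanarContour(points=pts, leaf_id="open", is_closed=False)
        with pytest.raises(ValueError):
            resample_equidistant(c, 32)
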