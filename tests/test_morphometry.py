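"""Closed-form and oracle checks for the morphometric suite."""
import numpy as np
import pytest
from scipy import special
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_skeleton, random_outward_tree
from gliaclone import (
    circularity,
    convex_hull_metrics,
    count_branches,
    measure_cell,
    project_silhouette,
    sholl_3d,
    solidity,
    total_thickness,
)
from gliaclone.morphometry import mask_perimeter


class TestSilhouette:
    def test_disc_area_and_circularity(self):
        soma = make_skeleton([(1, 1, 0, 0, 0, 10.0, -1)])
        mask, perim = project_silhouette(soma, pixel_size=0.2)
        area = mask.sum() * 0.2**2
        assert area == pytest.approx(np.pi * 100, rel=0.02)
        assert 0.95 <= circularity(area, perim) <= 1.02

    def test_square_mask_circularity(self):
        mask = np.zeros((70, 70), dtype=bool)
        mask[10:60, 10:60] = True  # 10 x 10 um square at 0.2 um/px
        area = mask.sum() * 0.2**2
        perim = mask_perimeter(mask, 0.2)
        assert circularity(area, perim) == pytest.approx(np.pi / 4, rel=0.03)

    def test_empty_skeleton_fails(self):
        # a zero-radius point occupies no pixel
        ghost = make_skeleton([(1, 0, 0, 0, 0, 0.0, -1)])
        with pytest.raises(ValueError, match="empty"):
            project_silhouette(ghost, pixel_size=0.5)


class TestCircularity:
    def test_perfect_circle_is_one(self):
        r = 7.3
        assert circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_square_closed_form(self):
        s = 4.2
        assert circularity(s**2, 4 * s) == pytest.approx(np.pi / 4)

    def test_ellipse_against_elliptic_integral(self):
        a, b = 2.0, 1.0
        e2 = 1 - (b / a) ** 2
        perimeter = 4 * a * special.ellipe(e2)  # numeric oracle
        c = circularity(np.pi * a * b, perimeter)
        assert c == pytest.approx(0.8412, abs=0.001)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            circularity(0.0, 1.0)


class TestSolidity:
    def test_convex_silhouette_is_one(self):
        assert solidity(12.0, 12.0) == 1.0

    def test_plus_sign_five_sevenths(self):
        # two crossed 3x1 um rectangles: area 5, hull (3x3 square minus 4
        # corner triangles) = 7
        px = 0.02
        n = int(3 / px)
        mask = np.zeros((n, n), dtype=bool)
        third = int(1 / px)
        mask[:, third : 2 * third] = True
        mask[third : 2 * third, :] = True
        area = mask.sum() * px**2
        idx = np.argwhere(mask).astype(float)
        corners = np.concatenate(
            [idx + d for d in ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])]
        ) * px
        hull_area = convex_hull_metrics(corners, mode="2D")
        assert solidity(area, hull_area) == pytest.approx(5 / 7, rel=0.01)

    def test_thin_star_below_half(self):
        # three thin 10x0.2 um arms from the center
        px = 0.05
        arms = []
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            t = np.linspace(0, 10, 400)
            arms.append(np.column_stack([t * np.cos(ang), t * np.sin(ang)]))
        pts = np.concatenate(arms)
        idx = np.unique(np.round(pts / px).astype(int), axis=0)
        area = len(idx) * px**2  # ~thin arms
        corners = np.concatenate(
            [idx + d for d in ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])]
        ) * px
        hull_area = convex_hull_metrics(corners.astype(float), mode="2D")
        assert solidity(area, hull_area) < 0.5

    def test_cell_larger_than_hull_fails(self):
        with pytest.raises(ValueError, match="hull"):
            solidity(10.0, 5.0)


class TestConvexHull:
    def test_unit_cube(self):
        pts = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        assert convex_hull_metrics(pts, mode="3D") == pytest.approx(1.0)

    def test_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        assert convex_hull_metrics(pts, mode="3D") == pytest.approx(1 / 6)

    def test_degenerate_fails_with_reason(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate"):
            convex_hull_metrics(line, mode="2D")

    def test_random_cloud_matches_facet_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(50, 3))
        got = convex_hull_metrics(pts, mode="3D")
        assert got == pytest.approx(_hull_volume_oracle(pts), rel=1e-9)


def _hull_volume_oracle(pts: np.ndarray) -> float:
    """Exhaustive facet enumeration: every point triple whose plane has all
    other points strictly on one side is a hull facet; sum signed tetrahedron
    volumes against the centroid."""
    from itertools import combinations

    centroid = pts.mean(axis=0)
    vol = 0.0
    for i, j, k in combinations(range(len(pts)), 3):
        a, b, c = pts[i], pts[j], pts[k]
        n = np.cross(b - a, c - a)
        side = (pts - a) @ n
        if (side > 1e-12).any() and (side < -1e-12).any():
            continue  # not a facet
        # orient the normal outward (away from the centroid)
        if (centroid - a) @ n > 0:
            n = -n
        vol += abs((a - centroid) @ np.cross(b - centroid, c - centroid)) / 6.0
    return vol


class TestBranches:
    def test_single_process_counts_one(self):
        sk = make_skeleton(
            [(1, 1, 0, 0, 0, 2.0, -1), (2, 0, 3, 0, 0, 0.5, 1), (3, 0, 6, 0, 0, 0.5, 2)]
        )
        assert count_branches(sk) == 1

    def test_one_bifurcation_counts_three(self, bifurcating_skeleton):
        assert count_branches(bifurcating_skeleton) == 3

    def test_random_binary_trees_have_2k_minus_1(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            # grow a random binary tree by splitting random tips
            nodes = [(1, 1, 0.0, 0.0, 0.0, 2.0, -1), (2, 0, 1.0, 0.0, 0.0, 0.5, 1)]
            tips = [2]
            for _ in range(int(rng.integers(1, 12))):
                t = int(rng.choice(tips))
                tips.remove(t)
                for _ in range(2):
                    nid = len(nodes) + 1
                    pos = rng.normal(size=3) * 5
                    nodes.append((nid, 0, *pos, 0.5, t))
                    tips.append(nid)
            sk = make_skeleton(nodes)
            assert count_branches(sk) == 2 * len(tips) - 1


class TestTotalThickness:
    def test_cylinder(self):
        sk = make_skeleton([(1, 0, 0, 0, 0, 1.0, -1), (2, 0, 10, 0, 0, 1.0, 1)])
        assert total_thickness(sk) == pytest.approx(np.pi * 10)

    def test_frustum(self):
        sk = make_skeleton([(1, 0, 0, 0, 0, 1.0, -1), (2, 0, 3, 0, 0, 2.0, 1)])
        assert total_thickness(sk) == pytest.approx(7 * np.pi)

    def test_threshold_filters_thin_branches(self):
        sk = make_skeleton([(1, 0, 0, 0, 0, 0.01, -1), (2, 0, 10, 0, 0, 0.01, 1)])
        assert total_thickness(sk, radius_threshold=0.05) == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(6)
        sk = random_outward_tree(rng)
        lo, hi = sorted([t1, t2])
        assert total_thickness(sk, hi) <= total_thickness(sk, lo) + 1e-12


class TestSholl:
    def test_straight_process(self, straight_path_skeleton):
        prof = sholl_3d(straight_path_skeleton, interval=4.0)
        assert prof.total_intersections == 2
        assert prof.ending_radius == 8.0
        assert prof.total_branch_length == pytest.approx(10.0)

    def test_bifurcation_counts(self, bifurcating_skeleton):
        prof = sholl_3d(bifurcating_skeleton, interval=4.0)
        assert dict(zip(prof.radii, prof.intersections)) == {4.0: 1, 8.0: 2, 12.0: 2}
        assert prof.total_intersections == 5
        assert prof.ending_radius == 12.0
        assert prof.total_branch_length == pytest.approx(5 + 7 + 13)

    def test_soma_only_all_zero(self):
        soma = make_skeleton([(1, 1, 0, 0, 0, 3.0, -1)])
        prof = sholl_3d(soma)
        assert prof.total_intersections == 0
        assert prof.ending_radius == 0.0
        assert prof.total_branch_length == 0.0

    def test_matches_dense_sampling_oracle_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            sk = random_outward_tree(rng)
            prof = sholl_3d(sk, interval=4.0)
            oracle = _sholl_oracle(sk, prof.radii)
            np.testing.assert_array_equal(prof.intersections, oracle)


def _sholl_oracle(sk, radii, step=0.01):
    """Walk each segment in 0.01 µm steps and count < r -> >= r transitions."""
    center = sk.soma_center()
    counts = np.zeros(len(radii), dtype=int)
    for pk, ck in sk.segments():
        a, b = sk.xyz[pk], sk.xyz[ck]
        L = np.linalg.norm(b - a)
        ts = np.linspace(0.0, 1.0, max(int(L / step), 2))
        d = np.linalg.norm(a[None] + ts[:, None] * (b - a)[None] - center[None], axis=1)
        for m, r in enumerate(radii):
            inside = d < r
            counts[m] += int(np.sum(inside[:-1] & ~inside[1:]))
    return counts


class TestFullSuite:
    def test_invariants_and_scaling(self):
        rng = np.random.default_rng(8)
        sk = random_outward_tree(rng, n_branch_events=6)
        base = measure_cell(sk, pixel_size=0.2, voxel_size=0.2)
        assert base.cell_body_area <= base.domain_area
        assert base.cell_body_volume <= base.domain_volume
        assert 0 < base.solidity <= 1
        assert base.avg_branch_thickness * base.n_branches == pytest.approx(
            base.total_thickness, rel=1e-6
        )
        for s in (0.5, 2.0):
            scaled = measure_cell(sk.scale(s), pixel_size=0.2 * s, voxel_size=0.2 * s)
            assert scaled.total_branch_length == pytest.approx(
                s * base.total_branch_length, rel=1e-6
            )
            assert scaled.cell_body_area == pytest.approx(s**2 * base.cell_body_area, rel=1e-6)
            assert scaled.domain_volume == pytest.approx(s**3 * base.domain_volume, rel=1e-6)
            assert scaled.circularity == pytest.approx(base.circularity, rel=1e-6)
            assert scaled.solidity == pytest.approx(base.solidity, rel=1e-6)
            assert scaled.n_branches == base.n_branches
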