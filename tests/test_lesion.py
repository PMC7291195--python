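"""Ring geometry, distances to lesion cores, inner/outer classification."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from shapely.geometry import Point, Polygon

from gliaclone import (
    build_rings,
    classify_inner_outer,
    distance_records,
    radial_summary,
)
from gliaclone.clones import Clone, ColorCode
from gliaclone.lesion import LesionGeometry, distance_to_core, ring_labels

CIRCLE = Point(0, 0).buffer(20.0, quad_segs=128)
CODE = ColorCode.from_string("100000000001")


def make_clone(cid, members):
    return Clone(clone_id=cid, code=CODE, member_cell_ids=list(members))


def cells_at(points, sections=None):
    n = len(points)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
            "section": sections if sections is not None else [0] * n,
        }
    )


class TestBuildRings:
    def test_circular_core_ring_radii_and_area(self):
        geom = build_rings(CIRCLE)
        assert len(geom.rings) == 4
        for ring, r_expect in zip(geom.rings, (70, 120, 170, 220)):
            # every boundary vertex of the buffered ring sits at radius offset+20
            coords = np.asarray(ring.exterior.coords)
            radii = np.hypot(coords[:, 0], coords[:, 1])
            assert np.abs(radii - r_expect).max() < 0.5
        first_annulus = geom.rings[0].area - geom.core.area
        assert first_annulus == pytest.approx(np.pi * (70**2 - 20**2), rel=0.005)

    def test_convex_core_buffer_boundary_closed_form(self):
        # convex set: buffered perimeter = perimeter + 2*pi*offset
        square = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        geom = build_rings(square)
        for ring, off in zip(geom.rings, geom.ring_offsets):
            expect = 400.0 + 2 * np.pi * off
            assert ring.exterior.length == pytest.approx(expect, rel=1e-3)

    def test_rings_strictly_nested(self):
        geom = build_rings(Polygon([(0, 0), (60, 10), (90, 80), (10, 50)]))
        inner = geom.core
        for ring in geom.rings:
            assert ring.covers(inner) and ring.area > inner.area
            inner = ring

    def test_self_intersecting_core_fails(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(ValueError, match="invalid"):
            build_rings(bowtie)

    def test_bad_offsets_fail(self):
        with pytest.raises(ValueError):
            build_rings(CIRCLE, offsets=(50, 50, 150, 200))

    def test_scale_mode_matches_buffer_on_circles(self):
        geom = build_rings(CIRCLE, mode="scale")
        coords = np.asarray(geom.rings[0].exterior.coords)
        assert np.abs(np.hypot(coords[:, 0], coords[:, 1]) - 70).max() < 0.5


class TestDistance:
    LESIONS = [LesionGeometry(section=0, core=CIRCLE)]

    def test_outside_point_distance_and_ring(self):
        recs = distance_records(cells_at([(100.0, 0.0)]), self.LESIONS)
        assert recs.loc[0, "distance_um"] == pytest.approx(80.0, abs=0.01)
        assert recs.loc[0, "ring"] == "50-100"

    def test_inside_core_distance_zero(self):
        recs = distance_records(cells_at([(5.0, -3.0)]), self.LESIONS)
        assert recs.loc[0, "distance_um"] == 0.0
        assert recs.loc[0, "ring"] == "core"

    def test_min_over_multiple_lesions(self):
        two = self.LESIONS + [
            LesionGeometry(section=0, core=Point(500, 0).buffer(10.0, quad_segs=64))
        ]
        d = distance_to_core(470.0, 0.0, two, section=0)
        assert d == pytest.approx(20.0, abs=0.05)

    def test_no_lesion_anywhere_fails(self):
        with pytest.raises(ValueError):
            distance_records(cells_at([(0.0, 0.0)]), [])

    def test_cell_on_lesion_free_section_is_outside(self):
        recs = distance_records(cells_at([(0.0, 0.0)], sections=[3]), self.LESIONS)
        assert np.isnan(recs.loc[0, "distance_um"])
        assert recs.loc[0, "ring"] == "outside"

    def test_matches_dense_boundary_sampling_oracle(self):
        poly = Polygon([(0, 0), (120, -20), (160, 90), (60, 140), (-30, 70)])
        lesions = [LesionGeometry(section=0, core=poly)]
        # oracle: sample the boundary at ~0.05 um spacing
        ring = poly.exterior
        ts = np.linspace(0, ring.length, int(ring.length / 0.05))
        boundary = np.array([ring.interpolate(t).coords[0] for t in ts])
        rng = np.random.default_rng(0)
        pts = rng.uniform(-300, 400, size=(1000, 2))
        df = cells_at([tuple(p) for p in pts])
        recs = distance_records(df, lesions)
        from shapely import contains_xy

        inside = contains_xy(poly, pts[:, 0], pts[:, 1])
        oracle = np.sqrt(
            ((pts[:, None, :] - boundary[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        oracle[inside] = 0.0
        assert np.abs(recs["distance_um"].to_numpy() - oracle).max() < 0.5

    def test_enlarging_core_never_increases_distance(self):
        small = Polygon([(0, 0), (50, 0), (50, 50), (0, 50)])
        big = small.buffer(30.0, quad_segs=32)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-200, 300, size=(200, 2))
        for x, y in pts:
            d_small = distance_to_core(x, y, [LesionGeometry(0, small)], 0)
            d_big = distance_to_core(x, y, [LesionGeometry(0, big)], 0)
            assert d_big <= d_small + 1e-9

    def test_ring_labels_partition_cells(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-400, 400, size=(300, 2))
        recs = distance_records(cells_at([tuple(p) for p in pts]), self.LESIONS)
        counts = recs["ring"].value_counts()
        assert counts.sum() == 300
        assert set(counts.index) <= set(ring_labels())


class TestInnerOuter:
    def distances(self, mapping):
        return pd.DataFrame(
            {"cell_id": list(mapping), "distance_um": list(mapping.values()),
             "ring": ["outside"] * len(mapping)}
        )

    def test_any_member_within_threshold_is_inner(self):
        c = make_clone("k1", ["a", "b"])
        assert classify_inner_outer(c, self.distances({"a": 30.0, "b": 250.0})) == "inner"

    def test_all_members_beyond_threshold_is_outer(self):
        c = make_clone("k2", ["a", "b"])
        assert classify_inner_outer(c, self.distances({"a": 201.0, "b": 500.0})) == "outer"

    def test_exactly_200_is_inner(self):
        c = make_clone("k3", ["a"])
        assert classify_inner_outer(c, self.distances({"a": 200.0})) == "inner"

    def test_missing_member_record_fails(self):
        c = make_clone("k4", ["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            classify_inner_outer(c, self.distances({"a": 10.0}))


class TestRadialSummary:
    def build(self, inner_sizes, outer_sizes):
        clones, rows = [], []
        cid = 0
        for j, s in enumerate(inner_sizes):
            members = [f"i{j}_{k}" for k in range(s)]
            clones.append(make_clone(f"in{j}", members))
            rows += [{"cell_id": m, "distance_um": 100.0, "ring": "50-100"} for m in members]
        for j, s in enumerate(outer_sizes):
            members = [f"o{j}_{k}" for k in range(s)]
            clones.append(make_clone(f"out{j}", members))
            rows += [{"cell_id": m, "distance_um": 400.0, "ring": "outside"} for m in members]
        return clones, pd.DataFrame(rows)

    def test_identical_groups_t_zero_p_one(self):
        clones, dist = self.build([5, 7, 9], [5, 7, 9])
        _, stats = radial_summary(clones, dist)
        assert stats["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert stats["p_value"] == pytest.approx(1.0, abs=1e-12)

    def test_single_clone_group_flags_no_test(self):
        clones, dist = self.build([5, 6], [4])
        _, stats = radial_summary(clones, dist)
        assert not stats["test_performed"]
        assert np.isnan(stats["p_value"])

    def test_inner_proportion(self):
        clones, dist = self.build([3] * 29, [3] * 19)  # 48 clones, 60% inner
        _, stats = radial_summary(clones, dist)
        assert stats["n_inner_clones"] + stats["n_outer_clones"] == 48
        assert stats["inner_proportion"] == pytest.approx(29 / 48, abs=1e-12)

    def test_per_clone_counts_partition_members(self):
        clones, dist = self.build([4, 6], [3])
        per_clone, _ = radial_summary(clones, dist)
        totals = per_clone.groupby("clone_id")["n_cells"].sum()
        assert totals["in0"] == 4 and totals["in1"] == 6 and totals["out0"] == 3

    def test_power_for_large_inner_effect(self):
        # inner mean size 20 vs outer 8, sd 5, n = 30/30: p < 0.001 nearly always
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            inner = np.clip(np.round(rng.normal(20, 5, 30)), 2, None).astype(int)
            outer = np.clip(np.round(rng.normal(8, 5, 30)), 2, None).astype(int)
            clones, dist = self.build(list(inner), list(outer))
            _, stats = radial_summary(clones, dist)
            hits += stats["p_value"] < 0.001
        assert hits >= 95
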