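"""Cluster-polygon linkage: containment, buffer area ratios, agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import Point, box

from acprev.geolink import (
    AmbiguousAssignmentError,
    buffer_reassign,
    compare_linkages,
    direct_assign,
)
from acprev.io import PolygonLayer
from acprev.synthetic import GeographySpec, displace_clusters, make_geography


def two_halfplane_layer(width=40_000.0, height=40_000.0, split=20_000.0):
    """Two rectangles split by a vertical border at x = split."""
    return PolygonLayer(
        pd.DataFrame({"ac_id": ["A", "B"]}),
        [box(0, 0, split, height), box(split, 0, width, height)],
    )


def circle_halfplane_fraction(d, r):
    """Closed form: fraction of a circle of radius r on the far side of a
    straight border at distance d from the centre."""
    seg = r * r * math.acos(d / r) - d * math.sqrt(r * r - d * d)
    return seg / (math.pi * r * r)


class TestDirectAssign:
    def test_centroid_containment(self, unit_grid_layer):
        pts = pd.DataFrame({"cluster_id": [0], "x": [1.5], "y": [2.5]})
        tab = direct_assign(pts, unit_grid_layer)
        assert tab.loc[0, "ac_id"] == "g21"

    def test_missing_coords_dropped(self, unit_grid_layer):
        pts = pd.DataFrame({"cluster_id": [0, 1], "x": [0.5, np.nan], "y": [0.5, 1.0]})
        tab = direct_assign(pts, unit_grid_layer)
        assert tab.loc[1, "drop_reason"] == "missing-coords"
        assert tab.loc[0, "drop_reason"] == "none"

    def test_outside_boundary_dropped(self, unit_grid_layer):
        pts = pd.DataFrame({"cluster_id": [0], "x": [99.0], "y": [99.0]})
        tab = direct_assign(pts, unit_grid_layer)
        assert tab.loc[0, "drop_reason"] == "outside-boundary"

    def test_shared_edge_tie_break(self, unit_grid_layer):
        # point exactly on the edge between g00 and g01
        pts = pd.DataFrame({"cluster_id": [0], "x": [1.0], "y": [0.5]})
        # brute-force scan finds both candidates
        pt = Point(1.0, 0.5)
        cands = sorted(
            unit_grid_layer.df["ac_id"][i]
            for i, g in enumerate(unit_grid_layer.geoms)
            if g.covers(pt)
        )
        assert cands == ["g00", "g01"]
        tab = direct_assign(pts, unit_grid_layer)
        assert tab.loc[0, "ac_id"] == "g00"  # lexicographically smallest

    def test_overlapping_interiors_ambiguous(self):
        layer = PolygonLayer(
            pd.DataFrame({"ac_id": ["A", "B"]}), [box(0, 0, 2, 2), box(1, 0, 3, 2)]
        )
        pts = pd.DataFrame({"cluster_id": [0], "x": [1.5], "y": [1.0]})
        with pytest.raises(AmbiguousAssignmentError):
            direct_assign(pts, layer)

    def test_null_name_drop(self):
        layer = PolygonLayer(
            pd.DataFrame({"ac_id": ["A", None]}), [box(0, 0, 1, 1), box(1, 0, 2, 1)]
        )
        pts = pd.DataFrame({"cluster_id": [0], "x": [1.5], "y": [0.5]})
        tab = direct_assign(pts, layer)
        assert tab.loc[0, "drop_reason"] == "null-ac-name"


class TestBufferReassign:
    def test_interior_buffer_matches_direct(self, unit_grid_layer):
        layer = two_halfplane_layer()
        pts = pd.DataFrame({"cluster_id": [0], "x": [10_000.0], "y": [20_000.0], "urban": [0]})
        tab = buffer_reassign(pts, layer)
        assert tab.loc[0, "ac_id"] == "A"
        assert tab.loc[0, "area_ratios"]["A"] == pytest.approx(1.0, abs=1e-9)
        direct = direct_assign(pts, layer)
        assert direct.loc[0, "ac_id"] == "A"

    @pytest.mark.parametrize("d_over_r", [0.1, 0.5, 0.9])
    def test_circular_segment_oracle(self, d_over_r):
        r = 5000.0
        d = d_over_r * r
        layer = two_halfplane_layer()
        pts = pd.DataFrame(
            {"cluster_id": [0], "x": [20_000.0 - d], "y": [20_000.0], "urban": [0]}
        )
        tab = buffer_reassign(pts, layer, rural_radius=r)
        expected_b = circle_halfplane_fraction(d, r)
        assert tab.loc[0, "area_ratios"]["B"] == pytest.approx(expected_b, abs=1e-3)
        assert tab.loc[0, "area_ratios"]["A"] == pytest.approx(1 - expected_b, abs=1e-3)
        assert tab.loc[0, "ac_id"] == "A"

    def test_point_just_past_border_reassigned_back(self):
        """A displaced point 1 m on the wrong side is pulled back to the
        majority-area polygon (the neighbouring unit is a narrow strip, so the
        true unit keeps most of the buffer)."""
        layer = PolygonLayer(
            pd.DataFrame({"ac_id": ["A", "B"]}),
            [box(0, 0, 20_000, 40_000), box(20_000, 0, 21_500, 40_000)],
        )
        pts = pd.DataFrame(
            {"cluster_id": [0], "x": [20_001.0], "y": [20_000.0], "urban": [0]}
        )
        assert direct_assign(pts, layer).loc[0, "ac_id"] == "B"
        tab = buffer_reassign(pts, layer)
        assert tab.loc[0, "ac_id"] == "A"
        # oracle: A's share is the circular segment beyond d = 1 m,
        # B's is the band between the two borders
        frac_a = circle_halfplane_fraction(1.0, 5000.0)
        frac_b = (1 - frac_a) - circle_halfplane_fraction(1499.0, 5000.0)
        assert tab.loc[0, "area_ratios"]["A"] == pytest.approx(frac_a, abs=1e-3)
        assert tab.loc[0, "area_ratios"]["B"] == pytest.approx(frac_b, abs=1e-3)

    def test_buffer_outside_all_polygons(self):
        layer = two_halfplane_layer()
        pts = pd.DataFrame({"cluster_id": [0], "x": [1e6], "y": [1e6], "urban": [0]})
        tab = buffer_reassign(pts, layer)
        assert tab.loc[0, "drop_reason"] == "outside-boundary"

    def test_monte_carlo_ratio_oracle(self):
        """Area ratios agree with the fraction of 100k uniform points in the buffer."""
        r, d = 5000.0, 2000.0
        layer = two_halfplane_layer()
        cx, cy = 20_000.0 - d, 20_000.0
        pts = pd.DataFrame({"cluster_id": [0], "x": [cx], "y": [cy], "urban": [0]})
        ratios = buffer_reassign(pts, layer, rural_radius=r).loc[0, "area_ratios"]
        rng = np.random.default_rng(0)
        u = rng.random(200_000)
        theta = rng.uniform(0, 2 * np.pi, 200_000)
        rr = r * np.sqrt(u)
        xs, ys = cx + rr * np.cos(theta), cy + rr * np.sin(theta)
        mc_b = float((xs > 20_000.0).mean())
        assert ratios["B"] == pytest.approx(mc_b, abs=0.005)

    def test_translation_rotation_invariance(self):
        layer = two_halfplane_layer()
        pts = pd.DataFrame(
            {"cluster_id": [0], "x": [19_000.0], "y": [20_000.0], "urban": [0]}
        )
        base = buffer_reassign(pts, layer).loc[0, "area_ratios"]
        moved_geoms = [
            affinity.rotate(affinity.translate(g, 123.0, -456.0), 30.0, origin=(0, 0))
            for g in layer.geoms
        ]
        px, py = affinity.rotate(
            affinity.translate(Point(19_000.0, 20_000.0), 123.0, -456.0), 30.0, origin=(0, 0)
        ).coords[0]
        moved = PolygonLayer(layer.df.copy(), moved_geoms)
        pts2 = pd.DataFrame({"cluster_id": [0], "x": [px], "y": [py], "urban": [0]})
        rot = buffer_reassign(pts2, moved).loc[0, "area_ratios"]
        for k in base:
            assert rot[k] == pytest.approx(base[k], abs=1e-6)

    def test_single_polygon_agreement_invariant(self, small_geography):
        """Reassignment equals direct assignment whenever the buffer sits in one AC."""
        pts = small_geography.clusters[["cluster_id", "x", "y", "urban"]]
        d = direct_assign(pts, small_geography.acs)
        r = buffer_reassign(pts, small_geography.acs)
        merged = d.merge(r, on="cluster_id", suffixes=("_d", "_r"))
        for _, row in merged.iterrows():
            ratios = row["area_ratios_r"]
            if isinstance(ratios, dict) and len(ratios) == 1 and row["drop_reason_d"] == "none":
                assert row["ac_id_d"] == row["ac_id_r"]


class TestCompareLinkages:
    def test_identical_tables(self, small_geography):
        pts = small_geography.clusters[["cluster_id", "x", "y", "urban"]]
        d = direct_assign(pts, small_geography.acs)
        rep = compare_linkages(d, d.assign(method="reassigned"))
        assert rep["n_differing"] == 0
        assert rep["fraction_differing"] == 0.0

    def test_counting(self):
        d = pd.DataFrame(
            {
                "cluster_id": range(10),
                "ac_id": ["A"] * 10,
                "method": "direct",
                "drop_reason": "none",
            }
        )
        r = d.copy()
        r.loc[3, "ac_id"] = "B"
        r["method"] = "reassigned"
        rep = compare_linkages(d, r)
        assert rep["n_differing"] == 1
        assert rep["fraction_differing"] == pytest.approx(0.10)

    def test_interior_clusters_always_agree(self):
        """Clusters further than the displacement radius from any border agree."""
        geo = make_geography(GeographySpec(1, 1, 4, 8, cell_size=30_000.0), seed=5)
        cl = geo.clusters
        # keep clusters >= 5 km from their AC boundary
        keep = []
        for _, row in cl.iterrows():
            ac_idx = list(geo.acs.df["ac_id"]).index(row["ac_id_true"])
            poly = geo.acs.geoms[ac_idx]
            keep.append(poly.exterior.distance(Point(row["x"], row["y"])) >= 5_000.0)
        cl = cl[np.array(keep)]
        if len(cl) == 0:
            pytest.skip("no interior clusters at this seed")
        disp = displace_clusters(cl, seed=8)
        pts = disp[["cluster_id", "x", "y", "urban"]]
        rep = compare_linkages(
            direct_assign(pts, geo.acs), buffer_reassign(pts, geo.acs)
        )
        assert rep["fraction_differing"] == 0.0
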