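import numpy as np
import pandas as pd
import pytest
import shapely

from storknet import sites
from storknet.geo import EARTH_RADIUS_KM, LocalProjection

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def disc(lon, lat, radius_km, habitat, pid):
    dlat = radius_km / KM_PER_DEG
    dlon = radius_km / (KM_PER_DEG * np.cos(np.radians(lat)))
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    geom = shapely.Polygon(np.column_stack([lon + dlon * np.cos(ang), lat + dlat * np.sin(ang)]))
    return {"polygon_id": pid, "habitat": habitat, "geometry": geom}


def polys_at(points_km_apart, habitat="Landfills", radius_km=0.3, lat0=37.0):
    """Discs along a meridian with given *boundary* separations in km."""
    rows = []
    lat = lat0
    for k, gap in enumerate([0] + list(points_km_apart)):
        lat += (gap + 2 * radius_km) / KM_PER_DEG if k else 0
        rows.append(disc(-5.0, lat, radius_km, habitat, k))
    return pd.DataFrame(rows)


class TestReclassify:
    @pytest.mark.parametrize(
        "code,expected",
        [
            (132, "Landfills"),
            (131, "Landfills"),
            (213, "Rice fields"),
            (111, "Urban areas"),
            (142, "Golf course"),
            (244, "Agro-forestry areas"),
            (421, "Marshes"),
            (511, "Water courses"),
            (422, "Salines"),
            (512, "Lakes and ponds"),
        ],
    )
    def test_default_mapping(self, code, expected):
        assert sites.reclassify_habitat(code) == expected

    def test_ambiguous_codes_take_override(self):
        assert sites.reclassify_habitat(512, "Dams") == "Dams"
        assert sites.reclassify_habitat(512, "Irrigation ponds") == "Irrigation ponds"
        assert sites.reclassify_habitat(422, "Fish aquaculture") == "Fish aquaculture"

    def test_unknown_code_errors(self):
        with pytest.raises(ValueError, match="999"):
            sites.reclassify_habitat(999)

    def test_invalid_override_for_code(self):
        with pytest.raises(ValueError):
            sites.reclassify_habitat(512, "Salines")


def brute_single_linkage(polys, merge_km):
    """Independent all-pairs transitive-closure clustering oracle."""
    n = len(polys)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    geoms = list(polys["geometry"])
    habs = list(polys["habitat"])
    for i in range(n):
        for j in range(i + 1, n):
            if habs[i] == habs[j] and sites.min_boundary_distance_km(geoms[i], geoms[j]) <= merge_km:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestMergeNearby:
    def test_close_pair_merges_far_pair_does_not(self):
        assert len(sites.merge_nearby(polys_at([5.0]))) == 1
        assert len(sites.merge_nearby(polys_at([12.0]))) == 2

    def test_chain_merges_under_single_linkage(self):
        # A-B 6 km, B-C 6 km, A-C ~12.6 km: one node by transitivity
        polys = polys_at([6.0, 6.0])
        nodes = sites.merge_nearby(polys)
        assert len(nodes) == 1
        assert len(nodes) == brute_single_linkage(polys, 10.0)

    def test_permutation_invariance_and_monotone_coarsening(self):
        rng = np.random.default_rng(5)
        rows = [
            disc(-5.0 + rng.uniform(0, 0.5), 36.8 + rng.uniform(0, 0.5), 0.3, h, k)
            for k, h in enumerate(["Landfills"] * 4 + ["Marshes"] * 4)
        ]
        polys = pd.DataFrame(rows)
        nodes = sites.merge_nearby(polys, 10.0)
        shuffled = polys.sample(frac=1, random_state=1).reset_index(drop=True)
        nodes2 = sites.merge_nearby(shuffled, 10.0)
        pd.testing.assert_frame_equal(
            nodes[["node_id", "habitat", "lon", "lat"]], nodes2[["node_id", "habitat", "lon", "lat"]]
        )
        for km in (1.0, 5.0, 20.0, 60.0):
            assert len(sites.merge_nearby(polys, km)) >= len(sites.merge_nearby(polys, km * 2))
        assert len(nodes) == brute_single_linkage(polys, 10.0)

    def test_different_habitats_never_merge(self):
        rows = [disc(-5.0, 37.0, 0.3, "Landfills", 0), disc(-5.0, 37.01, 0.3, "Marshes", 1)]
        assert len(sites.merge_nearby(pd.DataFrame(rows))) == 2


class TestBufferShoreline:
    def test_zero_buffer_identity(self):
        g = disc(-5.0, 37.0, 0.5, "Marshes", 0)["geometry"]
        assert sites.buffer_shoreline(g, 0.0, "Marshes") is g

    def test_square_lake_area_matches_planar_oracle(self):
        # 1 km x 1 km square, 200 m buffer -> rounded-corner square
        proj = LocalProjection(-5.0, 37.0, kind="equidistant")
        square_m = shapely.box(-500, -500, 500, 500)
        oracle_area_m2 = square_m.buffer(200.0, quad_segs=64).area
        lake = proj.inverse_geometry(square_m)
        buffered = sites.buffer_shoreline(lake, 200.0, "Lakes and ponds")
        area_m2 = proj.transform_geometry(buffered).area
        assert area_m2 == pytest.approx(oracle_area_m2, rel=2e-3)
        assert area_m2 == pytest.approx((1000 + 2 * 200) ** 2 - (4 - np.pi) * 200**2, rel=2e-3)

    def test_multipolygon_parts_all_dilated(self):
        a = disc(-5.0, 37.0, 0.3, "Marshes", 0)["geometry"]
        b = disc(-5.0, 37.5, 0.3, "Marshes", 0)["geometry"]
        mp = shapely.MultiPolygon([a, b])
        out = sites.buffer_shoreline(mp, 200.0, "Marshes")
        assert out.geom_type == "MultiPolygon" and len(out.geoms) == 2
        for part, orig in zip(out.geoms, [a, b]):
            assert part.area > orig.area

    def test_non_wetland_rejected(self):
        g = disc(-5.0, 37.0, 0.3, "Landfills", 0)["geometry"]
        with pytest.raises(ValueError, match="wetland"):
            sites.buffer_shoreline(g, 200.0, "Landfills")


class TestAssignFixes:
    def setup_method(self):
        self.nodes = sites.merge_nearby(polys_at([15.0, 15.0]))

    def test_centroid_inside_and_offshore_outside(self):
        fixes = pd.DataFrame(
            {"lon": [self.nodes["lon"].iloc[0], -9.0], "lat": [self.nodes["lat"].iloc[0], 37.0]}
        )
        got = sites.assign_fixes(fixes, self.nodes)
        assert got.iloc[0] == self.nodes["node_id"].iloc[0]
        assert pd.isna(got.iloc[1])

    def test_boundary_point_counts_as_inside(self):
        boundary = shapely.get_coordinates(self.nodes["geometry"].iloc[0])[0]
        fixes = pd.DataFrame({"lon": [boundary[0]], "lat": [boundary[1]]})
        got = sites.assign_fixes(fixes, self.nodes)
        assert got.iloc[0] == self.nodes["node_id"].iloc[0]

    def test_overlap_tie_breaks_to_smallest_node_id(self):
        rows = [disc(-5.0, 37.0, 0.5, "Landfills", 0), disc(-5.0, 37.002, 0.5, "Marshes", 1)]
        nodes = sites.merge_nearby(pd.DataFrame(rows))
        fixes = pd.DataFrame({"lon": [-5.0], "lat": [37.001]})
        with pytest.warns(UserWarning, match="overlapping"):
            got = sites.assign_fixes(fixes, nodes)
        assert got.iloc[0] == nodes["node_id"].min()


class TestOccupancyFilter:
    def make_nodes(self, lats):
        return pd.DataFrame(
            {
                "node_id": range(len(lats)),
                "habitat": "Landfills",
                "geometry": [disc(-5, la, 0.3, "Landfills", i)["geometry"] for i, la in enumerate(lats)],
                "lon": -5.0,
                "lat": lats,
            }
        )

    def test_median_threshold_southern_candidates(self):
        nodes = self.make_nodes([36.0] * 7 + [40.0])
        counts = pd.Series([1, 2, 6, 6, 7, 9, 11, 5], index=range(8))
        out, threshold = sites.occupancy_filter(nodes, counts, sites.SiteConfig())
        assert threshold == 6
        assert 7 not in set(out["node_id"])  # northern node with count 5 dropped too
        assert set(out["node_id"]) == {2, 3, 4, 5, 6}

    def test_override_matches_fixed_cutoff(self):
        nodes = self.make_nodes([36.0] * 4)
        counts = pd.Series([5, 6, 7, 2], index=range(4))
        out, threshold = sites.occupancy_filter(
            nodes, counts, sites.SiteConfig(min_birdyears_override=6)
        )
        assert threshold == 6 and set(out["node_id"]) == {1, 2}

    def test_even_count_takes_lower_middle_and_idempotent(self):
        nodes = self.make_nodes([36.0] * 4)
        counts = pd.Series([2, 4, 6, 8], index=range(4))
        out, threshold = sites.occupancy_filter(nodes, counts, sites.SiteConfig())
        assert threshold == 4
        out2, _ = sites.occupancy_filter(out, counts, sites.SiteConfig(min_birdyears_override=threshold))
        assert set(out2["node_id"]) == set(out["node_id"])

    def test_no_southern_candidates_errors(self):
        nodes = self.make_nodes([40.0, 41.0])
        with pytest.raises(ValueError, match="override"):
            sites.occupancy_filter(nodes, pd.Series([3, 3], index=[0, 1]), sites.SiteConfig())

    def test_all_above_threshold_nothing_dropped(self):
        nodes = self.make_nodes([36.0, 36.5, 37.0])
        counts = pd.Series([7, 7, 7], index=range(3))
        out, _ = sites.occupancy_filter(nodes, counts, sites.SiteConfig())
        assert len(out) == 3
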