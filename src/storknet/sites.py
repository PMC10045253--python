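"""Network nodes from habitat polygons.

Sites are merged clusters of same-habitat land-cover polygons: CLC codes are
reclassified into a 14-class habitat vocabulary, polygons of one habitat
within a merge radius are single-linkage clustered into one node, wetland
shorelines are dilated by a metric buffer, GPS fixes are assigned to nodes by
point-in-polygon, and nodes used by too few bird-years are discarded via a
median occupancy cutoff computed over the southern (wintering) part of the
study area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .geo import LocalProjection, geometry_centroid_lonlat, haversine_km, read_geojson, write_geojson

HABITATS = (
    "Landfills",
    "Urban areas",
    "Golf course",
    "Agro-forestry areas",
    "Non-irrigated arable land",
    "Permanently irrigated land",
    "Rice fields",
    "Fish aquaculture",
    "Irrigation ponds",
    "Dams",
    "Salines",
    "Marshes",
    "Lakes and ponds",
    "Water courses",
)

#: the eight wetland classes (five artificial + three natural)
WETLANDS = frozenset(
    {
        "Rice fields",
        "Fish aquaculture",
        "Irrigation ponds",
        "Dams",
        "Salines",
        "Marshes",
        "Lakes and ponds",
        "Water courses",
    }
)

# CLC 2018 code -> default habitat label. Codes 131, 422 and 512 map to
# several labels in the field protocol; the first listed label is the default
# and the alternatives require an explicit override.
CLC_DEFAULT = {
    111: "Urban areas",
    112: "Urban areas",
    121: "Urban areas",
    131: "Landfills",
    132: "Landfills",
    142: "Golf course",
    211: "Non-irrigated arable land",
    212: "Permanently irrigated land",
    213: "Rice fields",
    244: "Agro-forestry areas",
    411: "Marshes",
    421: "Marshes",
    422: "Salines",
    511: "Water courses",
    512: "Lakes and ponds",
}

CLC_ALTERNATIVES = {
    422: ("Salines", "Fish aquaculture"),
    512: ("Lakes and ponds", "Dams", "Irrigation ponds"),
    131: ("Landfills",),
}


@dataclass(frozen=True)
class SiteConfig:
    merge_km: float = 10.0
    shoreline_buffer_m: float = 200.0
    cutoff_lat_deg: float = 38.0
    min_birdyears_override: int | None = None

    def __post_init__(self):
        if self.merge_km <= 0 or self.shoreline_buffer_m < 0:
            raise ValueError("merge_km must be > 0 and shoreline_buffer_m >= 0")


def reclassify_habitat(clc_code: int, override: str | None = None) -> str:
    """Map a CLC code to its habitat label; overrides resolve ambiguous codes."""
    if override is not None:
        if override not in HABITATS:
            raise ValueError(f"unknown habitat override {override!r}")
        allowed = CLC_ALTERNATIVES.get(clc_code)
        if allowed is not None and override not in allowed:
            raise ValueError(f"override {override!r} not valid for CLC code {clc_code} (allowed: {allowed})")
        return override
    if clc_code not in CLC_DEFAULT:
        raise ValueError(f"unknown CLC code {clc_code}; provide an explicit habitat override")
    return CLC_DEFAULT[clc_code]


def load_polygons(path) -> pd.DataFrame:
    """Read habitat polygons from GeoJSON (properties: polygon_id, clc_code
    and/or habitat) into columns polygon_id, habitat, geometry."""
    recs = read_geojson(path)
    rows = []
    for i, rec in enumerate(recs):
        habitat = rec.get("habitat")
        clc = rec.get("clc_code")
        if habitat is None and clc is None:
            raise ValueError(f"feature {i}: needs 'habitat' or 'clc_code'")
        if clc is not None:
            habitat = reclassify_habitat(int(clc), habitat)
        elif habitat not in HABITATS:
            raise ValueError(f"feature {i}: unknown habitat {habitat!r}")
        geom = shapely.make_valid(rec["geometry"])
        rows.append({"polygon_id": rec.get("polygon_id", i), "habitat": habitat, "geometry": geom})
    return pd.DataFrame(rows)


def buffer_shoreline(geometry, buffer_m: float, habitat: str | None = None):
    """Dilate a wetland polygon outward by ``buffer_m`` metres.

    The buffer is applied in a local azimuthal equidistant projection about
    the geometry centroid; multipolygon parts are all dilated.
    """
    if habitat is not None and habitat not in WETLANDS:
        raise ValueError(f"shoreline buffer applies to wetland habitats only, got {habitat!r}")
    if buffer_m == 0:
        return geometry
    lon, lat = geometry_centroid_lonlat(geometry)
    proj = LocalProjection(lon, lat, kind="equidistant")
    return proj.inverse_geometry(proj.transform_geometry(geometry).buffer(buffer_m))


def buffer_wetlands(polys: pd.DataFrame, buffer_m: float) -> pd.DataFrame:
    polys = polys.copy()
    wet = polys["habitat"].isin(WETLANDS)
    polys.loc[wet, "geometry"] = [buffer_shoreline(g, buffer_m) for g in polys.loc[wet, "geometry"]]
    return polys


def _boundary_vertices(geom, spacing_m: float = 100.0) -> np.ndarray:
    """Vertices densified to at most ``spacing_m`` metres apart along the
    boundary, as (N, 2) lon/lat; used to approximate boundary distance."""
    spacing_deg = spacing_m / 111_320.0  # 1 degree of latitude in metres
    return shapely.get_coordinates(shapely.segmentize(geom, spacing_deg))


def min_boundary_distance_km(geom_a, geom_b) -> float:
    """Minimum boundary-to-boundary great-circle distance between polygons."""
    a = _boundary_vertices(geom_a)
    b = _boundary_vertices(geom_b)
    d = haversine_km(a[:, 0][:, None], a[:, 1][:, None], b[None, :, 0], b[None, :, 1])
    return float(d.min())


def merge_nearby(polys: pd.DataFrame, merge_km: float = 10.0) -> pd.DataFrame:
    """Single-linkage cluster same-habitat polygons within ``merge_km``.

    Returns the node table: node_id (deterministic: sorted by centroid
    latitude then longitude), habitat, geometry (union), lon, lat (centroid).
    """
    out_rows = []
    for habitat, grp in polys.groupby("habitat", sort=True):
        geoms = list(grp["geometry"])
        n = len(geoms)
        # coarse prefilter on bounding-box separation before exact distances
        ii, jj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if shapely.distance(geoms[i], geoms[j]) > 2.0 * merge_km / 111.32 + 0.2:
                    continue
                if min_boundary_distance_km(geoms[i], geoms[j]) <= merge_km:
                    ii.append(i)
                    jj.append(j)
        adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            members = [geoms[k] for k in range(n) if labels[k] == c]
            geom = unary_union(members)
            lon, lat = geometry_centroid_lonlat(geom)
            out_rows.append({"habitat": habitat, "geometry": geom, "lon": lon, "lat": lat})
    nodes = pd.DataFrame(out_rows)
    if len(nodes) == 0:
        return pd.DataFrame(columns=["node_id", "habitat", "geometry", "lon", "lat"])
    nodes = nodes.sort_values(["lat", "lon"], kind="mergesort").reset_index(drop=True)
    nodes.insert(0, "node_id", np.arange(len(nodes), dtype=int))
    return nodes


def assign_fixes(fixes: pd.DataFrame, nodes: pd.DataFrame) -> pd.Series:
    """Node id for each fix (pandas nullable Int64; <NA> outside all nodes).

    Boundary points count as inside; a fix covered by several nodes goes to
    the smallest node_id (with a warning when habitats differ).
    """
    pts = shapely.points(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    tree = STRtree(list(nodes["geometry"]))
    pi, ni = tree.query(pts, predicate="intersects")
    node_ids = nodes["node_id"].to_numpy()
    assigned = np.full(len(fixes), -1, dtype=np.int64)
    if len(pi):
        order = np.lexsort((node_ids[ni], pi))
        pi, ni = pi[order], ni[order]
        first = np.ones(len(pi), dtype=bool)
        first[1:] = pi[1:] != pi[:-1]
        assigned[pi[first]] = node_ids[ni[first]]
        dup_pts = len(pi) - int(first.sum())
        if dup_pts:
            habs = nodes["habitat"].to_numpy()
            multi = np.flatnonzero(~first)
            if any(habs[ni[k]] != habs[ni[k - 1]] for k in multi):
                warnings.warn("fixes covered by overlapping nodes of different habitat; assigned smallest node_id")
    out = pd.Series(assigned, index=fixes.index, dtype="Int64", name="node_id")
    return out.mask(out == -1)


def occupancy_table(fixes: pd.DataFrame) -> pd.Series:
    """Bird-years per node: a bird-year uses a node if >= 1 fix is assigned."""
    used = fixes.dropna(subset=["node_id"])
    return used.groupby(used["node_id"].astype(int))["birdyear"].nunique()


def occupancy_filter(
    nodes: pd.DataFrame, birdyear_counts: pd.Series, config: SiteConfig = SiteConfig()
) -> tuple[pd.DataFrame, int]:
    """Retain nodes used by at least the occupancy threshold of bird-years.

    The threshold is ``min_birdyears_override`` if set, otherwise the median
    bird-year count over candidate nodes with centroid latitude at or below
    ``cutoff_lat_deg`` (for an even count the lower middle value is taken).
    The threshold applies network-wide.
    """
    counts = nodes["node_id"].map(birdyear_counts).fillna(0).astype(int)
    if config.min_birdyears_override is not None:
        threshold = int(config.min_birdyears_override)
    else:
        south = counts[nodes["lat"] <= config.cutoff_lat_deg]
        if len(south) == 0:
            raise ValueError(
                f"no candidate nodes at or below latitude {config.cutoff_lat_deg}; "
                "set min_birdyears_override explicitly"
            )
        vals = np.sort(south.to_numpy())
        threshold = int(vals[(len(vals) - 1) // 2])  # lower middle for even length
    out = nodes.loc[counts >= threshold].copy()
    out["birdyear_count"] = counts[counts >= threshold].to_numpy()
    return out.reset_index(drop=True), threshold


def write_nodes(nodes: pd.DataFrame, geojson_path=None, csv_path=None) -> None:
    if geojson_path is not None:
        recs = [
            {
                "geometry": row.geometry,
                "node_id": int(row.node_id),
                "habitat": row.habitat,
                "centroid_lon": float(row.lon),
                "centroid_lat": float(row.lat),
                **({"birdyear_count": int(row.birdyear_count)} if "birdyear_count" in nodes.columns else {}),
            }
            for row in nodes.itertuples()
        ]
        write_geojson(geojson_path, recs)
    if csv_path is not None:
        cols = ["node_id", "habitat", "lon", "lat"] + (["birdyear_count"] if "birdyear_count" in nodes.columns else [])
        out = nodes[cols].rename(columns={"lon": "centroid_lon", "lat": "centroid_lat"})
        out.to_csv(csv_path, index=False, float_format="%.10g")


def read_nodes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(columns={"centroid_lon": "lon", "centroid_lat": "lat"})
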