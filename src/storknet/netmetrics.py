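"""Spatial-network assembly and metrics.

The network is a directed graph whose vertices are habitat sites and whose
integer edge weights count pooled direct flights. Shortest paths for
betweenness are cost-weighted by the great-circle distance between node
centroids in metres; flight counts do not modulate path cost. Betweenness is
reported unnormalised (raw fractional pair counts), and equal-cost paths are
detected with a relative tolerance of 1e-9 on accumulated distance.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .geo import haversine_km, write_geojson


@dataclass
class SpatialNetwork:
    nodes: pd.DataFrame  # node_id, habitat, lon, lat [, birdyear_count]
    edges: pd.DataFrame  # origin_node_id, dest_node_id, weight
    distance_m: np.ndarray = field(repr=False)  # symmetric centroid distances
    graph: nx.DiGraph = field(repr=False)

    @property
    def node_ids(self) -> np.ndarray:
        return self.nodes["node_id"].to_numpy()

    def node_index(self) -> dict:
        return {int(v): i for i, v in enumerate(self.node_ids)}

    def weight_matrix(self) -> np.ndarray:
        idx = self.node_index()
        n = len(self.nodes)
        w = np.zeros((n, n))
        for row in self.edges.itertuples():
            w[idx[int(row.origin_node_id)], idx[int(row.dest_node_id)]] = row.weight
        return w


def build_network(edges: pd.DataFrame, nodes: pd.DataFrame) -> SpatialNetwork:
    """Assemble the directed spatial network; validates edge endpoints."""
    nodes = nodes.sort_values("node_id", kind="mergesort").reset_index(drop=True)
    known = set(int(v) for v in nodes["node_id"])
    dangling = edges.loc[
        ~edges["origin_node_id"].astype(int).isin(known) | ~edges["dest_node_id"].astype(int).isin(known)
    ]
    if len(dangling):
        raise ValueError(f"edges reference unknown nodes:\n{dangling.to_string(index=False)}")
    if (edges["origin_node_id"] == edges["dest_node_id"]).any():
        raise ValueError("self-loop edges are not allowed")
    if (edges["weight"] < 1).any():
        raise ValueError("edge weights must be >= 1")
    lon = nodes["lon"].to_numpy()
    lat = nodes["lat"].to_numpy()
    dist_m = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :]) * 1000.0
    np.fill_diagonal(dist_m, 0.0)
    g = nx.DiGraph()
    for row in nodes.itertuples():
        g.add_node(int(row.node_id), habitat=row.habitat, lon=float(row.lon), lat=float(row.lat))
    idx = {int(v): i for i, v in enumerate(nodes["node_id"])}
    for row in edges.itertuples():
        o, d = int(row.origin_node_id), int(row.dest_node_id)
        g.add_edge(o, d, weight=int(row.weight), distance_m=float(dist_m[idx[o], idx[d]]))
    return SpatialNetwork(nodes=nodes, edges=edges.reset_index(drop=True), distance_m=dist_m, graph=g)


def strength(net: SpatialNetwork, direction: str) -> pd.Series:
    """Sum of link weights entering ('in') or leaving ('out') each node."""
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    col = "dest_node_id" if direction == "in" else "origin_node_id"
    s = net.edges.groupby(col)["weight"].sum()
    out = pd.Series(0, index=pd.Index(net.node_ids, name="node_id"), dtype=int)
    out.loc[s.index.astype(int)] = s.to_numpy()
    return out.rename(f"strength_{direction}")


def betweenness(net: SpatialNetwork, rel_tol: float = 1e-9) -> pd.Series:
    """Unnormalised distance-weighted betweenness (Brandes accumulation).

    For every ordered source/target pair, each intermediate node v accrues
    sigma_st(v)/sigma_st, where sigma counts minimum-geographic-distance
    paths over existing directed edges. Paths whose accumulated costs agree
    within ``rel_tol`` (relative) count as equally short.
    """
    idx = net.node_index()
    n = len(idx)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for row in net.edges.itertuples():
        o, d = idx[int(row.origin_node_id)], idx[int(row.dest_node_id)]
        adj[o].append((d, net.distance_m[o, d]))
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        settled_order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            settled_order.append(u)
            for v, w in adj[u]:
                nd = dist[u] + w
                tol = rel_tol * max(nd, dist[v] if np.isfinite(dist[v]) else nd)
                if nd < dist[v] - tol:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - dist[v]) <= tol:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for w in reversed(settled_order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return pd.Series(bc, index=pd.Index(net.node_ids, name="node_id"), name="betweenness")


def node_metrics(net: SpatialNetwork) -> pd.DataFrame:
    """Per-node metric table: habitat, centroid, betweenness, in/out strength."""
    df = net.nodes[["node_id", "habitat", "lon", "lat"]].copy()
    df = df.set_index("node_id")
    df["betweenness"] = betweenness(net)
    df["strength_in"] = strength(net, "in")
    df["strength_out"] = strength(net, "out")
    return df.reset_index()


def aggregate_by_habitat(net: SpatialNetwork) -> pd.DataFrame:
    """Undirected habitat-level network: total flights between habitat pairs.

    Same-habitat totals appear as self-links (habitat_a == habitat_b). The
    grand total over links equals the spatial network's total weight.
    """
    hab = net.nodes.set_index("node_id")["habitat"]
    a = net.edges["origin_node_id"].map(hab)
    b = net.edges["dest_node_id"].map(hab)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    df = pd.DataFrame({"habitat_a": lo, "habitat_b": hi, "weight": net.edges["weight"]})
    out = df.groupby(["habitat_a", "habitat_b"], sort=True)["weight"].sum().reset_index()
    return out.astype({"weight": int})


def rank_report(metrics: pd.DataFrame, habitat_net: pd.DataFrame, k: int = 10) -> dict[str, pd.DataFrame]:
    """Top-k tables by betweenness and in/out strength, and habitat links by
    weight; ties broken by node_id (deterministic)."""
    tables = {}
    for col in ("betweenness", "strength_in", "strength_out"):
        t = metrics.sort_values([col, "node_id"], ascending=[False, True], kind="mergesort")
        tables[f"top_{col}"] = t.head(k).reset_index(drop=True)
    h = habitat_net.sort_values(
        ["weight", "habitat_a", "habitat_b"], ascending=[False, True, True], kind="mergesort"
    )
    tables["habitat_links"] = h.head(k).reset_index(drop=True)
    return tables


def network_to_geojson(net: SpatialNetwork, path) -> None:
    """Export node centroids and links (as straight lines) for mapping."""
    import shapely

    recs = [
        {
            "geometry": shapely.Point(float(row.lon), float(row.lat)),
            "kind": "node",
            "node_id": int(row.node_id),
            "habitat": row.habitat,
        }
        for row in net.nodes.itertuples()
    ]
    coords = net.nodes.set_index("node_id")[["lon", "lat"]]
    for row in net.edges.itertuples():
        o, d = int(row.origin_node_id), int(row.dest_node_id)
        recs.append(
            {
                "geometry": shapely.LineString([coords.loc[o].to_list(), coords.loc[d].to_list()]),
                "kind": "link",
                "origin_node_id": o,
                "dest_node_id": d,
                "weight": int(row.weight),
            }
        )
    write_geojson(path, recs)
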