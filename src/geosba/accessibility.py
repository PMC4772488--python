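"""Nearest-facility network distances for survey sampling clusters.

Reproduces the construction behind the distance-to-facility covariate: each
sampling cluster is snapped to the nearest road-network junction and the
shortest-path (Dijkstra) distance to the closest maternity facility is
computed, with the Euclidean snap offset added. Clusters in network
components that contain no facility fall back to the straight-line distance
to the nearest facility node and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class RoadNetwork:
    """Weighted undirected road graph with facility nodes and cluster points.

    Coordinates are planar (km). Edge weights are road lengths in km and
    must be positive.
    """

    nodes: Mapping[str, tuple[float, float]]
    edges: Sequence[tuple[str, str, float]]
    facilities: set[str]
    clusters: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for u, v, w in self.edges:
            if w <= 0:
                raise ValueError(f"edge ({u}, {v}) has nonpositive length {w}")
            if u not in self.nodes or v not in self.nodes:
                raise KeyError(f"edge ({u}, {v}) references unknown node")
        unknown = set(self.facilities) - set(self.nodes)
        if unknown:
            raise KeyError(f"facility node(s) not in network: {unknown}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges:
            # parallel edges collapse to the shorter road
            if g.has_edge(u, v):
                g[u][v]["weight"] = min(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        return g


def nearest_facility_distance(net: RoadNetwork) -> pd.DataFrame:
    """Per-cluster distance (km) and identity of the closest facility.

    Returns a frame with columns ``cluster``, ``distance_km``, ``facility``,
    ``snapped_node``, ``snap_km`` and ``fallback`` (True when the snapped
    node cannot reach any facility on the network and the straight-line
    distance to the nearest facility is used instead).
    """
    if not net.facilities:
        raise ValueError("facility set is empty")
    g = net.to_networkx()
    node_ids = list(net.nodes)
    coords = np.array([net.nodes[n] for n in node_ids])
    tree = cKDTree(coords)

    dist_map, path_map = nx.multi_source_dijkstra(g, set(net.facilities), weight="weight")
    fac_ids = sorted(net.facilities)
    fac_coords = np.array([net.nodes[f] for f in fac_ids])

    rows = []
    for cid, (cx, cy) in net.clusters.items():
        snap_km, snap_i = tree.query([cx, cy])
        node = node_ids[int(snap_i)]
        if node in dist_map:
            rows.append(
                {
                    "cluster": cid,
                    "distance_km": float(snap_km) + float(dist_map[node]),
                    "facility": path_map[node][0],
                    "snapped_node": node,
                    "snap_km": float(snap_km),
                    "fallback": False,
                }
            )
        else:
            straight = np.hypot(fac_coords[:, 0] - cx, fac_coords[:, 1] - cy)
            j = int(np.argmin(straight))
            rows.append(
                {
                    "cluster": cid,
                    "distance_km": float(straight[j]),
                    "facility": fac_ids[j],
                    "snapped_node": node,
                    "snap_km": float(snap_km),
                    "fallback": True,
                }
            )
    return pd.DataFrame(rows)


def read_road_network(nodes_csv, edges_csv, facilities_csv, clusters_csv) -> RoadNetwork:
    """Assemble a :class:`RoadNetwork` from CSV node/edge/facility/cluster tables."""
    nodes_df = pd.read_csv(nodes_csv)
    edges_df = pd.read_csv(edges_csv)
    fac_df = pd.read_csv(facilities_csv)
    clus_df = pd.read_csv(clusters_csv)
    nodes = {str(r.node): (float(r.x), float(r.y)) for r in nodes_df.itertuples()}
    edges = [
        (str(r.source), str(r.target), float(r.length_km))
        for r in edges_df.itertuples()
    ]
    facilities = {str(v) for v in fac_df["node"]}
    clusters = {str(r.cluster): (float(r.x), float(r.y)) for r in clus_df.itertuples()}
    return RoadNetwork(nodes, edges, facilities, clusters)
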