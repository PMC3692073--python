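"""The coevolution network: nodes are residues, edges are significant MI z-scores.

An edge is retained when its MI z-score exceeds the significance threshold
(default 6.5, strict inequality). Per node, the cumulative MI (cMI) is the
sum of retained z-scores over all partners, and the proximity MI (pMI) is
the average cMI of spatial neighbors within a radius (default 5 Angstrom) in
the mapped structure. Edges are classified into percentile bands (top 5%,
70-95%, rest) for display.
"""

from __future__ import annotations

import math
from typing import Sequence

import networkx as nx
import numpy as np

from coevomap.mi_engine import ScoreMatrices
from coevomap.structure_map import SeqStructMap

Z_THRESHOLD_DEFAULT = 6.5

BAND_TOP = "top5"
BAND_MID = "mid70_95"
BAND_LOW = "low"


def build_network(
    scores: ScoreMatrices,
    threshold: float = Z_THRESHOLD_DEFAULT,
    conservation: Sequence[float] | None = None,
    reference_aa: Sequence[str] | None = None,
) -> nx.Graph:
    """Build the MI network from a z-score matrix.

    Nodes are all kept positions (keyed by 1-based reference position) so
    isolated residues still carry their conservation; edges are exactly the
    pairs with z strictly greater than ``threshold``. ``conservation`` and
    ``reference_aa`` are per kept column, in the order of ``scores.positions``.
    """
    positions = [int(p) for p in scores.positions]
    k = len(positions)
    graph = nx.Graph(z_threshold=float(threshold))
    for idx, pos in enumerate(positions):
        graph.add_node(
            pos,
            kept_index=idx,
            aa=(reference_aa[idx] if reference_aa is not None else "X"),
            kl=(float(conservation[idx]) if conservation is not None else math.nan),
            cmi=0.0,
            pmi=math.nan,
            secondary=None,
            pdb_number=None,
        )
    z = scores.z
    for i in range(k):
        for j in range(i + 1, k):
            zij = z[i, j]
            if np.isfinite(zij) and zij > threshold:
                graph.add_edge(
                    positions[i],
                    positions[j],
                    z=float(zij),
                    separation=abs(positions[i] - positions[j]),
                    distance=math.nan,
                    band=None,
                )
    cumulative_mi(graph)
    if graph.number_of_edges():
        percentile_bands(graph)
    return graph


def cumulative_mi(network: nx.Graph) -> dict[int, float]:
    """cMI per node: sum of z over incident retained edges (0 if isolated)."""
    cmi = {}
    for node in network.nodes:
        total = sum(data["z"] for _, _, data in network.edges(node, data=True))
        network.nodes[node]["cmi"] = total
        cmi[node] = total
    return cmi


def proximity_mi(
    network: nx.Graph,
    seqstruct_map: SeqStructMap,
    distances: np.ndarray,
    radius: float = 5.0,
    include_self: bool = False,
) -> dict[int, float]:
    """pMI per node: mean cMI of mapped residues within ``radius`` (inclusive).

    The residue itself is excluded unless ``include_self``. Unmapped positions
    and positions without any neighbor inside the radius get NaN. Also
    annotates nodes with their PDB author number and edges with the spatial
    distance between their endpoints where both map.
    """
    col_to_res = seqstruct_map.column_to_residue
    mapped_nodes = {
        node: col_to_res[data["kept_index"]]
        for node, data in network.nodes(data=True)
        if data["kept_index"] in col_to_res
    }
    for node, res_idx in mapped_nodes.items():
        pdb_num = seqstruct_map.author_numbers.get(network.nodes[node]["kept_index"])
        network.nodes[node]["pdb_number"] = pdb_num
    for u, v, data in network.edges(data=True):
        if u in mapped_nodes and v in mapped_nodes:
            data["distance"] = float(distances[mapped_nodes[u], mapped_nodes[v]])
    pmi: dict[int, float] = {}
    for node in network.nodes:
        if node not in mapped_nodes:
            network.nodes[node]["pmi"] = math.nan
            pmi[node] = math.nan
            continue
        ri = mapped_nodes[node]
        vals = []
        for other, rj in mapped_nodes.items():
            if other == node and not include_self:
                continue
            d = distances[ri, rj]
            if np.isfinite(d) and d <= radius:
                vals.append(network.nodes[other]["cmi"])
        value = float(np.mean(vals)) if vals else math.nan
        network.nodes[node]["pmi"] = value
        pmi[node] = value
    return pmi


def percentile_bands(network: nx.Graph) -> dict[tuple[int, int], str]:
    """Classify retained edges by z percentile: >=95th top5, >=70th mid, else low.

    Percentiles are linear-interpolation quantiles over the retained-edge z
    values; ties are assigned the higher band, so an all-equal network is
    entirely top5.
    """
    edges = list(network.edges(data=True))
    if not edges:
        raise ValueError("network has no edges to band")
    zvals = np.array([data["z"] for _, _, data in edges])
    p95 = np.percentile(zvals, 95)
    p70 = np.percentile(zvals, 70)
    bands = {}
    for u, v, data in edges:
        if data["z"] >= p95:
            band = BAND_TOP
        elif data["z"] >= p70:
            band = BAND_MID
        else:
            band = BAND_LOW
        data["band"] = band
        bands[(u, v)] = band
    return bands


def _in_range(value: float, bounds: tuple[float | None, float | None]) -> bool:
    lo, hi = bounds
    if not np.isfinite(value):
        return False
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def filter_network(
    network: nx.Graph,
    *,
    kl: tuple[float | None, float | None] | None = None,
    cmi: tuple[float | None, float | None] | None = None,
    pmi: tuple[float | None, float | None] | None = None,
    z: tuple[float | None, float | None] | None = None,
    distance: tuple[float | None, float | None] | None = None,
    separation: tuple[float | None, float | None] | None = None,
    top_n: int | None = None,
) -> nx.Graph:
    """Sub-network selection by node and edge criteria.

    Node criteria (``kl``, ``cmi``, ``pmi``) keep nodes whose attribute lies
    in the closed range (None = unbounded); edge criteria (``z``,
    ``distance``, ``separation``) drop edges outside the range. ``top_n``
    finally keeps only the N highest-z edges and their endpoints.
    Contradictory ranges simply yield an empty sub-network.
    """
    sub = network.copy()
    for attr, bounds in (("kl", kl), ("cmi", cmi), ("pmi", pmi)):
        if bounds is not None:
            drop = [n for n, d in sub.nodes(data=True) if not _in_range(d[attr], bounds)]
            sub.remove_nodes_from(drop)
    for attr, bounds in (("z", z), ("distance", distance), ("separation", separation)):
        if bounds is not None:
            drop = [(u, v) for u, v, d in sub.edges(data=True)
                    if not _in_range(d[attr], bounds)]
            sub.remove_edges_from(drop)
    if top_n is not None:
        ranked = sorted(sub.edges(data=True), key=lambda e: e[2]["z"], reverse=True)
        kept_edges = ranked[: max(0, top_n)]
        keep_nodes = {u for u, _, _ in kept_edges} | {v for _, v, _ in kept_edges}
        sub = sub.edge_subgraph((u, v) for u, v, _ in kept_edges).copy() \
            if kept_edges else nx.Graph(**sub.graph)
        sub.remove_nodes_from([n for n in list(sub.nodes) if n not in keep_nodes])
    return sub


def neighborhood(network: nx.Graph, node: int, mode: str = "first_neighbors") -> nx.Graph:
    """First neighbors of a node, or its maximal connected component."""
    if node not in network:
        raise KeyError(f"node {node} not in network")
    if mode == "first_neighbors":
        nodes = {node} | set(network.neighbors(node))
    elif mode == "connected_component":
        nodes = nx.node_connected_component(network, node)
    else:
        raise ValueError(f"unknown neighborhood mode {mode!r}")
    return network.subgraph(nodes).copy()
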