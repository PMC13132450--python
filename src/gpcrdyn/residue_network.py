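"""Dynamic residue-network analysis: occupancy-gated, correlation-weighted
residue graphs, optimal and suboptimal communication paths, and
Girvan–Newman communities.

Edges connect residues whose heavy atoms are within 4.5 Å for more than 75%
of the frames (the gate is strict, the distance cutoff inclusive).  Edge
weights are ``w_ij = -log |C_ij|`` with ``C_ij`` the normalised covariance of
the two residues' reference-point displacements, so strongly correlated
residues are "close" and the shortest (optimal) path between distant
residues models their dominant communication route.  Residue reference
points are Cα for amino acids and the heavy-atom centroid otherwise.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import contact_frequency, _pairwise_min
from .core_io import Role, SelectionSpec, TrajectoryWindow
from .errors import CommunityError, NoPathError, SpecError

__all__ = [
    "ResidueGraph",
    "PathResult",
    "CommunityPartition",
    "build_graph",
    "optimal_path",
    "suboptimal_paths",
    "communities",
]

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class ResidueGraph:
    """Undirected residue graph with occupancy, correlation and weight per edge."""

    graph: nx.Graph
    contact_cutoff: float
    occupancy_gate: float

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def edge_data(self, i: int, j: int) -> dict:
        return self.graph.edges[i, j]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"i": i, "j": j, "occupancy": d["occupancy"], "C": d["correlation"], "w": d["weight"]}
            for i, j, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PathResult:
    """A residue path with its total length (sum of traversed edge weights)."""

    nodes: tuple[int, ...]
    length: float
    optimal: bool = False

    def labelled(self, numbering=None, chain: str = "R") -> list[str]:
        if numbering is None:
            return [str(n) for n in self.nodes]
        out = []
        for n in self.nodes:
            try:
                out.append(numbering.label_for(chain, n))
            except Exception:
                out.append(str(n))
        return out


@dataclass
class CommunityPartition:
    """Node -> community assignment at the maximum-modularity GN split."""

    assignment: dict[int, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _reference_points(traj: TrajectoryWindow, residues: list[int]) -> np.ndarray:
    """Per-residue reference trajectory: Cα if present, else heavy centroid."""
    top = traj.topology
    heavy = top.heavy_mask()
    points = np.empty((traj.n_frames, len(residues), 3))
    for k, seq in enumerate(residues):
        rows = np.nonzero(top.residue_seq == seq)[0]
        if rows.size == 0:
            raise SpecError(f"residue {seq} not in topology")
        resname = top.residue_names[rows[0]].upper()
        ca = [r for r in rows if top.atom_names[r].upper() == "CA"]
        if resname in _AMINO_ACIDS and ca:
            points[:, k] = traj.frames[:, ca[0]]
        else:
            hrows = rows[heavy[rows]]
            points[:, k] = traj.frames[:, hrows].mean(axis=1)
    return points


def build_graph(
    traj: TrajectoryWindow,
    residues: list[int],
    contact_cutoff: float = 4.5,
    occupancy_gate: float = 0.75,
) -> ResidueGraph:
    """Build the dynamic residue network from a trajectory.

    An edge (i, j) exists iff the pair's heavy-atom contact occupancy at
    ``contact_cutoff`` is *strictly* greater than ``occupancy_gate`` ("over
    75%") and the displacement correlation is non-zero.  Residues with zero
    displacement variance (rigidly fixed) have undefined correlations; they
    are excluded from edges with a warning.
    """
    if len(residues) < 2:
        raise SpecError("need at least 2 residues")
    if traj.n_frames < 2:
        raise SpecError("need at least 2 frames")
    top = traj.topology
    heavy = top.heavy_mask()
    rows_by_res = {}
    for seq in residues:
        rows = np.nonzero((top.residue_seq == seq) & heavy)[0]
        if rows.size == 0:
            raise SpecError(f"residue {seq} has no heavy atoms")
        rows_by_res[seq] = rows

    points = _reference_points(traj, residues)
    disp = points - points.mean(axis=0, keepdims=True)
    # residue displacement (co)variances over frames
    var = (disp**2).sum(axis=2).mean(axis=0)     # (n_residues,)
    fixed = var < 1e-12
    if fixed.any():
        bad = [residues[k] for k in np.nonzero(fixed)[0]]
        warnings.warn(
            f"residues {bad} have zero displacement variance; correlations "
            "undefined, excluded from edges",
            stacklevel=2,
        )

    g = nx.Graph()
    g.add_nodes_from(residues)
    n = len(residues)
    for a in range(n):
        for b in range(a + 1, n):
            dmin = _pairwise_min(traj, rows_by_res[residues[a]], rows_by_res[residues[b]])
            occupancy = float((dmin <= contact_cutoff).mean())
            if occupancy <= occupancy_gate:
                continue
            if fixed[a] or fixed[b]:
                continue
            cov = (disp[:, a] * disp[:, b]).sum(axis=1).mean()
            corr = float(cov / np.sqrt(var[a] * var[b]))
            if corr == 0.0:
                continue
            g.add_edge(
                residues[a], residues[b],
                occupancy=occupancy, correlation=corr,
                weight=float(-np.log(min(abs(corr), 1.0))),
            )
    return ResidueGraph(graph=g, contact_cutoff=contact_cutoff, occupancy_gate=occupancy_gate)


# ---------------------------------------------------------------------------
# Paths
# ---------------------------------------------------------------------------

def optimal_path(rgraph: ResidueGraph, source: int, sink: int) -> PathResult:
    """Minimum-total-weight (optimal) path; ties broken lexicographically."""
    g = rgraph.graph
    if source == sink:
        raise SpecError("source and sink must differ")
    for node in (source, sink):
        if node not in g:
            raise SpecError(f"node {node} not in graph")
    if not nx.has_path(g, source, sink):
        comp_s = sorted(nx.node_connected_component(g, source))
        comp_t = sorted(nx.node_connected_component(g, sink))
        raise NoPathError(
            f"no path: {source} in component {comp_s}, {sink} in component {comp_t}"
        )
    best = min(
        nx.all_shortest_paths(g, source, sink, weight="weight"),
        key=tuple,
    )
    length = nx.path_weight(g, best, weight="weight")
    return PathResult(nodes=tuple(best), length=float(length), optimal=True)


def suboptimal_paths(
    rgraph: ResidueGraph, source: int, sink: int, tolerance: float
) -> list[PathResult]:
    """All simple paths within ``tolerance`` of the optimal length.

    Sorted by length, then lexicographically by node sequence; the optimal
    path(s) come first.  ``tolerance`` is a required parameter.
    """
    if tolerance < 0:
        raise SpecError("tolerance must be non-negative")
    opt = optimal_path(rgraph, source, sink)
    g = rgraph.graph
    limit = opt.length + tolerance + 1e-12

    # distance-to-sink lower bounds for pruning
    dist_to_sink = nx.single_source_dijkstra_path_length(g, sink, weight="weight")
    results: list[PathResult] = []

    def dfs(node: int, visited: set[int], path: list[int], length: float) -> None:
        if node == sink:
            results.append(PathResult(nodes=tuple(path), length=length))
            return
        for nbr in sorted(g.neighbors(node)):
            if nbr in visited or nbr not in dist_to_sink:
                continue
            w = g.edges[node, nbr]["weight"]
            if length + w + dist_to_sink[nbr] > limit:
                continue
            visited.add(nbr)
            path.append(nbr)
            dfs(nbr, visited, path, length + w)
            path.pop()
            visited.remove(nbr)

    dfs(source, {source}, [source], 0.0)
    results.sort(key=lambda p: (p.length, p.nodes))
    if results:
        results[0] = PathResult(nodes=results[0].nodes, length=results[0].length, optimal=True)
    return results


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def communities(rgraph: ResidueGraph) -> CommunityPartition:
    """Girvan–Newman divisive clustering, cut at maximum modularity.

    Edge betweenness (path lengths in the -log|C| weights) drives edge
    removal; modularity is evaluated with coupling strength |C| as the edge
    weight.  The undivided graph is a candidate partition, so a complete
    graph with equal weights stays a single community.
    """
    g = rgraph.graph
    if g.number_of_edges() == 0:
        raise CommunityError("community detection needs at least one edge")

    strength = g.copy()
    for i, j, d in strength.edges(data=True):
        strength.edges[i, j]["coupling"] = abs(d.get("correlation", 1.0))

    def most_valuable_edge(graph: nx.Graph):
        bw = nx.edge_betweenness_centrality(graph, weight="weight")
        return max(sorted(bw), key=lambda e: bw[e])

    candidates = [tuple(frozenset(c) for c in nx.connected_components(g))]
    gn = nx.community.girvan_newman(g, most_valuable_edge=most_valuable_edge)
    for partition in gn:
        candidates.append(tuple(frozenset(c) for c in partition))
        if len(partition) >= g.number_of_nodes():
            break

    def score(partition) -> float:
        return nx.community.modularity(strength, partition, weight="coupling")

    best = max(candidates, key=score)
    assignment: dict[int, int] = {}
    for cid, comm in enumerate(sorted(best, key=lambda c: min(c))):
        for node in comm:
            assignment[node] = cid
    return CommunityPartition(assignment=assignment, modularity=float(score(best)))


def paths_to_json(paths: list[PathResult], path: str | Path, numbering=None) -> None:
    """Export paths as ordered residue-label lists (generic labels if mapped)."""
    payload = [
        {
            "nodes": list(p.nodes),
            "labels": p.labelled(numbering),
            "length": p.length,
            "optimal": p.optimal,
        }
        for p in paths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
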