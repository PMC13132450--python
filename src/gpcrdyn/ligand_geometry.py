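"""Ligand conformational descriptors: the internal angle α, binding-site
superposed ligand RMSD, average-linkage pose clustering with medoid
selection, and bond-graph descriptors (rotatable-bond counts).

The internal angle α is the angle at the mid-chain vertex between the
phosphate head and the chain terminus — the shape coordinate that separates
U-shaped (α ≈ 60°), L-shaped (α ≈ 75°) and extended (α ≈ 180°) acyl-chain
conformations, and the second collective variable of the ligand-association
free-energy surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .core_io import BondOrder, SelectionSpec, TrajectoryWindow, resolve_selection
from .errors import GeometryError, GraphError, SelectionError, TopologyError

__all__ = [
    "AlphaAnchors",
    "InternalAngleSeries",
    "PoseClustering",
    "LigandGraph",
    "internal_angle",
    "alpha_series",
    "ligand_rmsd",
    "cluster_poses",
    "rotatable_bond_count",
    "LPA_18_0_SMILES",
    "LPA_18_1_SMILES",
    "lpa_graph",
]

#: 1-stearoyl-2-hydroxy-sn-glycero-3-phosphate (saturated C18 acyl chain)
LPA_18_0_SMILES = "CCCCCCCCCCCCCCCCCC(=O)OC[C@@H](O)COP(=O)(O)O"
#: 1-oleoyl-2-hydroxy-sn-glycero-3-phosphate (cis C9=C10 double bond)
LPA_18_1_SMILES = "CCCCCCCC/C=C\\CCCCCCCC(=O)OC[C@@H](O)COP(=O)(O)O"


@dataclass(frozen=True)
class AlphaAnchors:
    """Atom names defining the three α anchor points on the ligand.

    The head point is the phosphate P atom, the mid point is the midpoint of
    the C9/C10 positions, and the tail point is the midpoint of the two
    terminal chain carbons.
    """

    head: str = "P"
    mid: tuple[str, str] = ("C9", "C10")
    tail: tuple[str, str] = ("C1", "C2")


@dataclass
class InternalAngleSeries:
    """Per-frame internal angle α in [0, 180] degrees with its anchor record."""

    values: np.ndarray
    anchors: AlphaAnchors

    def mean(self) -> float:
        return float(self.values.mean())

    def sd(self) -> float:
        return float(self.values.std(ddof=0))


@dataclass
class PoseClustering:
    """Flat clustering of conformers with the representative (medoid) frame."""

    membership: np.ndarray       # cluster id per frame (1-based, scipy style)
    largest_cluster: int
    medoid_frame: int

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.membership == cluster_id)[0]


def internal_angle(head, mid, tail) -> float:
    """Angle (degrees, [0, 180]) at ``mid`` between ``head`` and ``tail``."""
    head, mid, tail = (np.asarray(p, dtype=float) for p in (head, mid, tail))
    u = head - mid
    v = tail - mid
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("anchor points coincide; internal angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def alpha_series(
    traj: TrajectoryWindow, anchors: AlphaAnchors = AlphaAnchors()
) -> InternalAngleSeries:
    """Per-frame ligand internal angle α from the anchor atom positions."""
    top = traj.topology
    from .core_io import Role

    def _row(name: str) -> int:
        for i in range(top.n_atoms):
            if top.roles[i] is Role.LIGAND and top.atom_names[i].upper() == name.upper():
                return i
        raise TopologyError(f"ligand anchor atom {name!r} missing from topology")

    head_row = _row(anchors.head)
    mid_rows = [_row(n) for n in anchors.mid]
    tail_rows = [_row(n) for n in anchors.tail]
    head = traj.frames[:, head_row]
    mid = traj.frames[:, mid_rows].mean(axis=1)
    tail = traj.frames[:, tail_rows].mean(axis=1)
    u = head - mid
    v = tail - mid
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise GeometryError("anchor points coincide in at least one frame")
    cosang = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
    return InternalAngleSeries(values=np.degrees(np.arccos(cosang)), anchors=anchors)


# ---------------------------------------------------------------------------
# Superposed ligand RMSD
# ---------------------------------------------------------------------------

def _superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (site atoms).

    Returns the rotation plus the two centroids; degenerate (collinear) site
    geometry raises :class:`GeometryError`.
    """
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    a = mobile - cm
    b = target - ct
    # collinearity check: rank of the site cloud
    if min(np.linalg.matrix_rank(a, tol=1e-8), np.linalg.matrix_rank(b, tol=1e-8)) < 2:
        raise GeometryError("site selection is collinear/degenerate; superposition ill-defined")
    rot, _ = Rotation.align_vectors(b, a)
    return rot, cm, ct


def ligand_rmsd(
    traj: TrajectoryWindow,
    ligand_sel: SelectionSpec,
    site_sel: SelectionSpec,
    reference_frame: int = 0,
    pairwise: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Ligand heavy-atom RMSD after superposing each frame on the binding site.

    Each frame is rigid-body fitted onto the reference using the site
    selection only; the RMSD is then computed over the ligand heavy atoms
    without refitting.  With ``pairwise=True`` the full symmetric conformer ×
    conformer RMSD matrix (every frame fitted onto every other) is also
    returned, as consumed by :func:`cluster_poses`.
    """
    top = traj.topology
    lig = resolve_selection(top, SelectionSpec(
        role=ligand_sel.role, chain=ligand_sel.chain, residue_seq=ligand_sel.residue_seq,
        atom_names=ligand_sel.atom_names, heavy_only=True))
    site = resolve_selection(top, SelectionSpec(
        role=site_sel.role, chain=site_sel.chain, residue_seq=site_sel.residue_seq,
        atom_names=site_sel.atom_names, heavy_only=True))
    if lig.size == 0 or site.size == 0:
        raise SelectionError("ligand or site selection resolved to no heavy atoms")
    if site.size < 3:
        raise GeometryError("site selection needs at least 3 atoms for superposition")
    lig_rows = top.index_of(lig)
    site_rows = top.index_of(site)

    def fitted_ligand(frame: int, onto: int) -> np.ndarray:
        rot, cm, ct = _superpose(traj.frames[frame, site_rows], traj.frames[onto, site_rows])
        return rot.apply(traj.frames[frame, lig_rows] - cm) + ct

    ref_lig = traj.frames[reference_frame, lig_rows]
    series = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        moved = fitted_ligand(f, reference_frame)
        series[f] = np.sqrt(((moved - ref_lig) ** 2).sum(axis=1).mean())

    matrix = None
    if pairwise:
        n = traj.n_frames
        matrix = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                moved = fitted_ligand(j, i)
                rmsd = np.sqrt(((moved - traj.frames[i, lig_rows]) ** 2).sum(axis=1).mean())
                matrix[i, j] = matrix[j, i] = rmsd
    return series, matrix


def cluster_poses(matrix: np.ndarray, cutoff: float) -> PoseClustering:
    """Average-linkage clustering of the RMSD matrix, cut at ``cutoff`` Å.

    The largest cluster (ties: the one containing the lowest frame index) is
    selected and its medoid — the member minimising the summed RMSD to all
    other members, ties broken by lowest frame index — is the representative
    ("most-preferred") pose.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n == 1:
        return PoseClustering(membership=np.array([1]), largest_cluster=1, medoid_frame=0)
    condensed = squareform(matrix, checks=False)
    tree = linkage(condensed, method="average")
    membership = fcluster(tree, t=cutoff, criterion="distance")
    sizes = {cid: (membership == cid).sum() for cid in np.unique(membership)}
    max_size = max(sizes.values())
    candidates = [cid for cid, s in sizes.items() if s == max_size]
    largest = min(candidates, key=lambda cid: np.nonzero(membership == cid)[0][0])
    members = np.nonzero(membership == largest)[0]
    sums = matrix[np.ix_(members, members)].sum(axis=1)
    medoid = int(members[int(np.argmin(sums))])  # argmin takes the lowest index on ties
    return PoseClustering(membership=membership, largest_cluster=int(largest), medoid_frame=medoid)


# ---------------------------------------------------------------------------
# Ligand bond graphs
# ---------------------------------------------------------------------------

@dataclass
class LigandGraph:
    """Heavy-atom bond graph of a ligand (elements, ids, bond orders)."""

    elements: list[str]
    bonds: list[tuple[int, int, BondOrder]]
    name: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_neighbors(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for a, b, _ in self.bonds:
            if self.elements[a].upper() not in ("H", "D") and self.elements[b].upper() not in ("H", "D"):
                adj[a].add(b)
                adj[b].add(a)
        return adj

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "LigandGraph":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise GraphError(f"RDKit could not parse SMILES {smiles!r}")
        order_map = {
            Chem.BondType.SINGLE: BondOrder.SINGLE,
            Chem.BondType.DOUBLE: BondOrder.DOUBLE,
            Chem.BondType.TRIPLE: BondOrder.TRIPLE,
            Chem.BondType.AROMATIC: BondOrder.AROMATIC,
        }
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map[b.GetBondType()])
            for b in mol.GetBonds()
        ]
        return cls(elements=elements, bonds=bonds, name=name)

    @classmethod
    def from_molblock(cls, molblock: str, name: str = "") -> "LigandGraph":
        from rdkit import Chem

        mol = Chem.MolFromMolBlock(molblock)
        if mol is None:
            raise GraphError("RDKit could not parse MOL block")
        graph = cls.from_smiles(Chem.MolToSmiles(mol), name=name)
        return graph


def lpa_graph(species: str) -> LigandGraph:
    """Bond graph of an LPA species: ``"18:0"`` (stearoyl) or ``"18:1"`` (oleoyl)."""
    if species == "18:0":
        return LigandGraph.from_smiles(LPA_18_0_SMILES, name="18:0-LPA")
    if species == "18:1":
        return LigandGraph.from_smiles(LPA_18_1_SMILES, name="18:1-LPA")
    raise GraphError(f"unknown LPA species {species!r}")


def rotatable_bond_count(graph: LigandGraph) -> int:
    """Count rotatable bonds: acyclic single bonds between non-terminal heavy atoms.

    A bond rotates iff it is a single bond, not in a ring (i.e. it is a
    bridge of the heavy-atom graph), and each end atom has at least two heavy
    neighbours.  Disconnected heavy-atom graphs raise :class:`GraphError`.
    """
    import networkx as nx

    heavy = [i for i, e in enumerate(graph.elements) if e.upper() not in ("H", "D")]
    g = nx.Graph()
    g.add_nodes_from(heavy)
    for a, b, order in graph.bonds:
        if a in g and b in g:
            g.add_edge(a, b, order=order)
    if g.number_of_nodes() and not nx.is_connected(g):
        raise GraphError("ligand heavy-atom graph is disconnected")
    bridges = set(frozenset(e) for e in nx.bridges(g))
    count = 0
    for a, b, order in graph.bonds:
        if a not in g or b not in g:
            continue
        if order is not BondOrder.SINGLE:
            continue
        if frozenset((a, b)) not in bridges:
            continue  # ring bond
        if g.degree[a] < 2 or g.degree[b] < 2:
            continue  # terminal heavy atom
        count += 1
    return count
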