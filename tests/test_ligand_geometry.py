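"""Internal angle, superposed RMSD, pose clustering and bond-graph counts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrdyn.core_io import BondOrder, Role, SelectionSpec
from gpcrdyn.errors import GeometryError, GraphError
from gpcrdyn.ligand_geometry import (
    LigandGraph,
    alpha_series,
    cluster_poses,
    internal_angle,
    ligand_rmsd,
    lpa_graph,
    rotatable_bond_count,
)
from gpcrdyn.synthetic_data import ContactScheduleSpec, make_toy_complex


class TestInternalAngle:
    def test_collinear_is_180(self):
        assert internal_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert internal_angle((0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(90.0)

    def test_135_degrees_hand_computed(self):
        # cos α = -1/sqrt(2) at the (1,0,0) vertex
        assert internal_angle((0, 0, 0), (1, 0, 0), (2, 1, 0)) == pytest.approx(135.0)

    def test_coincident_points_raise(self):
        with pytest.raises(GeometryError):
            internal_angle((1, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_invariance_rigid_motion_and_anchor_swap(self):
        rng = np.random.default_rng(40)
        h, m, t = rng.normal(size=(3, 3)) * 4
        ref = internal_angle(h, m, t)
        rot = Rotation.from_euler("xyz", [0.2, 0.9, -1.4])
        assert internal_angle(rot.apply(h) + 3, rot.apply(m) + 3, rot.apply(t) + 3) == pytest.approx(ref)
        assert internal_angle(t, m, h) == pytest.approx(ref)


class TestAlphaSeries:
    @pytest.mark.parametrize("shape,alpha", [("U", 60.0), ("L", 75.0), ("extended", 180.0)])
    def test_planted_shapes(self, shape, alpha):
        spec = ContactScheduleSpec(pairs=((124, 1.0),), n_frames=3, seed=0)
        traj = make_toy_complex(spec, ligand_shape=shape)
        series = alpha_series(traj)
        np.testing.assert_allclose(series.values, alpha, atol=1e-9)

    def test_composition_with_internal_angle(self):
        spec = ContactScheduleSpec(pairs=((124, 1.0),), n_frames=2, seed=0)
        traj = make_toy_complex(spec, ligand_shape="L")
        series = alpha_series(traj)
        top = traj.topology
        rows = {top.atom_names[i]: i for i in range(top.n_atoms) if top.roles[i] is Role.LIGAND}
        for f in range(traj.n_frames):
            head = traj.frames[f, rows["P"]]
            mid = 0.5 * (traj.frames[f, rows["C9"]] + traj.frames[f, rows["C10"]])
            tail = 0.5 * (traj.frames[f, rows["C1"]] + traj.frames[f, rows["C2"]])
            assert series.values[f] == pytest.approx(internal_angle(head, mid, tail))


def _kabsch_oracle(mobile, target):
    """Independent least-squares superposition (hand-coded Kabsch/SVD)."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - cm, target - ct
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cm, ct


class TestLigandRMSD:
    def _traj(self, n_frames=2, perturb=0.0, rigid=None, seed=41):
        spec = ContactScheduleSpec(pairs=((124, 1.0), (125, 1.0), (129, 1.0)),
                                   n_frames=n_frames, seed=seed)
        traj = make_toy_complex(spec, ligand_shape="U")
        rng = np.random.default_rng(seed)
        if perturb:
            lig_rows = [i for i, r in enumerate(traj.topology.roles) if r is Role.LIGAND]
            traj.frames[1:, lig_rows, :] += rng.normal(0, perturb, size=(n_frames - 1, len(lig_rows), 3))
        if rigid is not None:
            rot, shift = rigid
            for f in range(1, n_frames):
                traj.frames[f] = rot.apply(traj.frames[f]) + shift
        return traj

    SITE = SelectionSpec(role=Role.RECEPTOR)
    LIG = SelectionSpec(role=Role.LIGAND)

    def test_identical_frame_zero(self):
        spec = ContactScheduleSpec(pairs=((124, 1.0), (125, 1.0), (129, 1.0)), n_frames=1, seed=1)
        traj = make_toy_complex(spec)
        traj.frames = np.repeat(traj.frames, 2, axis=0)
        traj.frame_times = np.array([0.0, 10.0])
        series, _ = ligand_rmsd(traj, self.LIG, self.SITE)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_rigid_motion_removed_by_superposition(self):
        rot = Rotation.from_euler("zxz", [0.5, 1.0, -0.25])
        traj = self._traj(n_frames=1)
        traj.frames = np.repeat(traj.frames, 3, axis=0)
        traj.frame_times = np.array([0.0, 10.0, 20.0])
        for f in (1, 2):
            traj.frames[f] = rot.apply(traj.frames[f]) + np.array([4.0, -7.0, 2.0]) * f
        series, _ = ligand_rmsd(traj, self.LIG, self.SITE)
        np.testing.assert_allclose(series, 0.0, atol=1e-8)

    def test_matches_independent_kabsch_oracle(self):
        traj = self._traj(n_frames=4, perturb=0.8)
        series, matrix = ligand_rmsd(traj, self.LIG, self.SITE, pairwise=True)
        top = traj.topology
        lig_rows = [i for i, r in enumerate(top.roles) if r is Role.LIGAND]
        site_rows = [i for i, r in enumerate(top.roles) if r is Role.RECEPTOR]
        for f in range(traj.n_frames):
            R, cm, ct = _kabsch_oracle(traj.frames[f, site_rows], traj.frames[0, site_rows])
            moved = (traj.frames[f, lig_rows] - cm) @ R.T + ct
            expected = np.sqrt(((moved - traj.frames[0, lig_rows]) ** 2).sum(axis=1).mean())
            assert series[f] == pytest.approx(expected, abs=1e-6)
        # matrix symmetry and zero diagonal
        np.testing.assert_allclose(matrix, matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(matrix), 0.0, atol=1e-12)

    def test_collinear_site_raises(self):
        traj = self._traj(n_frames=2)
        top = traj.topology
        site_rows = [i for i, r in enumerate(top.roles) if r is Role.RECEPTOR]
        for k, row in enumerate(site_rows):
            traj.frames[:, row, :] = [float(k), 0.0, 0.0]
        with pytest.raises(GeometryError):
            ligand_rmsd(traj, self.LIG, self.SITE)


def _brute_average_linkage(matrix, cutoff):
    """Naive agglomerative average-linkage: merge while min average distance <= cutoff."""
    clusters = [[i] for i in range(matrix.shape[0])]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([matrix[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        if best[0] > cutoff:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


class TestClusterPoses:
    def test_hand_worked_matrix(self):
        m = np.array([[0, 1, 9], [1, 0, 9], [9, 9, 0]], dtype=float)
        pc = cluster_poses(m, cutoff=2.0)
        assert set(pc.members(pc.largest_cluster)) == {0, 1}
        assert pc.medoid_frame == 0   # tie broken by lowest frame index

    def test_single_conformer_is_its_own_medoid(self):
        pc = cluster_poses(np.zeros((1, 1)), cutoff=1.0)
        assert pc.medoid_frame == 0

    def test_matches_brute_force_on_random_conformers(self):
        rng = np.random.default_rng(44)
        pts = rng.uniform(0, 10, size=(12, 3))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for cutoff in (1.5, 3.0, 6.0):
            pc = cluster_poses(m, cutoff)
            got = {
                frozenset(np.nonzero(pc.membership == cid)[0].tolist())
                for cid in np.unique(pc.membership)
            }
            assert got == _brute_average_linkage(m, cutoff)

    def test_extreme_cutoffs(self):
        rng = np.random.default_rng(45)
        pts = rng.uniform(0, 5, size=(8, 2))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        assert len(np.unique(cluster_poses(m, 1e9).membership)) == 1
        assert len(np.unique(cluster_poses(m, 1e-12).membership)) == 8


def _exhaustive_rotatable(graph):
    """Independent classifier: ring test by removing the bond and re-checking
    connectivity with a plain BFS."""
    heavy = {i for i, e in enumerate(graph.elements) if e.upper() not in ("H", "D")}
    adj = {i: set() for i in heavy}
    for a, b, _ in graph.bonds:
        if a in heavy and b in heavy:
            adj[a].add(b)
            adj[b].add(a)

    def connected_without(a, b):
        seen, stack = {a}, [a]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if (node, nbr) in ((a, b), (b, a)):
                    continue
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return b in seen

    count = 0
    for a, b, order in graph.bonds:
        if a not in heavy or b not in heavy or order is not BondOrder.SINGLE:
            continue
        if len(adj[a]) < 2 or len(adj[b]) < 2:
            continue
        if connected_without(a, b):   # bond lies in a ring
            continue
        count += 1
    return count


class TestRotatableBonds:
    def test_ethane_and_butane(self):
        ethane = LigandGraph.from_smiles("CC")
        butane = LigandGraph.from_smiles("CCCC")
        assert rotatable_bond_count(ethane) == 0
        assert rotatable_bond_count(butane) == 1

    def test_lpa_species_counts(self):
        g0, g1 = lpa_graph("18:0"), lpa_graph("18:1")
        assert rotatable_bond_count(g0) == 22
        assert rotatable_bond_count(g1) == 21
        # the cis double bond removes exactly one rotatable bond
        assert rotatable_bond_count(g0) - rotatable_bond_count(g1) == 1

    def test_agrees_with_exhaustive_classifier(self):
        for smiles in ("CC", "CCCC", "c1ccccc1CCO", "CC(C)CC(=O)OC"):
            g = LigandGraph.from_smiles(smiles)
            assert rotatable_bond_count(g) == _exhaustive_rotatable(g)
        for species in ("18:0", "18:1"):
            g = lpa_graph(species)
            assert rotatable_bond_count(g) == _exhaustive_rotatable(g)

    def test_disconnected_graph_raises(self):
        g = LigandGraph(elements=["C", "C", "C"], bonds=[(0, 1, BondOrder.SINGLE)])
        with pytest.raises(GraphError):
            rotatable_bond_count(g)
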