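"""Contact frequencies, distance series and preset interface distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrdyn.contacts import (
    DistanceSeries,
    contact_frequency,
    interface_preset_distances,
    min_distance_series,
    segment_fingerprint,
)
from gpcrdyn.core_io import (
    GenericNumberingMap,
    Role,
    SelectionSpec,
    Topology,
    TrajectoryWindow,
)
from gpcrdyn.errors import LookupError_, MappingError, SelectionError, SpecError
from gpcrdyn.synthetic_data import ContactScheduleSpec, make_toy_complex


def _topology(n_atoms, residue_seq, roles=None, names=None, elements=None,
              resnames=None, chains=None):
    return Topology(
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=names or [f"C{i}" for i in range(n_atoms)],
        elements=elements or ["C"] * n_atoms,
        residue_seq=np.asarray(residue_seq),
        residue_names=resnames or ["GLY"] * n_atoms,
        chain_ids=chains or ["R"] * n_atoms,
        roles=roles or [Role.RECEPTOR] * n_atoms,
    )


def _window(top, frames):
    frames = np.asarray(frames, dtype=float)
    return TrajectoryWindow(
        topology=top, frames=frames, frame_times=np.arange(frames.shape[0], dtype=float)
    )


def test_min_distance_3_4_5_triangle():
    top = _topology(2, [1, 2])
    traj = _window(top, [[[0, 0, 0], [3, 4, 0]]])
    series = min_distance_series(
        traj,
        SelectionSpec(residue_seq=frozenset({1})),
        SelectionSpec(residue_seq=frozenset({2})),
    )
    assert series.values[0] == pytest.approx(5.0)


def test_min_distance_selection_vs_itself_is_zero():
    top = _topology(3, [1, 1, 1])
    traj = _window(top, [np.random.default_rng(0).normal(size=(3, 3))])
    spec = SelectionSpec(residue_seq=frozenset({1}))
    assert min_distance_series(traj, spec, spec).values[0] == 0.0


def test_min_distance_matches_brute_force():
    rng = np.random.default_rng(1)
    top = _topology(12, [1] * 5 + [2] * 7)
    frames = rng.uniform(-10, 10, size=(6, 12, 3))
    traj = _window(top, frames)
    series = min_distance_series(
        traj, SelectionSpec(residue_seq=frozenset({1})), SelectionSpec(residue_seq=frozenset({2}))
    )
    for f in range(6):
        brute = min(
            np.linalg.norm(frames[f, i] - frames[f, j])
            for i in range(5)
            for j in range(5, 12)
        )
        assert series.values[f] == pytest.approx(brute, abs=1e-12)


def test_empty_selection_raises():
    top = _topology(2, [1, 2])
    traj = _window(top, [[[0, 0, 0], [1, 0, 0]]])
    with pytest.raises(SelectionError):
        min_distance_series(traj, SelectionSpec(chain="Z"), SelectionSpec(residue_seq=frozenset({2})))


class TestContactFrequency:
    def test_planted_occupancy_returned_as_percentage(self):
        spec = ContactScheduleSpec(pairs=((124, 0.75),), n_frames=40, seed=2)
        traj = make_toy_complex(spec)
        cm = contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [124])
        assert cm.frequency[0] == 0.75
        assert cm.percentage[0] == 75.0

    def test_boundary_distance_counts_as_contact(self):
        top = _topology(2, [1, 900], roles=[Role.RECEPTOR, Role.LIGAND])
        traj = _window(top, [[[0, 0, 0], [4.0, 0, 0]]])
        cm = contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [1], cutoff=4.0)
        assert cm.frequency[0] == 1.0

    def test_matches_per_frame_brute_force(self):
        rng = np.random.default_rng(3)
        roles = [Role.RECEPTOR] * 6 + [Role.LIGAND] * 3
        top = _topology(9, [1, 1, 2, 2, 3, 3, 900, 900, 900], roles=roles)
        frames = rng.uniform(-6, 6, size=(10, 9, 3))
        traj = _window(top, frames)
        cm = contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [1, 2, 3], cutoff=4.0)
        for j, rows in enumerate([(0, 1), (2, 3), (4, 5)]):
            for f in range(10):
                brute = min(
                    np.linalg.norm(frames[f, i] - frames[f, l])
                    for i in rows for l in (6, 7, 8)
                )
                assert cm.states[f, j] == (brute <= 4.0)

    def test_missing_residue_raises(self):
        top = _topology(2, [1, 900], roles=[Role.RECEPTOR, Role.LIGAND])
        traj = _window(top, [[[0, 0, 0], [1, 0, 0]]])
        with pytest.raises(LookupError_):
            contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [999])

    def test_frequency_invariant_under_rigid_motion(self):
        spec = ContactScheduleSpec(pairs=((124, 0.5), (125, 0.25)), n_frames=8, seed=5)
        traj = make_toy_complex(spec)
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0])
        moved = _window(
            traj.topology, rot.apply(traj.frames.reshape(-1, 3)).reshape(traj.frames.shape) + 7.5
        )
        a = contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [124, 125])
        b = contact_frequency(moved, SelectionSpec(role=Role.LIGAND), [124, 125])
        np.testing.assert_array_equal(a.states, b.states)

    def test_extreme_cutoffs(self):
        spec = ContactScheduleSpec(pairs=((124, 0.5),), n_frames=4, seed=6)
        traj = make_toy_complex(spec)
        wide = contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [124], cutoff=1e6)
        assert wide.frequency[0] == 1.0
        tight = contact_frequency(traj, SelectionSpec(role=Role.LIGAND), [124], cutoff=1e-9)
        assert tight.frequency[0] == 0.0


class TestSegmentFingerprint:
    def _traj(self):
        roles = [Role.LIGAND] * 4 + [Role.LIPID] * 2
        names = ["P", "O1", "C9", "C17", "N", "C50"]
        top = _topology(6, [900, 900, 900, 900, 10, 11], roles=roles, names=names)
        frames = np.array(
            [
                [[0, 0, 0], [1, 0, 0], [8, 0, 0], [16, 0, 0], [2, 0, 0], [17, 0, 0]],
                [[0, 0, 0], [1, 0, 0], [8, 0, 0], [16, 0, 0], [30, 0, 0], [17, 0, 0]],
            ],
            dtype=float,
        )
        return _window(top, frames)

    def test_planted_and_zero_frequencies(self):
        traj = self._traj()
        segments = {
            "head": SelectionSpec(atom_names=frozenset({"P", "O1"})),
            "tail": SelectionSpec(atom_names=frozenset({"C17"})),
        }
        partners = {
            "choline": SelectionSpec(residue_seq=frozenset({10})),
            "alkyl": SelectionSpec(residue_seq=frozenset({11})),
        }
        fps = {fp.segment: fp.frequencies for fp in segment_fingerprint(traj, segments, partners)}
        assert fps["head"]["choline"] == 0.5   # within 4 Å in frame 0 only
        assert fps["head"]["alkyl"] == 0.0
        assert fps["tail"]["alkyl"] == 1.0

    def test_overlapping_segments_rejected(self):
        traj = self._traj()
        segments = {
            "head": SelectionSpec(atom_names=frozenset({"P", "O1"})),
            "also_head": SelectionSpec(atom_names=frozenset({"P"})),
        }
        with pytest.raises(SpecError, match="overlap"):
            segment_fingerprint(traj, segments, {"x": SelectionSpec(residue_seq=frozenset({10}))})


class TestInterfacePresets:
    def _interface_traj(self):
        names = ["NE", "NH1", "O", "NZ", "OD1", "OD2", "ND2"]
        resnames = ["ARG", "ARG", "CYS", "LYS", "ASP", "ASP", "ASN"]
        seqs = [146, 146, 351, 316, 350, 350, 347]
        chains = ["R", "R", "G", "R", "G", "G", "G"]
        roles = [Role.RECEPTOR, Role.RECEPTOR, Role.GPROTEIN, Role.RECEPTOR,
                 Role.GPROTEIN, Role.GPROTEIN, Role.GPROTEIN]
        top = Topology(
            atom_ids=np.arange(1, 8), atom_names=names,
            elements=[n[0] for n in names], residue_seq=np.array(seqs),
            residue_names=resnames, chain_ids=chains, roles=roles,
        )
        frames = np.array([[
            [0, 0, 0], [1, 0, 0], [0, 2.8, 0],      # R146 NE/NH1; C351 backbone O
            [10, 0, 0], [10, 3.1, 0], [10, 3.5, 0],  # K316 NZ; D350 OD1/OD2
            [20, 0, 0],
        ]], dtype=float)
        return _window(top, frames)

    def _map(self):
        return GenericNumberingMap(entries={
            ("R", 146): "3.50", ("R", 316): "8.49",
            ("G", 351): "G.H5.23", ("G", 350): "G.H5.22", ("G", 347): "G.H5.19",
        })

    def test_planted_donor_acceptor_distance(self):
        presets = {"pair": [{"name": "3.50-G.H5.23", "a_label": "3.50",
                             "a_atoms": ["NE", "NH1"], "b_label": "G.H5.23",
                             "b_atoms": ["O"]}]}
        series = interface_preset_distances(self._interface_traj(), self._map(), "pair", presets)
        assert series[0].values[0] == pytest.approx(2.8)

    def test_unresolvable_label_raises(self):
        presets = {"pair": [{"a_label": "7.53", "b_label": "G.H5.23"}]}
        with pytest.raises(MappingError):
            interface_preset_distances(self._interface_traj(), self._map(), "pair", presets)

    def test_preset_equals_componentwise_min_distance(self):
        traj = self._interface_traj()
        presets = {"iface": [
            {"a_label": "3.50", "a_atoms": ["NE", "NH1"], "b_label": "G.H5.23", "b_atoms": ["O"]},
            {"a_label": "8.49", "a_atoms": ["NZ"], "b_label": "G.H5.22", "b_atoms": ["OD1", "OD2"]},
        ]}
        series = interface_preset_distances(traj, self._map(), "iface", presets)
        direct = min_distance_series(
            traj,
            SelectionSpec(chain="R", residue_seq=frozenset({316}), atom_names=frozenset({"NZ"})),
            SelectionSpec(chain="G", residue_seq=frozenset({350}),
                          atom_names=frozenset({"OD1", "OD2"})),
        )
        np.testing.assert_allclose(series[1].values, direct.values)
        assert series[1].values[0] == pytest.approx(3.1)


def test_summary_statistics_match_sorting():
    rng = np.random.default_rng(8)
    values = rng.uniform(0, 20, size=101)
    series = DistanceSeries("x", values)
    s = series.summary()
    ordered = np.sort(values)
    assert s["median"] == pytest.approx(ordered[50])
    assert s["min"] == ordered[0] and s["max"] == ordered[-1]
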