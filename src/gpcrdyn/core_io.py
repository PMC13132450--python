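"""Topology/trajectory data model, the selection mini-language, generic residue
numbering (Ballesteros–Weinstein / CGN), and readers/writers for the standard
structure and trajectory formats every analysis module consumes.

Conventions used throughout the package:

* coordinates are Cartesian and in Å (readers convert nm-based containers on
  ingest);
* residue numbering is taken verbatim from the input file (1-based author
  numbering); generic labels such as ``3.50`` or ``G.H5.22`` live only in the
  :class:`GenericNumberingMap` and are never inferred;
* a *heavy* atom is any element other than H/D;
* when a periodic box is present, distances use the minimum-image convention
  for orthorhombic cells; toy fixtures are non-periodic.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    FormatError,
    MappingError,
    RoleAssignmentError,
    SelectionError,
    TopologyError,
    TruncationError,
)

__all__ = [
    "Role",
    "BondOrder",
    "Topology",
    "TrajectoryWindow",
    "SelectionSpec",
    "GenericNumberingMap",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
]


class Role(enum.Enum):
    """Coarse biochemical role of an atom; the role partition is total."""

    RECEPTOR = "receptor"
    LIGAND = "ligand"
    GPROTEIN = "gprotein"
    WATER = "water"
    LIPID = "lipid"
    ION = "ion"


class BondOrder(enum.Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


#: elements treated as non-heavy throughout the package
_LIGHT_ELEMENTS = {"H", "D"}

#: two-letter element symbols recognised when inferring elements from names
_TWO_LETTER = {"CL", "NA", "MG", "ZN", "FE", "BR", "CA_ION"}


@dataclass(frozen=True)
class Bond:
    atom_a: int
    atom_b: int
    order: BondOrder = BondOrder.SINGLE


@dataclass
class Topology:
    """Static atom table: identities, residues, chains, roles and optional bonds.

    All per-atom fields are parallel arrays/lists of length ``n_atoms``;
    ``atom_ids`` must be unique and strictly increasing.
    """

    atom_ids: np.ndarray           # (n,) int
    atom_names: list[str]
    elements: list[str]
    residue_seq: np.ndarray        # (n,) int
    residue_names: list[str]
    chain_ids: list[str]
    roles: list[Role]
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        n = len(self.atom_ids)
        for name, seq in [
            ("atom_names", self.atom_names),
            ("elements", self.elements),
            ("residue_names", self.residue_names),
            ("chain_ids", self.chain_ids),
            ("roles", self.roles),
        ]:
            if len(seq) != n:
                raise TopologyError(f"{name} has length {len(seq)}, expected {n}")
        if n and not np.all(np.diff(self.atom_ids) > 0):
            raise TopologyError("atom_ids must be unique and strictly increasing")
        ids = set(self.atom_ids.tolist())
        for b in self.bonds:
            if b.atom_a not in ids or b.atom_b not in ids:
                raise TopologyError(f"bond ({b.atom_a}, {b.atom_b}) references unknown atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def index_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        """Map atom ids to 0-based row indices."""
        lookup = {int(a): i for i, a in enumerate(self.atom_ids)}
        try:
            return np.array([lookup[int(a)] for a in atom_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise TopologyError(f"atom id {exc.args[0]} not in topology") from exc

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() not in _LIGHT_ELEMENTS for e in self.elements])


@dataclass
class TrajectoryWindow:
    """A contiguous block of frames over a fixed topology (coordinates in Å)."""

    topology: Topology
    frames: np.ndarray             # (n_frames, n_atoms, 3) Å
    frame_times: np.ndarray        # (n_frames,) ps, strictly increasing
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic edges Å, or None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if len(self.frame_times) != self.frames.shape[0]:
            raise TopologyError("frame_times length must equal n_frames")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise TopologyError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise TopologyError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.frames.shape[0], 3):
                raise TopologyError("box must be (n_frames, 3) edge lengths")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection resolved deterministically against a Topology.

    All filters are conjunctive; ``None`` means "no constraint".  ``residue_seq``
    may be a set of residue numbers or an inclusive ``(lo, hi)`` range.
    """

    role: Role | None = None
    chain: str | None = None
    residue_seq: frozenset[int] | tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False

    def _residue_mask(self, seqs: np.ndarray) -> np.ndarray:
        if self.residue_seq is None:
            return np.ones(len(seqs), dtype=bool)
        if isinstance(self.residue_seq, tuple):
            lo, hi = self.residue_seq
            return (seqs >= lo) & (seqs <= hi)
        wanted = set(self.residue_seq)
        return np.array([int(s) in wanted for s in seqs])


def resolve_selection(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Return the ordered (by atom_id) array of atom ids matching ``spec``.

    An empty result is valid; ordering is canonical regardless of input file
    ordering because atom_ids are strictly increasing in the topology.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if spec.role is not None:
        mask &= np.array([r is spec.role for r in topology.roles])
    if spec.chain is not None:
        mask &= np.array([c == spec.chain for c in topology.chain_ids])
    mask &= spec._residue_mask(topology.residue_seq)
    if spec.atom_names is not None:
        wanted = {n.upper() for n in spec.atom_names}
        mask &= np.array([n.upper() in wanted for n in topology.atom_names])
    if spec.heavy_only:
        mask &= topology.heavy_mask()
    return topology.atom_ids[mask]


# ---------------------------------------------------------------------------
# Generic numbering (Ballesteros–Weinstein / CGN)
# ---------------------------------------------------------------------------

@dataclass
class GenericNumberingMap:
    """Map author residue numbering to generic labels ("3.50", "G.H5.22").

    Stored as ``(chain, residue_seq) -> label`` with an optional motif tag
    (CWxP, PIF, NPxxY, DRY/ERH).  Labels must be injective within a chain.
    """

    entries: dict[tuple[str, int], str] = field(default_factory=dict)
    motifs: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_chain: dict[str, set[str]] = {}
        for (chain, _), label in self.entries.items():
            seen = by_chain.setdefault(chain, set())
            if label in seen:
                raise MappingError(f"label {label!r} assigned twice within chain {chain!r}")
            seen.add(label)

    def label_for(self, chain: str, residue_seq: int) -> str:
        try:
            return self.entries[(chain, residue_seq)]
        except KeyError as exc:
            raise MappingError(f"residue {chain}:{residue_seq} has no generic label") from exc

    def residue_for(self, label: str) -> tuple[str, int]:
        for (chain, seq), lab in self.entries.items():
            if lab == label:
                return chain, seq
        raise MappingError(f"generic label {label!r} not present in numbering map")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenericNumberingMap":
        entries: dict[tuple[str, int], str] = {}
        motifs: dict[tuple[str, int], str] = {}
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh), start=1):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                if len(row) < 3:
                    raise FormatError("numbering map rows need chain,residue_seq,label", i)
                chain, seq_s, label = row[0].strip(), row[1].strip(), row[2].strip()
                try:
                    seq = int(seq_s)
                except ValueError:
                    raise FormatError(f"residue_seq {seq_s!r} is not an integer", i) from None
                entries[(chain, seq)] = label
                if len(row) > 3 and row[3].strip():
                    motifs[(chain, seq)] = row[3].strip()
        return cls(entries=entries, motifs=motifs)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for (chain, seq), label in sorted(self.entries.items()):
                motif = self.motifs.get((chain, seq), "")
                row = [chain, seq, label] + ([motif] if motif else [])
                writer.writerow(row)


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name when columns 77-78 are blank."""
    stripped = atom_name.strip()
    alpha = "".join(c for c in stripped if c.isalpha())
    if not alpha:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = alpha[:2].upper()
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE"} and len(stripped) > 1:
        return two.capitalize()
    return alpha[0].upper()


def _coerce_role(value: "Role | str") -> Role:
    return value if isinstance(value, Role) else Role(value)


def read_structure(
    path: str | Path, role_rules: Mapping[str, "Role | str"]
) -> tuple[Topology, TrajectoryWindow]:
    """Parse a PDB file into a Topology plus a single-frame TrajectoryWindow.

    ``role_rules`` maps every chain id present in the file to a :class:`Role`
    (or its string value).  One atom is produced per ATOM/HETATM record;
    malformed records raise :class:`FormatError` with the line number, chains
    missing from ``role_rules`` raise :class:`RoleAssignmentError`.
    """
    rules = {k: _coerce_role(v) for k, v in role_rules.items()}
    ids: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    seqs: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    roles: list[Role] = []
    coords: list[tuple[float, float, float]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            try:
                atom_id = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip()
                seq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed ATOM/HETATM record: {exc}", lineno) from None
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                try:
                    element = _infer_element(name)
                except ValueError as exc:
                    raise FormatError(str(exc), lineno) from None
            if chain not in rules:
                raise RoleAssignmentError(
                    f"chain {chain!r} (line {lineno}) has no entry in the role rules"
                )
            ids.append(atom_id)
            names.append(name)
            elements.append(element)
            seqs.append(seq)
            resnames.append(resname)
            chains.append(chain)
            roles.append(rules[chain])
            coords.append((x, y, z))

    order = np.argsort(np.asarray(ids, dtype=int), kind="stable")
    topology = Topology(
        atom_ids=np.asarray(ids)[order],
        atom_names=[names[i] for i in order],
        elements=[elements[i] for i in order],
        residue_seq=np.asarray(seqs)[order],
        residue_names=[resnames[i] for i in order],
        chain_ids=[chains[i] for i in order],
        roles=[roles[i] for i in order],
    )
    frame = np.asarray(coords, dtype=float)[order][None, :, :]
    window = TrajectoryWindow(topology=topology, frames=frame, frame_times=np.array([0.0]))
    return topology, window


def write_structure(window: TrajectoryWindow, path: str | Path, frame: int = 0) -> None:
    """Write one frame as fixed-column PDB (coordinates to 3 decimals)."""
    top = window.topology
    xyz = window.frames[frame]
    with open(path, "w") as fh:
        for i in range(top.n_atoms):
            name = top.atom_names[i]
            # PDB convention: 1-3 char names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name[:4]
            fh.write(
                "ATOM  {aid:>5d} {name:4s} {res:<3s} {chain:1s}{seq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n".format(
                    aid=int(top.atom_ids[i]),
                    name=padded,
                    res=top.residue_names[i][:3],
                    chain=top.chain_ids[i][:1] or "A",
                    seq=int(top.residue_seq[i]),
                    x=xyz[i, 0],
                    y=xyz[i, 1],
                    z=xyz[i, 2],
                    el=top.elements[i][:2],
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Multi-frame trajectory containers (DCD / XTC via MDAnalysis readers)
# ---------------------------------------------------------------------------

def _reader_for(path: Path):
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader

        return DCDReader(str(path))
    if suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader

        return XTCReader(str(path))
    raise FormatError(f"unsupported trajectory container {suffix!r} (use .dcd or .xtc)")


def read_trajectory(topology: Topology, path: str | Path) -> TrajectoryWindow:
    """Read a DCD/XTC container against ``topology``; coordinates returned in Å.

    MDAnalysis readers convert nm-based containers (XTC) to Å on ingest.  An
    atom-count mismatch raises :class:`TopologyError`; a truncated container
    raises :class:`TruncationError` reporting the last intact frame.
    """
    path = Path(path)
    reader = _reader_for(path)
    try:
        if reader.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"container has {reader.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        frames: list[np.ndarray] = []
        times: list[float] = []
        try:
            for ts in reader:
                frames.append(np.array(ts.positions, dtype=float))
                times.append(float(ts.time))
        except (EOFError, OSError, ValueError) as exc:
            raise TruncationError(f"trajectory ended mid-frame: {exc}", len(frames) - 1) from exc
    finally:
        reader.close()
    times_arr = np.asarray(times, dtype=float)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        # containers without time metadata fall back to frame indices
        times_arr = np.arange(len(frames), dtype=float)
    return TrajectoryWindow(
        topology=topology, frames=np.stack(frames), frame_times=times_arr
    )


def write_trajectory(window: TrajectoryWindow, path: str | Path) -> None:
    """Write frames to a DCD/XTC container (units handled by MDAnalysis)."""
    import MDAnalysis as mda

    path = Path(path)
    n = window.topology.n_atoms
    universe = mda.Universe.empty(n, trajectory=True)
    dt = float(window.frame_times[1] - window.frame_times[0]) if window.n_frames > 1 else 1.0
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDWriter

        writer = DCDWriter(str(path), n_atoms=n, dt=dt)
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCWriter

        writer = XTCWriter(str(path), n_atoms=n)
    else:
        raise FormatError(f"unsupported trajectory container {suffix!r} (use .dcd or .xtc)")
    with writer:
        for i in range(window.n_frames):
            universe.atoms.positions = window.frames[i].astype(np.float32)
            universe.trajectory.ts.time = float(window.frame_times[i])
            universe.trajectory.ts.frame = i
            writer.write(universe.atoms)


def minimum_image_displacements(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)
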