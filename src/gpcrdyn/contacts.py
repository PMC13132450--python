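"""Contact-frequency analysis and nearest-heavy-atom distance series.

Implements the contact bookkeeping used for orthosteric-pocket fingerprints
and for the receptor–Gα interface: per-residue contact occupancy at a 4 Å
heavy-atom cutoff (inclusive), per-segment ligand fingerprints against
residue or lipid-group partners, and named polar-interaction distance presets
(salt bridges between charged-group heavy atoms, H-bond donor to backbone
carbonyl O).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .core_io import (
    GenericNumberingMap,
    SelectionSpec,
    Topology,
    TrajectoryWindow,
    minimum_image_displacements,
    resolve_selection,
)
from .errors import LookupError_, MappingError, SelectionError, SpecError

__all__ = [
    "ContactMatrix",
    "DistanceSeries",
    "SegmentFingerprint",
    "min_distance_series",
    "contact_frequency",
    "segment_fingerprint",
    "interface_preset_distances",
    "load_presets",
]


@dataclass
class DistanceSeries:
    """Per-frame distance (Å) between two atom groups."""

    label: str
    values: np.ndarray
    definition: str = "min_heavy_heavy"   # or "named_atom_pair"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and non-negative")

    def summary(self) -> dict[str, float]:
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        return {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(self.values.min()), "max": float(self.values.max()),
        }


@dataclass
class ContactMatrix:
    """Per-frame boolean residue contacts and the derived occupancy."""

    residue_seq: list[int]
    states: np.ndarray      # (n_frames, n_residues) bool
    cutoff: float

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def frequency(self) -> np.ndarray:
        """Fraction of frames in contact, exactly n_true / n_frames."""
        return self.states.sum(axis=0) / self.n_frames

    @property
    def percentage(self) -> np.ndarray:
        return 100.0 * self.frequency

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_seq,
                "frequency_pct": self.percentage,
                "n_frames": self.n_frames,
                "cutoff": self.cutoff,
            }
        )


@dataclass
class SegmentFingerprint:
    """Contact-frequency table of one ligand segment against named partners."""

    segment: str
    frequencies: dict[str, float]   # partner name -> fraction in [0, 1]


def _heavy(spec: SelectionSpec) -> SelectionSpec:
    if spec.heavy_only:
        return spec
    return SelectionSpec(
        role=spec.role, chain=spec.chain, residue_seq=spec.residue_seq,
        atom_names=spec.atom_names, heavy_only=True,
    )


def _pairwise_min(traj: TrajectoryWindow, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Per-frame minimum pair distance between two atom-row sets."""
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if traj.box is None:
            out[f] = cdist(traj.frames[f, rows_a], traj.frames[f, rows_b]).min()
        else:
            delta = traj.frames[f, rows_a][:, None, :] - traj.frames[f, rows_b][None, :, :]
            delta = minimum_image_displacements(delta, traj.box[f])
            out[f] = np.sqrt((delta**2).sum(axis=-1)).min()
    return out


def min_distance_series(
    traj: TrajectoryWindow,
    sel_a: SelectionSpec,
    sel_b: SelectionSpec,
    label: str = "min_distance",
) -> DistanceSeries:
    """Per-frame minimum heavy-atom distance between two selections.

    Uses the minimum-image convention when the trajectory carries a box.
    Empty selections raise :class:`SelectionError`.
    """
    top = traj.topology
    ids_a = resolve_selection(top, _heavy(sel_a))
    ids_b = resolve_selection(top, _heavy(sel_b))
    if ids_a.size == 0 or ids_b.size == 0:
        raise SelectionError(f"selection resolved to no heavy atoms for {label!r}")
    rows_a = top.index_of(ids_a)
    rows_b = top.index_of(ids_b)
    return DistanceSeries(label=label, values=_pairwise_min(traj, rows_a, rows_b))


def contact_frequency(
    traj: TrajectoryWindow,
    ligand_sel: SelectionSpec,
    residues: list[int],
    cutoff: float = 4.0,
) -> ContactMatrix:
    """Residue–ligand contact occupancy at an inclusive heavy-atom cutoff.

    A residue is in contact in a frame iff its minimum heavy-atom distance to
    the ligand selection is <= ``cutoff`` (the boundary counts as contact).
    Residues absent from the topology raise :class:`LookupError_`.
    """
    top = traj.topology
    lig_ids = resolve_selection(top, _heavy(ligand_sel))
    if lig_ids.size == 0:
        raise SelectionError("ligand selection resolved to no heavy atoms")
    lig_rows = top.index_of(lig_ids)
    states = np.zeros((traj.n_frames, len(residues)), dtype=bool)
    heavy = top.heavy_mask()
    for j, seq in enumerate(residues):
        rows = np.nonzero((top.residue_seq == seq) & heavy)[0]
        if rows.size == 0:
            raise LookupError_(f"residue {seq} has no heavy atoms in the topology")
        states[:, j] = _pairwise_min(traj, rows, lig_rows) <= cutoff
    return ContactMatrix(residue_seq=list(residues), states=states, cutoff=cutoff)


def segment_fingerprint(
    traj: TrajectoryWindow,
    ligand_segments: dict[str, SelectionSpec],
    partners: dict[str, SelectionSpec],
    cutoff: float = 4.0,
) -> list[SegmentFingerprint]:
    """Per-segment contact-frequency tables against residue or lipid groups.

    Segments must resolve to disjoint atom sets (overlap raises
    :class:`SpecError`).  Typical segments: glycerophosphate head, upper acyl
    chain (C1–C9), lower acyl chain (C10–C18).
    """
    top = traj.topology
    resolved = {
        name: resolve_selection(top, _heavy(spec)) for name, spec in ligand_segments.items()
    }
    seen: set[int] = set()
    for name, ids in resolved.items():
        overlap = seen.intersection(ids.tolist())
        if overlap:
            raise SpecError(f"segment {name!r} overlaps a previous segment on atoms {sorted(overlap)}")
        seen.update(ids.tolist())

    results = []
    for name, ids in resolved.items():
        freqs: dict[str, float] = {}
        if ids.size == 0:
            raise SelectionError(f"segment {name!r} resolved to no heavy atoms")
        rows = top.index_of(ids)
        for pname, pspec in partners.items():
            pids = resolve_selection(top, _heavy(pspec))
            if pids.size == 0:
                raise SelectionError(f"partner {pname!r} resolved to no heavy atoms")
            prows = top.index_of(pids)
            dmin = _pairwise_min(traj, rows, prows)
            freqs[pname] = float((dmin <= cutoff).mean())
        results.append(SegmentFingerprint(segment=name, frequencies=freqs))
    return results


# ---------------------------------------------------------------------------
# Named interface presets
# ---------------------------------------------------------------------------

def load_presets(path: str | Path | None = None) -> dict:
    """Load distance presets (YAML keyed by generic labels).

    The packaged default encodes the receptor–Gα polar-interaction pairs
    (3.50 sidechain to G.H5.23 backbone carbonyl, 3.56–G.H5.22, H8–G.H5.22,
    3.56–G.H5.19) and the activation-switch pairs.
    """
    if path is None:
        text = resources.files("gpcrdyn.data").joinpath("presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def interface_preset_distances(
    traj: TrajectoryWindow,
    numbering: GenericNumberingMap,
    preset: str,
    presets: dict | None = None,
) -> list[DistanceSeries]:
    """Distance series for every pair of a named polar-interaction preset.

    Each pair lists two generic labels plus optional atom-name groups (e.g.
    charged-group nitrogens vs carboxylate oxygens for a salt bridge, or the
    backbone carbonyl O for an H-bond acceptor).  Labels that the numbering
    map cannot resolve, or atom groups absent from the topology, raise
    :class:`MappingError`.
    """
    table = presets if presets is not None else load_presets()
    if preset not in table:
        raise MappingError(f"unknown preset {preset!r}; available: {sorted(table)}")
    series = []
    for pair in table[preset]:
        specs = []
        for side in ("a", "b"):
            label = pair[f"{side}_label"]
            chain, seq = numbering.residue_for(label)
            atoms = pair.get(f"{side}_atoms")
            specs.append(
                SelectionSpec(
                    chain=chain,
                    residue_seq=frozenset({seq}),
                    atom_names=frozenset(atoms) if atoms else None,
                    heavy_only=True,
                )
            )
        name = pair.get("name", f"{pair['a_label']}-{pair['b_label']}")
        try:
            series.append(
                min_distance_series(traj, specs[0], specs[1], label=name)
            )
        except SelectionError as exc:
            raise MappingError(f"preset pair {name!r} resolves to no atoms: {exc}") from exc
    return series


def contacts_to_csv(matrix: ContactMatrix, path: str | Path, label: str = "") -> None:
    """Tidy CSV export (residue, label, frequency_pct, n_frames, cutoff)."""
    df = matrix.to_frame()
    df.insert(1, "label", label)
    df.to_csv(path, index=False)
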