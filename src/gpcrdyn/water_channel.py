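"""Water bookkeeping: counts near the ligand, waters bridging ligand and
pocket, upper↔lower flux events with a hysteresis rule, and transmembrane
channel continuity along a pore axis.

A water is represented by its O atom throughout (H positions are noise at a
4 Å counting cutoff).  A flux *crossing* is recorded only when a water that
was last beyond one plane reaches beyond the other — re-entering the
inter-plane slab without reaching the far plane records nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import Role, SelectionSpec, TrajectoryWindow, resolve_selection
from .errors import GeometryError, SelectionError, SpecError, TopologyError

__all__ = [
    "WaterCountSeries",
    "FluxResult",
    "ChannelProfile",
    "waters_near",
    "bridging_waters",
    "water_flux",
    "channel_profile",
    "suggest_planes",
]


@dataclass
class WaterCountSeries:
    """Per-frame water counts with the counting criterion attached."""

    counts: np.ndarray
    cutoff: float
    criterion: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class FluxResult:
    """Crossing bookkeeping between two z-planes.

    ``per_water`` maps water residue_seq -> (downward, upward) event counts;
    ``total_events`` counts events, ``unique_waters`` counts distinct waters
    with at least one event (both are reported because "how many waters
    moved" and "how many traversals happened" are different questions).
    """

    per_water: dict[int, tuple[int, int]]
    upper_z: float
    lower_z: float

    @property
    def total_events(self) -> int:
        return sum(d + u for d, u in self.per_water.values())

    @property
    def unique_waters(self) -> int:
        return sum(1 for d, u in self.per_water.values() if d + u > 0)

    @property
    def downward(self) -> int:
        return sum(d for d, _ in self.per_water.values())

    @property
    def upward(self) -> int:
        return sum(u for _, u in self.per_water.values())


@dataclass
class ChannelProfile:
    """Per-frame per-bin water counts inside a pore cylinder."""

    bin_edges: np.ndarray
    counts: np.ndarray          # (n_frames, n_bins)
    continuous: np.ndarray      # (n_frames,) bool: every bin occupied

    @property
    def continuity_fraction(self) -> float:
        return float(self.continuous.mean())


def _water_rows(traj: TrajectoryWindow) -> np.ndarray:
    """Row indices of water O atoms, grouped order preserved."""
    top = traj.topology
    rows = np.array(
        [
            i
            for i in range(top.n_atoms)
            if top.roles[i] is Role.WATER and top.elements[i].upper() == "O"
        ],
        dtype=int,
    )
    return rows


def waters_near(
    traj: TrajectoryWindow, target_sel: SelectionSpec, cutoff: float = 4.0
) -> WaterCountSeries:
    """Count waters whose O atom is within ``cutoff`` of any target heavy atom."""
    top = traj.topology
    w_rows = _water_rows(traj)
    if w_rows.size == 0:
        raise TopologyError("topology contains no water O atoms")
    target = resolve_selection(
        top,
        SelectionSpec(
            role=target_sel.role, chain=target_sel.chain,
            residue_seq=target_sel.residue_seq, atom_names=target_sel.atom_names,
            heavy_only=True,
        ),
    )
    if target.size == 0:
        raise SelectionError("target selection resolved to no heavy atoms")
    t_rows = top.index_of(target)
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        d = cdist(traj.frames[f, w_rows], traj.frames[f, t_rows])
        counts[f] = int((d.min(axis=1) <= cutoff).sum())
    return WaterCountSeries(counts=counts, cutoff=cutoff, criterion="O within cutoff of target")


def _near_mask(traj: TrajectoryWindow, w_rows: np.ndarray, rows: np.ndarray, cutoff: float) -> np.ndarray:
    mask = np.zeros((traj.n_frames, w_rows.size), dtype=bool)
    for f in range(traj.n_frames):
        d = cdist(traj.frames[f, w_rows], traj.frames[f, rows])
        mask[f] = d.min(axis=1) <= cutoff
    return mask


def bridging_waters(
    traj: TrajectoryWindow,
    ligand_sel: SelectionSpec,
    pocket_sel: SelectionSpec,
    cutoff: float = 4.0,
) -> WaterCountSeries:
    """Count waters in contact with both the ligand and the pocket in a frame."""
    top = traj.topology
    w_rows = _water_rows(traj)
    if w_rows.size == 0:
        raise TopologyError("topology contains no water O atoms")
    lig = resolve_selection(top, SelectionSpec(
        role=ligand_sel.role, chain=ligand_sel.chain, residue_seq=ligand_sel.residue_seq,
        atom_names=ligand_sel.atom_names, heavy_only=True))
    pocket = resolve_selection(top, SelectionSpec(
        role=pocket_sel.role, chain=pocket_sel.chain, residue_seq=pocket_sel.residue_seq,
        atom_names=pocket_sel.atom_names, heavy_only=True))
    if lig.size == 0 or pocket.size == 0:
        raise SelectionError("ligand or pocket selection resolved to no heavy atoms")
    if set(lig.tolist()) & set(pocket.tolist()):
        raise SpecError("ligand and pocket selections overlap")
    near_lig = _near_mask(traj, w_rows, top.index_of(lig), cutoff)
    near_pocket = _near_mask(traj, w_rows, top.index_of(pocket), cutoff)
    counts = (near_lig & near_pocket).sum(axis=1)
    return WaterCountSeries(
        counts=counts, cutoff=cutoff, criterion="O within cutoff of ligand AND pocket"
    )


def water_flux(traj: TrajectoryWindow, upper_z: float, lower_z: float) -> FluxResult:
    """Count full upper↔lower plane traversals per water (hysteresis rule).

    The counter tracks the last plane each water was beyond; a crossing event
    fires only when it reaches beyond the *other* plane.  Planes placed
    entirely outside the sampled z-range raise :class:`SpecError` since no
    crossing is even possible.
    """
    if upper_z <= lower_z:
        raise SpecError("upper_z must exceed lower_z")
    top = traj.topology
    w_rows = _water_rows(traj)
    if w_rows.size == 0:
        raise TopologyError("topology contains no water O atoms")
    z = traj.frames[:, w_rows, 2]   # (n_frames, n_waters)
    if lower_z > z.max() or upper_z < z.min():
        raise SpecError(
            f"planes ({lower_z:g}, {upper_z:g}) lie entirely outside the sampled "
            f"z-range [{z.min():.2f}, {z.max():.2f}]; no crossing is possible"
        )
    per_water: dict[int, tuple[int, int]] = {}
    seqs = [int(top.residue_seq[r]) for r in w_rows]
    for col, seq in enumerate(seqs):
        down = up = 0
        state = 0   # +1 above upper, -1 below lower, 0 not yet beyond any plane
        for zz in z[:, col]:
            region = 1 if zz > upper_z else (-1 if zz < lower_z else 0)
            if region == 0:
                continue
            if state == 1 and region == -1:
                down += 1
            elif state == -1 and region == 1:
                up += 1
            state = region
        per_water[seq] = (down, up)
    return FluxResult(per_water=per_water, upper_z=upper_z, lower_z=lower_z)


def channel_profile(
    traj: TrajectoryWindow,
    axis_origin,
    axis_direction,
    radius: float,
    z_bins: np.ndarray,
) -> ChannelProfile:
    """Bin waters inside a pore cylinder by axial coordinate.

    A frame is flagged continuous iff every bin contains at least one water —
    the per-snapshot reading of a continuous transmembrane water channel.
    """
    axis_origin = np.asarray(axis_origin, dtype=float)
    axis_direction = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(axis_direction)
    if norm < 1e-12:
        raise GeometryError("pore axis direction is a zero vector")
    if radius <= 0:
        raise SpecError("pore radius must be positive")
    z_bins = np.asarray(z_bins, dtype=float)
    if z_bins.size < 3:
        raise SpecError("need at least 2 bins (3 edges)")
    u = axis_direction / norm
    w_rows = _water_rows(traj)
    if w_rows.size == 0:
        raise TopologyError("topology contains no water O atoms")
    n_bins = z_bins.size - 1
    counts = np.zeros((traj.n_frames, n_bins), dtype=int)
    for f in range(traj.n_frames):
        rel = traj.frames[f, w_rows] - axis_origin
        axial = rel @ u
        radial = np.linalg.norm(rel - axial[:, None] * u[None, :], axis=1)
        inside = radial <= radius
        counts[f], _ = np.histogram(axial[inside], bins=z_bins)
    continuous = (counts > 0).all(axis=1)
    return ChannelProfile(bin_edges=z_bins, counts=counts, continuous=continuous)


def suggest_planes(
    traj: TrajectoryWindow, site_sel: SelectionSpec, axis: int = 2
) -> tuple[float, float]:
    """Place flux planes at the 10th/90th axial percentiles of site atoms.

    The upper/lower "ends of the binding pocket" are a free parameter of the
    flux measurement; this helper exposes a reproducible default.
    """
    top = traj.topology
    ids = resolve_selection(top, site_sel)
    if ids.size == 0:
        raise SelectionError("site selection resolved to no atoms")
    rows = top.index_of(ids)
    coords = traj.frames[:, rows, axis].ravel()
    lo, hi = np.percentile(coords, [10, 90])
    return float(hi), float(lo)
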