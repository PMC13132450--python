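"""Synthetic fixtures with planted, recoverable ground truth.

Every generator here is a pure function of its spec (seed included): the same
spec produces bit-identical output.  The generators emulate, at toy scale, the
data a receptor–ligand–water simulation campaign would produce:

* :func:`make_toy_complex` — a rigid cage of single-atom "residues" around a
  five-bead ligand (head bead ``P``, mid beads ``C9``/``C10``, tail anchor
  beads ``C1``/``C2``), with residue–ligand contact occupancies planted
  *exactly* (not Bernoulli-drawn) so contact recovery is sharp;
* :func:`sample_dihedrals` — von Mises rotamer-state mixtures;
* :func:`sample_umbrella_windows` — umbrella-window samples drawn by
  inverse-CDF from the exact biased distribution of a known PMF
  (k = 1.5 kcal/mol/Å², 30 windows at 1 Å spacing, 310 K by default);
* :func:`make_hills` — well-tempered metadynamics hills along a CV path
  (σ = 0.05 nm, bias factor 15 by default), heights stored already tempered;
* :func:`make_water_walk` — water z-walks realising an exact number of full
  upper↔lower traversals under the hysteresis crossing rule.

None of this emulates force-field dynamics, lipid structure, or solvent
correlations beyond what each analysis module needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core_io import Bond, BondOrder, Role, Topology, TrajectoryWindow
from .errors import SpecError
from .free_energy import BOLTZMANN_KCAL, BOLTZMANN_KJ, HillsRecord, UmbrellaWindow

__all__ = [
    "ContactScheduleSpec",
    "DihedralStateSpec",
    "UmbrellaSpec",
    "HillsSpec",
    "WaterFluxSpec",
    "make_toy_complex",
    "sample_dihedrals",
    "sample_umbrella_windows",
    "make_hills",
    "make_water_walk",
    "make_rotamer_trajectory",
    "make_distance_pair_trajectory",
    "make_state_metric_frames",
    "double_well_pmf",
    "default_umbrella_spec",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactScheduleSpec:
    """Planted residue–ligand contact occupancies."""

    pairs: tuple[tuple[int, float], ...]   # (residue_seq, target occupancy in [0, 1])
    n_frames: int
    cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for seq, occ in self.pairs:
            if not 0.0 <= occ <= 1.0:
                raise SpecError(f"occupancy {occ} for residue {seq} outside [0, 1]")
            k = occ * self.n_frames
            if abs(k - round(k)) > 1e-9:
                raise SpecError(
                    f"occupancy {occ} x {self.n_frames} frames is not an integer "
                    f"frame count for residue {seq}"
                )


@dataclass(frozen=True)
class DihedralStateSpec:
    """Mixture of von Mises rotamer states (means in degrees)."""

    components: tuple[tuple[float, float, float], ...]  # (mean_deg, kappa, weight)
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise SpecError(f"component weights sum to {w}, expected 1")
        if any(c[1] < 0 for c in self.components):
            raise SpecError("kappa must be non-negative")


@dataclass(frozen=True)
class UmbrellaSpec:
    """Umbrella windows drawn from a tabulated PMF under harmonic biases."""

    pmf_z: tuple[float, ...]               # grid, Å
    pmf_F: tuple[float, ...]               # kcal/mol
    window_centers: tuple[float, ...]      # Å
    k_bias: float = 1.5                    # kcal/(mol Å^2)
    temperature: float = 310.0             # K
    n_samples_per_window: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pmf_z) != len(self.pmf_F):
            raise SpecError("pmf_z and pmf_F lengths differ")
        if not np.all(np.isfinite(self.pmf_F)):
            raise SpecError("PMF must be finite on its grid")
        sigma = np.sqrt(BOLTZMANN_KCAL * self.temperature / self.k_bias)
        lo, hi = min(self.pmf_z), max(self.pmf_z)
        for c in self.window_centers:
            if c - 3 * sigma < lo or c + 3 * sigma > hi:
                raise SpecError(
                    f"PMF grid [{lo}, {hi}] does not cover window {c} ± 3σ (σ={sigma:.3f})"
                )


@dataclass(frozen=True)
class HillsSpec:
    """Well-tempered hills deposited along an ordered CV path."""

    cv_path: tuple[tuple[float, float], ...]  # (cv1 nm, cv2 degrees)
    sigma: tuple[float, float] = (0.05, 5.0)
    height: float = 1.5
    bias_factor: float = 15.0
    stride: float = 1.0                       # ps
    temperature: float = 310.0
    height_units: str = "kJ/mol"

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise SpecError("bias factor must exceed 1")
        if any(s <= 0 for s in self.sigma):
            raise SpecError("sigma must be positive")
        if self.height_units not in ("kJ/mol", "kcal/mol"):
            raise SpecError(f"unknown height units {self.height_units!r}")


@dataclass(frozen=True)
class WaterFluxSpec:
    """Water z-walks with an exact planted number of full plane traversals."""

    planted_crossings: tuple[int, ...]   # one entry per water
    upper_z: float
    lower_z: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upper_z <= self.lower_z:
            raise SpecError("upper_z must exceed lower_z")
        for i, c in enumerate(self.planted_crossings):
            if c < 0:
                raise SpecError("planted crossings must be non-negative")
            if self.n_frames < 2 * (c + 1):
                raise SpecError(
                    f"{c} crossings for water {i} not achievable in {self.n_frames} frames"
                )


# ---------------------------------------------------------------------------
# Toy receptor–ligand complex
# ---------------------------------------------------------------------------

_LIGAND_ATOMS = ["P", "C9", "C10", "C1", "C2"]
_SHAPE_ALPHA = {"U": 60.0, "L": 75.0, "extended": 180.0}


def _ligand_coords(alpha_deg: float) -> np.ndarray:
    """Five-bead ligand with the planted internal angle at the mid vertex.

    The mid beads C9/C10 straddle the origin (their midpoint is the angle
    vertex), the head bead P sits 6 Å along +x, and the tail anchors C1/C2
    straddle a point 6 Å away at the requested angle.
    """
    a = np.radians(alpha_deg)
    head = np.array([6.0, 0.0, 0.0])
    tail_mid = 6.0 * np.array([np.cos(a), np.sin(a), 0.0])
    return np.array(
        [
            head,
            [0.0, 0.0, 0.5],     # C9
            [0.0, 0.0, -0.5],    # C10
            tail_mid + [0.0, 0.0, 0.5],   # C1
            tail_mid + [0.0, 0.0, -0.5],  # C2
        ]
    )


def build_complex_topology(
    residue_seqs: Sequence[int], n_waters: int = 0
) -> Topology:
    """One-atom-per-residue receptor cage + five-bead ligand (+ optional waters)."""
    ids, names, elements, seqs, resnames, chains, roles = [], [], [], [], [], [], []
    aid = 1
    for seq in residue_seqs:
        ids.append(aid); aid += 1
        names.append("CA"); elements.append("C")
        seqs.append(seq); resnames.append("GLY"); chains.append("R")
        roles.append(Role.RECEPTOR)
    for name in _LIGAND_ATOMS:
        ids.append(aid); aid += 1
        names.append(name)
        elements.append("P" if name == "P" else "C")
        seqs.append(900); resnames.append("LPA"); chains.append("L")
        roles.append(Role.LIGAND)
    for w in range(n_waters):
        ids.append(aid); aid += 1
        names.append("O"); elements.append("O")
        seqs.append(1000 + w); resnames.append("HOH"); chains.append("W")
        roles.append(Role.WATER)
    return Topology(
        atom_ids=np.array(ids), atom_names=names, elements=elements,
        residue_seq=np.array(seqs), residue_names=resnames, chain_ids=chains,
        roles=roles,
    )


def make_toy_complex(
    schedule: ContactScheduleSpec,
    ligand_shape: str = "U",
    decoy_residues: Sequence[int] = (),
) -> TrajectoryWindow:
    """Build a trajectory whose residue–ligand contact occupancies are exact.

    Scheduled residues toggle between an "in" position (``cutoff - 1`` Å from
    the ligand head bead) in exactly ``occupancy * n_frames`` seeded-random
    frames and an "out" position whose nearest ligand atom is farther than
    ``cutoff + 2`` Å; ``decoy_residues`` stay out in every frame.
    """
    if ligand_shape not in _SHAPE_ALPHA:
        raise SpecError(f"unknown ligand shape {ligand_shape!r}")
    rng = np.random.default_rng(schedule.seed)
    scheduled = [seq for seq, _ in schedule.pairs]
    residues = list(scheduled) + [s for s in decoy_residues if s not in scheduled]
    top = build_complex_topology(residues)
    ligand_xyz = _ligand_coords(_SHAPE_ALPHA[ligand_shape])
    head = ligand_xyz[0]

    n = schedule.n_frames
    d_in = schedule.cutoff - 1.0
    d_out = schedule.cutoff + 15.0  # nearest ligand atom stays > cutoff + 2 Å
    frames = np.zeros((n, top.n_atoms, 3))
    n_res = len(residues)
    lig_rows = slice(n_res, n_res + len(_LIGAND_ATOMS))
    frames[:, lig_rows, :] = ligand_xyz

    occupancy = dict(schedule.pairs)
    for row, seq in enumerate(residues):
        psi = 2 * np.pi * row / max(n_res, 1)
        u = np.array([1.0, 0.3 * np.sin(psi), 0.3 * np.cos(psi)])
        u /= np.linalg.norm(u)
        occ = occupancy.get(seq, 0.0)
        k = int(round(occ * n))
        in_frames = np.zeros(n, dtype=bool)
        if k:
            in_frames[rng.choice(n, size=k, replace=False)] = True
        jitter = rng.uniform(-0.3, 0.3, size=n)
        dist = np.where(in_frames, d_in, d_out) + jitter
        frames[:, row, :] = head + dist[:, None] * u
    times = 10.0 * np.arange(n, dtype=float)  # saved every 10 ps
    return TrajectoryWindow(topology=top, frames=frames, frame_times=times)


# ---------------------------------------------------------------------------
# Dihedral mixtures
# ---------------------------------------------------------------------------

def sample_dihedrals(spec: DihedralStateSpec) -> np.ndarray:
    """Sample angles (degrees, wrapped to (-180, 180]) from a von Mises mixture."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[2] for c in spec.components])
    choice = rng.choice(len(spec.components), size=spec.n_samples, p=weights)
    out = np.empty(spec.n_samples)
    for i, (mean, kappa, _) in enumerate(spec.components):
        m = choice == i
        if not m.any():
            continue
        if kappa == 0:
            draws = rng.uniform(-np.pi, np.pi, size=m.sum())
        else:
            draws = rng.vonmises(np.radians(mean), kappa, size=m.sum())
        out[m] = np.degrees(draws)
    # wrap to (-180, 180]
    out = ((out + 180.0) % 360.0) - 180.0
    out[out == -180.0] = 180.0
    return out


# ---------------------------------------------------------------------------
# Umbrella windows from a known PMF
# ---------------------------------------------------------------------------

def sample_umbrella_windows(spec: UmbrellaSpec) -> list[UmbrellaWindow]:
    """Draw window samples from ``p_i(z) ∝ exp(-[F(z) + k/2 (z - z_i)^2]/RT)``.

    Sampling is inverse-CDF on a fine grid, so the draws follow the exact
    biased distribution up to grid resolution (0.01 Å).
    """
    RT = BOLTZMANN_KCAL * spec.temperature
    z_grid = np.asarray(spec.pmf_z, dtype=float)
    F_grid = np.asarray(spec.pmf_F, dtype=float)
    zf = np.arange(z_grid.min(), z_grid.max() + 1e-9, 0.01)
    Ff = np.interp(zf, z_grid, F_grid)
    rng = np.random.default_rng(spec.seed)

    windows = []
    for center in spec.window_centers:
        logp = -(Ff + 0.5 * spec.k_bias * (zf - center) ** 2) / RT
        p = np.exp(logp - logp.max())
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        u = rng.random(spec.n_samples_per_window)
        samples = np.interp(u, cdf, zf)
        windows.append(
            UmbrellaWindow(
                center=center, k_bias=spec.k_bias, samples=samples,
                temperature=spec.temperature,
            )
        )
    return windows


def double_well_pmf() -> tuple[np.ndarray, np.ndarray]:
    """Tabulated membrane-partitioning PMF used as planted ground truth.

    Monotone-spline (PCHIP) curve with an aqueous plateau at 0 (z >= 26 Å), a
    single well of depth -9 kcal/mol at z = 15 Å, and a barrier rising to
    +2 kcal/mol at the bilayer center z = 0, i.e. planted descriptors
    dG_partitioning = -9 and dG_crossing = 11 kcal/mol.  PCHIP through
    monotone control runs guarantees no overshoot, so the planted extrema are
    exact by construction.
    """
    knots_z = np.array([-3.0, 0.0, 4.0, 8.0, 12.0, 15.0, 18.0, 21.0, 24.0, 26.0, 29.0, 32.0])
    knots_F = np.array([2.0, 2.0, 0.0, -3.5, -7.5, -9.0, -7.0, -3.0, -0.8, 0.0, 0.0, 0.0])
    z = np.arange(-3.0, 32.0 + 1e-9, 0.05)
    F = PchipInterpolator(knots_z, knots_F)(z)
    return z, F


def default_umbrella_spec(seed: int = 0, n_samples: int = 10_000) -> UmbrellaSpec:
    """30 windows at 1 Å spacing, k = 1.5 kcal/(mol Å²), 310 K, double-well PMF."""
    z, F = double_well_pmf()
    return UmbrellaSpec(
        pmf_z=tuple(z), pmf_F=tuple(F),
        window_centers=tuple(float(c) for c in range(30)),
        k_bias=1.5, temperature=310.0,
        n_samples_per_window=n_samples, seed=seed,
    )


# ---------------------------------------------------------------------------
# Well-tempered hills
# ---------------------------------------------------------------------------

def make_hills(spec: HillsSpec) -> list[HillsRecord]:
    """Deposit hills along the CV path with well-tempered height damping.

    Each deposited height is ``H0 * exp(-V(s_k)/((γ-1) RT))`` where ``V`` is
    the bias accumulated from the previously deposited (already scaled)
    hills, evaluated at the deposition point — the convention PLUMED uses
    when writing HILLS files.
    """
    kB = BOLTZMANN_KJ if spec.height_units == "kJ/mol" else BOLTZMANN_KCAL
    RT = kB * spec.temperature
    s1, s2 = spec.sigma
    records: list[HillsRecord] = []
    centers: list[tuple[float, float]] = []
    heights: list[float] = []
    for k, (c1, c2) in enumerate(spec.cv_path):
        v = 0.0
        for (p1, p2), h in zip(centers, heights):
            v += h * np.exp(-((c1 - p1) ** 2) / (2 * s1**2) - ((c2 - p2) ** 2) / (2 * s2**2))
        h_k = spec.height * np.exp(-v / ((spec.bias_factor - 1.0) * RT))
        records.append(
            HillsRecord(
                time=k * spec.stride, cv1=c1, cv2=c2,
                sigma_cv1=s1, sigma_cv2=s2, height=h_k,
                bias_factor=spec.bias_factor,
            )
        )
        centers.append((c1, c2))
        heights.append(h_k)
    return records


# ---------------------------------------------------------------------------
# Water walks
# ---------------------------------------------------------------------------

def make_water_walk(spec: WaterFluxSpec) -> TrajectoryWindow:
    """Build water z-paths realising exactly the planted traversal counts.

    Waters with ``c`` crossings interpolate between ``c + 1`` alternating
    stations beyond the two planes; waters with 0 crossings dip into the
    inter-plane slab and return, which the hysteresis rule must not count.
    Small seeded jitter (bounded well below the plane margin) is added so
    the paths are not exactly piecewise linear.
    """
    rng = np.random.default_rng(spec.seed)
    n_w = len(spec.planted_crossings)
    margin = 2.0
    above = spec.upper_z + margin
    below = spec.lower_z - margin
    mid = 0.5 * (spec.upper_z + spec.lower_z)
    n = spec.n_frames

    top = build_complex_topology([], n_waters=n_w)
    # topology contains the 5 ligand beads before waters; park the ligand far away
    frames = np.zeros((n, top.n_atoms, 3))
    frames[:, :5, :] = _ligand_coords(180.0) + np.array([500.0, 500.0, 500.0])

    jitter_amp = min(0.2, (spec.upper_z - spec.lower_z) / 10.0)
    for w, c in enumerate(spec.planted_crossings):
        if c == 0:
            stations = np.array([above, mid, above])
        else:
            stations = np.array([above if i % 2 == 0 else below for i in range(c + 1)])
        idx = np.linspace(0, n - 1, len(stations))
        z = np.interp(np.arange(n), idx, stations)
        z += rng.uniform(-jitter_amp, jitter_amp, size=n)
        col = 5 + w
        frames[:, col, 0] = 10.0 * w + rng.normal(0, 0.5, size=n)
        frames[:, col, 1] = rng.normal(0, 0.5, size=n)
        frames[:, col, 2] = z
    times = 10.0 * np.arange(n, dtype=float)
    return TrajectoryWindow(topology=top, frames=frames, frame_times=times)


# ---------------------------------------------------------------------------
# Small targeted fixtures
# ---------------------------------------------------------------------------

def make_rotamer_trajectory(
    chi2_deg: Sequence[float], residue_seq: int = 210, residue_name: str = "TRP"
) -> TrajectoryWindow:
    """Single aromatic residue whose χ2 torsion equals the given series exactly.

    CD1 is rotated about the CB–CG axis; by construction the IUPAC torsion
    over CA–CB–CG–CD1 equals the requested angle frame by frame.
    """
    angles = np.asarray(chi2_deg, dtype=float)
    names = ["CA", "CB", "CG", "CD1" if residue_name != "PRO" else "CD"]
    top = Topology(
        atom_ids=np.arange(1, 5),
        atom_names=names,
        elements=["C"] * 4,
        residue_seq=np.full(4, residue_seq),
        residue_names=[residue_name] * 4,
        chain_ids=["R"] * 4,
        roles=[Role.RECEPTOR] * 4,
    )
    ca = np.array([-0.5, 1.4, 0.0])
    cb = np.zeros(3)
    cg = np.array([1.5, 0.0, 0.0])
    frames = np.zeros((len(angles), 4, 3))
    theta = np.radians(angles)
    frames[:, 0] = ca
    frames[:, 1] = cb
    frames[:, 2] = cg
    frames[:, 3, 0] = cg[0] + 0.5
    frames[:, 3, 1] = 1.3 * np.cos(theta)
    frames[:, 3, 2] = 1.3 * np.sin(theta)
    return TrajectoryWindow(
        topology=top, frames=frames, frame_times=10.0 * np.arange(len(angles))
    )


def make_distance_pair_trajectory(
    distances: Sequence[float],
    seq_a: int = 142,
    seq_b: int = 260,
    shared_drift: float = 0.0,
) -> TrajectoryWindow:
    """Two single-atom residues separated by the given distance in each frame.

    ``shared_drift`` superimposes a common sinusoidal x-motion on both
    residues so that displacement correlations are defined (a rigidly fixed
    residue has zero variance and no correlation).
    """
    d = np.asarray(distances, dtype=float)
    top = Topology(
        atom_ids=np.array([1, 2]),
        atom_names=["CA", "CA"],
        elements=["C", "C"],
        residue_seq=np.array([seq_a, seq_b]),
        residue_names=["ILE", "VAL"],
        chain_ids=["R", "R"],
        roles=[Role.RECEPTOR, Role.RECEPTOR],
    )
    frames = np.zeros((len(d), 2, 3))
    drift = shared_drift * np.sin(2 * np.pi * np.arange(len(d)) / max(len(d), 1))
    frames[:, 0, 0] = drift
    frames[:, 1, 0] = drift + d
    return TrajectoryWindow(
        topology=top, frames=frames, frame_times=10.0 * np.arange(len(d))
    )


def make_state_metric_frames(
    n_frames: int,
    fraction_active: float,
    references: dict[str, tuple[float, float]],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-frame metric values planted exactly at active/inactive references.

    ``fraction_active * n_frames`` must be an integer; the active frames are a
    seeded-random subset, every metric sits exactly on its reference value.
    """
    k = fraction_active * n_frames
    if abs(k - round(k)) > 1e-9:
        raise SpecError("fraction_active x n_frames must be an integer")
    rng = np.random.default_rng(seed)
    active = np.zeros(n_frames, dtype=bool)
    active[rng.choice(n_frames, size=int(round(k)), replace=False)] = True
    return {
        label: np.where(active, act, inact)
        for label, (act, inact) in references.items()
    }
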