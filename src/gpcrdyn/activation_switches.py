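"""Activation-switch metrics: interhelical distances, side-chain χ2 rotamer
series with circular statistics, 2D kernel-density summaries, and per-frame
classification against active/inactive reference values.

The χ2 torsion distinguishes rotamer states of the aromatic microswitch
residues (CWxP, PIF, NPxxY motifs); interhelical distances between the
intracellular ends of TM3, TM6 and TM7 report the outward TM6 / inward TM7
motion that opens the G-protein coupling cavity.  Angle summaries use
circular statistics (correct near ±180°, and indistinguishable from the
arithmetic mean for concentrated distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean, circstd, gaussian_kde

from .contacts import DistanceSeries, load_presets, min_distance_series
from .core_io import (
    GenericNumberingMap,
    SelectionSpec,
    TrajectoryWindow,
)
from .errors import (
    ClassificationError,
    DegenerateDensityError,
    GeometryError,
    MappingError,
    TopologyError,
)

__all__ = [
    "CHI2_QUARTETS",
    "DihedralSeries",
    "StateReference",
    "Density2D",
    "dihedral",
    "chi2_series",
    "activation_distances",
    "density2d",
    "classify_state",
]

#: χ2 atom quartets by residue type (IUPAC side-chain torsion definitions)
CHI2_QUARTETS: dict[str, tuple[str, str, str, str]] = {
    "TRP": ("CA", "CB", "CG", "CD1"),
    "PHE": ("CA", "CB", "CG", "CD1"),
    "TYR": ("CA", "CB", "CG", "CD1"),
    "HIS": ("CA", "CB", "CG", "ND1"),
    "LEU": ("CA", "CB", "CG", "CD1"),
    "PRO": ("CA", "CB", "CG", "CD"),
    "MET": ("CA", "CB", "CG", "SD"),
    "GLU": ("CA", "CB", "CG", "CD"),
    "GLN": ("CA", "CB", "CG", "CD"),
    "ARG": ("CA", "CB", "CG", "CD"),
    "LYS": ("CA", "CB", "CG", "CD"),
    "ILE": ("CA", "CB", "CG1", "CD1"),
    "ASP": ("CA", "CB", "CG", "OD1"),
    "ASN": ("CA", "CB", "CG", "OD1"),
}


@dataclass
class DihedralSeries:
    """Per-frame side-chain torsion in degrees, wrapped to (-180, 180]."""

    residue_seq: int
    chi_index: int
    atom_names: tuple[str, str, str, str]
    values: np.ndarray

    def circular_mean(self) -> float:
        return float(circmean(self.values, high=180.0, low=-180.0))

    def circular_sd(self) -> float:
        return float(circstd(self.values, high=180.0, low=-180.0))


@dataclass
class StateReference:
    """Active/inactive reference values per metric, with source-structure tags.

    ``kinds`` records whether a metric is a distance (Å, linear tolerance) or
    an angle (degrees, circular tolerance).
    """

    values: dict[str, tuple[float, float]]   # label -> (active, inactive)
    kinds: dict[str, str] = field(default_factory=dict)  # label -> "distance"|"angle"
    sources: dict[str, str] = field(default_factory=dict)  # e.g. "7TD1"/"4Z34"

    def kind(self, label: str) -> str:
        return self.kinds.get(label, "distance")


@dataclass
class Density2D:
    """Gaussian-kernel density on a regular (d1, d2) grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray        # (nx, ny), integrates to ~1 over the grid
    bandwidth: tuple[float, float]

    def integral(self) -> float:
        return float(
            np.trapezoid(np.trapezoid(self.density, self.grid_y, axis=1), self.grid_x)
        )

    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.grid_x[i]), float(self.grid_y[j])

    def local_modes(self, rel_threshold: float = 0.05) -> list[tuple[float, float]]:
        """Grid points that dominate their 8-neighbourhood, above a floor."""
        d = self.density
        floor = rel_threshold * d.max()
        pad = np.pad(d, 1, constant_values=-np.inf)
        out = []
        for i in range(d.shape[0]):
            for j in range(d.shape[1]):
                window = pad[i : i + 3, j : j + 3]
                if d[i, j] >= floor and d[i, j] == window.max() and (window < d[i, j]).sum() >= 7:
                    out.append((float(self.grid_x[i]), float(self.grid_y[j])))
        return out


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle (degrees in (-180, 180]) of four points.

    Computed with the atan2 form: the angle between the two bond planes,
    signed by the right-hand rule about the central bond.  Collinear central
    geometry raises :class:`GeometryError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("degenerate quartet: collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def _dihedral_frames(frames: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Vectorised torsion over all frames for one atom quartet."""
    p = frames[:, rows, :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2, axis=1)
    if np.any(norm_b2 < 1e-12) or np.any(np.linalg.norm(n1, axis=1) < 1e-10) or np.any(
        np.linalg.norm(n2, axis=1) < 1e-10
    ):
        raise GeometryError("degenerate quartet geometry in at least one frame")
    x = (n1 * n2).sum(axis=1)
    y = (np.cross(n1, n2) * b2).sum(axis=1) / norm_b2
    angle = np.degrees(np.arctan2(y, x))
    angle[angle <= -180.0] += 360.0
    return angle


def chi2_series(traj: TrajectoryWindow, residue_seq: int) -> DihedralSeries:
    """Per-frame χ2 torsion of one residue using its residue-type quartet."""
    top = traj.topology
    res_rows = np.nonzero(top.residue_seq == residue_seq)[0]
    if res_rows.size == 0:
        raise TopologyError(f"residue {residue_seq} not in topology")
    resname = top.residue_names[res_rows[0]].upper()
    if resname not in CHI2_QUARTETS:
        raise TopologyError(f"no χ2 quartet defined for residue type {resname!r}")
    quartet = CHI2_QUARTETS[resname]
    rows = []
    for name in quartet:
        hit = [r for r in res_rows if top.atom_names[r].upper() == name]
        if not hit:
            raise TopologyError(f"residue {residue_seq} ({resname}) misses atom {name!r}")
        rows.append(hit[0])
    values = _dihedral_frames(traj.frames, np.array(rows))
    return DihedralSeries(
        residue_seq=residue_seq, chi_index=2, atom_names=quartet, values=values
    )


# ---------------------------------------------------------------------------
# Interhelical distances
# ---------------------------------------------------------------------------

def activation_distances(
    traj: TrajectoryWindow,
    numbering: GenericNumberingMap,
    pairs: list[tuple[str, str, str]] | None = None,
) -> list[DistanceSeries]:
    """Min heavy-atom distance series for the activation-switch label pairs.

    Defaults to the packaged preset (TM3–TM6, TM3–TM7, TM1–TM7, the 3.49–3.50
    ionic lock, 6.33–3.50, and the CWxP 6.48–3.36 alkyl-π pair).  ``pairs``
    may override with ``(label_a, label_b, name)`` triples.
    """
    if pairs is None:
        preset = load_presets()["activation_switches"]
        pairs = [(p["a_label"], p["b_label"], p["name"]) for p in preset]
    series = []
    for label_a, label_b, name in pairs:
        chain_a, seq_a = numbering.residue_for(label_a)
        chain_b, seq_b = numbering.residue_for(label_b)
        sel_a = SelectionSpec(chain=chain_a, residue_seq=frozenset({seq_a}), heavy_only=True)
        sel_b = SelectionSpec(chain=chain_b, residue_seq=frozenset({seq_b}), heavy_only=True)
        series.append(min_distance_series(traj, sel_a, sel_b, label=name))
    return series


# ---------------------------------------------------------------------------
# Kernel densities
# ---------------------------------------------------------------------------

def density2d(
    d1: DistanceSeries, d2: DistanceSeries, grid_points: int = 101
) -> Density2D:
    """Gaussian KDE of two distance series on a regular grid.

    Bandwidth is Scott's rule per dimension (recorded in the result); the grid
    spans the data ± 3 bandwidths.  Zero variance in both dimensions raises
    :class:`DegenerateDensityError`.
    """
    x, y = d1.values, d2.values
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("series must have equal length >= 2")
    if np.std(x) == 0 and np.std(y) == 0:
        raise DegenerateDensityError("both dimensions have zero variance")
    data = np.vstack([x, y])
    kde = gaussian_kde(data, bw_method="scott")
    bw = np.sqrt(np.diag(kde.covariance))
    gx = np.linspace(x.min() - 3 * bw[0], x.max() + 3 * bw[0], grid_points)
    gy = np.linspace(y.min() - 3 * bw[1], y.max() + 3 * bw[1], grid_points)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(GX.shape)
    return Density2D(grid_x=gx, grid_y=gy, density=dens, bandwidth=(float(bw[0]), float(bw[1])))


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

def _circular_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(((a - b) + 180.0) % 360.0 - 180.0)
    return d


def classify_state(
    frame_metrics: dict[str, np.ndarray],
    reference: StateReference,
    tolerances: dict[str, float] | None = None,
    distance_tolerance: float = 1.5,
    angle_tolerance: float = 30.0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Classify each frame as active-like / inactive-like / intermediate.

    A frame is active-like iff *every* metric lies within its tolerance of the
    active reference (circular distance for angles); inactive-like iff every
    metric is within tolerance of the inactive reference and the frame is not
    active-like; anything else is intermediate.  Active-likeness is decided
    independently of the inactive test so that tightening tolerances can only
    shrink the active-like population.  Returns the per-frame label array and
    the population fractions (which sum to 1).
    """
    missing = [m for m in reference.values if m not in frame_metrics]
    if missing:
        raise ClassificationError(f"metrics missing from input: {missing}")
    labels_all = list(reference.values)
    n = len(next(iter(frame_metrics.values())))
    near_active = np.ones(n, dtype=bool)
    near_inactive = np.ones(n, dtype=bool)
    for label in labels_all:
        series = np.asarray(frame_metrics[label], dtype=float)
        active_ref, inactive_ref = reference.values[label]
        kind = reference.kind(label)
        if tolerances and label in tolerances:
            tol = tolerances[label]
        else:
            tol = angle_tolerance if kind == "angle" else distance_tolerance
        if kind == "angle":
            near_active &= _circular_distance(series, active_ref) <= tol
            near_inactive &= _circular_distance(series, inactive_ref) <= tol
        else:
            near_active &= np.abs(series - active_ref) <= tol
            near_inactive &= np.abs(series - inactive_ref) <= tol

    labels = np.full(n, "intermediate", dtype=object)
    labels[near_active] = "active_like"
    labels[near_inactive & ~near_active] = "inactive_like"
    fractions = {
        state: float((labels == state).mean())
        for state in ("active_like", "inactive_like", "intermediate")
    }
    return labels, fractions
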