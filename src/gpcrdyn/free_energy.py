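"""Free-energy post-processing: WHAM estimation of 1D potentials of mean force
from umbrella-sampling windows, reconstruction of 2D well-tempered
metadynamics free-energy surfaces from deposited hills, membrane-partitioning
descriptors, and minimum-energy path extraction on a 2D grid.

Model summary
-------------
Umbrella sampling biases window *i* with a harmonic restraint
``U_i(z) = k/2 (z - z_i)^2``; WHAM solves the self-consistent equations

    p(z_b) = sum_i h_ib / sum_i N_i exp(beta f_i) exp(-beta U_i(z_b))
    exp(-beta f_i) = sum_b p(z_b) exp(-beta U_i(z_b))

for the unbiased bin probabilities ``p`` and the per-window free-energy
constants ``f_i``; the PMF is ``F = -RT ln p``, anchored so that the mean over
a declared aqueous plateau is zero.

Well-tempered metadynamics deposits Gaussians whose heights shrink by
``exp(-V/( (gamma-1) RT ))``; PLUMED-style HILLS files store the *already
scaled* heights, so the reconstruction here sums the recorded Gaussians into
the bias ``V(s)`` and reports ``F(s) = -(gamma/(gamma-1)) V(s)`` shifted to a
zero minimum.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    ConsistencyError,
    ConvergenceError,
    DegeneratePathError,
    FormatError,
    OverlapError,
    SpecError,
)

__all__ = [
    "BOLTZMANN_KCAL",
    "BOLTZMANN_KJ",
    "UmbrellaWindow",
    "PMFCurve",
    "PartitioningDescriptors",
    "HillsRecord",
    "FES2D",
    "wham",
    "pmf_descriptors",
    "metad_fes",
    "min_energy_path",
    "read_hills",
    "write_hills",
    "read_umbrella_windows",
    "write_umbrella_windows",
]

#: Boltzmann constant in kcal/(mol K); RT(310 K) = 0.616 kcal/mol
BOLTZMANN_KCAL = 0.0019872041
#: Boltzmann constant in kJ/(mol K)
BOLTZMANN_KJ = 0.0083144621


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate from one harmonically biased window."""

    center: float            # z_i, Å
    k_bias: float            # kcal/(mol Å^2)
    samples: np.ndarray      # z values, Å
    temperature: float       # K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise SpecError("umbrella window needs at least one sample")
        if self.k_bias <= 0:
            raise SpecError("k_bias must be positive")


@dataclass
class PMFCurve:
    """1D potential of mean force on a regular grid (kcal/mol)."""

    z: np.ndarray
    F: np.ndarray
    anchor: str = "min"
    uncertainty: np.ndarray | None = None

    def shifted(self, offset: float) -> "PMFCurve":
        return PMFCurve(z=self.z.copy(), F=self.F - offset, anchor=self.anchor)

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.z, self.F])
        np.savetxt(path, arr, header="z_angstrom,F_kcal_per_mol", delimiter=",", comments="")


@dataclass
class PartitioningDescriptors:
    """Scalar summaries of a membrane-partitioning PMF.

    ``dG_partitioning`` is the PMF value at the global minimum relative to the
    aqueous plateau (water -> membrane transfer); ``dG_crossing`` is the
    highest barrier between that minimum and the bilayer center, relative to
    the minimum; ``accessible_halfwidth`` is the half-extent of the region
    within RT of the minimum.
    """

    dG_partitioning: float
    dG_crossing: float
    z_min: float
    accessible_halfwidth: float
    RT: float


@dataclass(frozen=True)
class HillsRecord:
    """One deposited metadynamics Gaussian (heights stored already tempered)."""

    time: float          # ps
    cv1: float           # nm (ligand-site COM distance)
    cv2: float           # degrees (ligand internal angle alpha)
    sigma_cv1: float
    sigma_cv2: float
    height: float        # in the declared energy units
    bias_factor: float


@dataclass
class FES2D:
    """2D free-energy surface on a regular (cv1, cv2) grid."""

    cv1: np.ndarray              # (n1,)
    cv2: np.ndarray              # (n2,)
    F: np.ndarray                # (n1, n2)
    height_units: str = "kJ/mol"
    bias_factor: float | None = None

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i, a in enumerate(self.cv1):
            for j, b in enumerate(self.cv2):
                rows.append((a, b, self.F[i, j]))
        np.savetxt(
            path, np.asarray(rows),
            header="cv1,cv2,F", delimiter=",", comments="",
        )


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.2,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    plateau: tuple[float, float] | None = None,
) -> PMFCurve:
    """Estimate the unbiased PMF from harmonically biased umbrella windows.

    Iterates the WHAM self-consistency equations until the per-window
    free-energy constants change by less than ``tol`` (kcal/mol).  Adjacent
    windows (ordered by center) must have overlapping sampled histograms;
    a gap raises :class:`OverlapError` naming the two centers.  When a
    ``plateau`` z-range is given the PMF mean over it is anchored to zero,
    otherwise the minimum is anchored to zero.
    """
    if not windows:
        raise SpecError("wham requires at least one window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise SpecError(f"windows mix temperatures: {sorted(temps)}")
    RT = BOLTZMANN_KCAL * windows[0].temperature
    beta = 1.0 / RT

    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    hist = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    counts = np.array([w.samples.size for w in windows], dtype=float)

    # adjacent-window overlap diagnostic
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        occ_a = np.nonzero(hist[a])[0]
        occ_b = np.nonzero(hist[b])[0]
        if occ_a.size and occ_b.size and (occ_a.max() < occ_b.min() - 1 or occ_b.max() < occ_a.min() - 1):
            raise OverlapError(
                "no histogram overlap between windows centered at "
                f"{windows[a].center:g} and {windows[b].center:g} Å"
            )

    bias = np.stack([0.5 * w.k_bias * (centers - w.center) ** 2 for w in windows])
    A = np.exp(-beta * bias)                      # (n_windows, n_bins)
    H = hist.sum(axis=0).astype(float)            # (n_bins,)

    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (counts * np.exp(beta * f)) @ A   # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, H / denom, 0.0)
        z_i = A @ p                               # exp(-beta f_new)
        f_new = -RT * np.log(z_i)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations", residual=residual
        )

    sampled = H > 0
    with np.errstate(divide="ignore"):
        F = np.where(sampled, -RT * np.log(np.where(sampled, p, 1.0)), np.nan)
    z = centers[sampled]
    F = F[sampled]

    if plateau is not None:
        mask = (z >= plateau[0]) & (z <= plateau[1])
        if not mask.any():
            raise SpecError(f"plateau range {plateau} contains no sampled bins")
        F = F - F[mask].mean()
        anchor = f"plateau mean over {plateau} = 0"
    else:
        F = F - F.min()
        anchor = "min = 0"
    return PMFCurve(z=z, F=F, anchor=anchor)


def pmf_descriptors(
    pmf: PMFCurve,
    temperature: float,
    plateau: tuple[float, float],
    center_z: float = 0.0,
) -> PartitioningDescriptors:
    """Extract membrane-partitioning descriptors from a PMF.

    The curve is re-anchored so the mean over the aqueous ``plateau`` range is
    zero (making the result invariant under constant shifts of ``F``), the
    global-minimum position is refined parabolically, and the crossing barrier
    is measured between the minimum and the bilayer center ``center_z``.
    """
    z = np.asarray(pmf.z, dtype=float)
    F = np.asarray(pmf.F, dtype=float)
    RT = BOLTZMANN_KCAL * temperature

    mask = (z >= plateau[0]) & (z <= plateau[1])
    if not mask.any():
        raise SpecError(f"plateau range {plateau} lies outside the PMF grid")
    if not (z.min() <= center_z <= z.max()):
        raise SpecError(f"PMF grid does not cover the bilayer center z={center_z:g}")
    F = F - F[mask].mean()

    imin = int(np.argmin(F))
    z_min, F_min = float(z[imin]), float(F[imin])
    if 0 < imin < len(z) - 1:
        # parabolic refinement through the three bins around the minimum
        z3, f3 = z[imin - 1 : imin + 2], F[imin - 1 : imin + 2]
        denom = (z3[0] - z3[1]) * (z3[0] - z3[2]) * (z3[1] - z3[2])
        if abs(denom) > 0:
            a = (z3[2] * (f3[1] - f3[0]) + z3[1] * (f3[0] - f3[2]) + z3[0] * (f3[2] - f3[1])) / denom
            b = (z3[2] ** 2 * (f3[0] - f3[1]) + z3[1] ** 2 * (f3[2] - f3[0]) + z3[0] ** 2 * (f3[1] - f3[2])) / denom
            if a > 0:
                z_ref = -b / (2 * a)
                if z3[0] <= z_ref <= z3[2]:
                    c = f3[0] - a * z3[0] ** 2 - b * z3[0]
                    z_min = float(z_ref)
                    F_min = float(a * z_ref**2 + b * z_ref + c)

    span = (min(z_min, center_z), max(z_min, center_z))
    # include bins within half a grid step of the interval ends so that an
    # extremum sitting exactly at an endpoint is not lost to float round-off
    half_step = 0.5 * float(np.median(np.diff(z))) if len(z) > 1 else 0.0
    on_path = (z >= span[0] - half_step) & (z <= span[1] + half_step)
    dG_crossing = float(F[on_path].max() - F_min) if on_path.any() else 0.0

    # thermally accessible region: contiguous span around the minimum with F <= F_min + RT
    thr = F_min + RT
    i = imin
    while i > 0 and F[i - 1] <= thr:
        i -= 1
    if i > 0 and F[i - 1] > F[i]:  # interpolate the left crossing of the RT level
        lo_z = float(z[i] - (z[i] - z[i - 1]) * (thr - F[i]) / (F[i - 1] - F[i]))
    else:
        lo_z = float(z[i])
    j = imin
    while j < len(z) - 1 and F[j + 1] <= thr:
        j += 1
    if j < len(z) - 1 and F[j + 1] > F[j]:
        hi_z = float(z[j] + (z[j + 1] - z[j]) * (thr - F[j]) / (F[j + 1] - F[j]))
    else:
        hi_z = float(z[j])

    return PartitioningDescriptors(
        dG_partitioning=F_min,
        dG_crossing=max(dG_crossing, 0.0),
        z_min=z_min,
        accessible_halfwidth=max((hi_z - lo_z) / 2.0, 0.0),
        RT=RT,
    )


# ---------------------------------------------------------------------------
# Well-tempered metadynamics FES
# ---------------------------------------------------------------------------

_HILLS_FIELDS = ["time", "cv1", "cv2", "sigma_cv1", "sigma_cv2", "height", "biasf"]


def write_hills(records: list[HillsRecord], path: str | Path, height_units: str) -> None:
    """Write PLUMED-dialect HILLS text (whitespace table with named header)."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(_HILLS_FIELDS) + "\n")
        fh.write(f"#! SET height_units {height_units}\n")
        for r in records:
            fh.write(
                f"{r.time:.3f} {r.cv1:.6f} {r.cv2:.6f} {r.sigma_cv1:.6f} "
                f"{r.sigma_cv2:.6f} {r.height:.10f} {r.bias_factor:.3f}\n"
            )


def read_hills(path: str | Path, height_units: str) -> list[HillsRecord]:
    """Read a HILLS file; ``height_units`` must be declared by the caller.

    Heights are stored already well-tempered (as deposited) and are *not*
    rescaled on read.  If the file carries its own unit declaration and it
    disagrees with ``height_units`` a :class:`ConsistencyError` is raised.
    """
    records: list[HillsRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "height_units" in line:
                    declared = line.split()[-1]
                    if declared != height_units:
                        raise ConsistencyError(
                            f"file declares heights in {declared!r}, caller expects {height_units!r}"
                        )
                continue
            parts = line.split()
            if len(parts) < 7:
                raise FormatError("hills record needs 7 columns", lineno)
            try:
                t, c1, c2, s1, s2, h, g = (float(p) for p in parts[:7])
            except ValueError:
                raise FormatError("non-numeric hills record", lineno) from None
            records.append(HillsRecord(t, c1, c2, s1, s2, h, g))
    return records


def metad_fes(
    hills: list[HillsRecord],
    cv1_grid: np.ndarray,
    cv2_grid: np.ndarray,
    height_units: str = "kJ/mol",
) -> FES2D:
    """Reconstruct the well-tempered FES from deposited hills.

    The bias is the plain sum of the recorded Gaussians; the free energy is
    ``F = -(gamma/(gamma-1)) V`` shifted so ``min F = 0``.  Mixed bias factors
    raise :class:`ConsistencyError`.
    """
    if not hills:
        raise SpecError("no hills records supplied")
    gammas = {h.bias_factor for h in hills}
    if len(gammas) > 1:
        raise ConsistencyError(f"hills mix bias factors: {sorted(gammas)}")
    gamma = hills[0].bias_factor
    if gamma <= 1:
        raise SpecError("bias factor must exceed 1 for well-tempered metadynamics")

    cv1_grid = np.asarray(cv1_grid, dtype=float)
    cv2_grid = np.asarray(cv2_grid, dtype=float)
    G1, G2 = np.meshgrid(cv1_grid, cv2_grid, indexing="ij")
    V = np.zeros_like(G1)
    for h in hills:
        V += h.height * np.exp(
            -((G1 - h.cv1) ** 2) / (2 * h.sigma_cv1**2)
            - ((G2 - h.cv2) ** 2) / (2 * h.sigma_cv2**2)
        )
    F = -(gamma / (gamma - 1.0)) * V
    F -= F.min()
    return FES2D(cv1=cv1_grid, cv2=cv2_grid, F=F, height_units=height_units, bias_factor=gamma)


# ---------------------------------------------------------------------------
# Minimum-energy path on a 2D grid (minimax criterion)
# ---------------------------------------------------------------------------

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def min_energy_path(
    fes: FES2D, start: tuple[int, int], end: tuple[int, int]
) -> list[tuple[tuple[int, int], float]]:
    """Extract the minimum-energy path between two grid nodes on an FES.

    The path is 8-connected and minimises, in order: (1) the maximum free
    energy along the path (the energetic bottleneck), (2) the summed free
    energy, (3) the number of nodes, (4) lexicographic node order.  For
    determinism the search always
    runs from the lexicographically smaller endpoint and the result is
    reversed if needed, so ``path(a, b)`` equals ``path(b, a)`` reversed.
    Returns ``[(node, F(node)), ...]`` including both endpoints.
    """
    if start == end:
        raise DegeneratePathError("start and end nodes coincide")
    F = fes.F
    n1, n2 = F.shape
    for node in (start, end):
        if not (0 <= node[0] < n1 and 0 <= node[1] < n2):
            raise SpecError(f"node {node} outside the {F.shape} grid")

    flipped = start > end
    s, e = (end, start) if flipped else (start, end)

    # phase 1: bottleneck Dijkstra for the minimal achievable maximum
    best = np.full(F.shape, np.inf)
    best[s] = F[s]
    heap: list[tuple[float, tuple[int, int]]] = [(F[s], s)]
    while heap:
        m, node = heapq.heappop(heap)
        if m > best[node]:
            continue
        if node == e:
            break
        for di, dj in _NEIGHBOURS:
            ni, nj = node[0] + di, node[1] + dj
            if 0 <= ni < n1 and 0 <= nj < n2:
                cand = max(m, F[ni, nj])
                if cand < best[ni, nj]:
                    best[ni, nj] = cand
                    heapq.heappush(heap, (cand, (ni, nj)))
    bottleneck = best[e]
    if not np.isfinite(bottleneck):  # pragma: no cover - grid is always connected
        raise SpecError("no path found on the grid")

    # phase 2: among paths respecting the bottleneck, minimise (sum F, lex)
    allowed = F <= bottleneck + 1e-12
    settled = np.zeros(F.shape, dtype=bool)
    heap2: list[tuple[float, int, tuple[tuple[int, int], ...]]] = [(float(F[s]), 1, (s,))]
    while heap2:
        total, nsteps, path = heapq.heappop(heap2)
        node = path[-1]
        if settled[node]:
            continue
        settled[node] = True
        if node == e:
            out = [(p, float(F[p])) for p in path]
            return out[::-1] if flipped else out
        for di, dj in _NEIGHBOURS:
            ni, nj = node[0] + di, node[1] + dj
            if 0 <= ni < n1 and 0 <= nj < n2 and allowed[ni, nj] and not settled[ni, nj]:
                heapq.heappush(
                    heap2, (total + float(F[ni, nj]), nsteps + 1, path + ((ni, nj),))
                )
    raise SpecError("no path found within the bottleneck level set")  # pragma: no cover


# ---------------------------------------------------------------------------
# Umbrella-window text I/O
# ---------------------------------------------------------------------------

def write_umbrella_windows(windows: list[UmbrellaWindow], directory: str | Path) -> None:
    """Write per-window two-column text (time_ps, z_angstrom) plus metadata YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        t = np.arange(w.samples.size, dtype=float)
        np.savetxt(directory / fname, np.column_stack([t, w.samples]), fmt="%.6f")
        meta.append(
            {"file": fname, "center": float(w.center), "k_bias": float(w.k_bias),
             "temperature": float(w.temperature)}
        )
    with open(directory / "windows.yaml", "w") as fh:
        yaml.safe_dump({"windows": meta}, fh)


def read_umbrella_windows(directory: str | Path) -> list[UmbrellaWindow]:
    directory = Path(directory)
    with open(directory / "windows.yaml") as fh:
        meta = yaml.safe_load(fh)["windows"]
    windows = []
    for m in meta:
        data = np.loadtxt(directory / m["file"])
        samples = np.atleast_2d(data)[:, 1]
        windows.append(
            UmbrellaWindow(
                center=m["center"], k_bias=m["k_bias"], samples=samples,
                temperature=m["temperature"],
            )
        )
    return windows


def descriptors_to_json(desc: PartitioningDescriptors, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "dG_partitioning_kcal_mol": desc.dG_partitioning,
                "dG_crossing_kcal_mol": desc.dG_crossing,
                "z_min_angstrom": desc.z_min,
                "accessible_halfwidth_angstrom": desc.accessible_halfwidth,
                "RT_kcal_mol": desc.RT,
            },
            fh,
            indent=2,
        )
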