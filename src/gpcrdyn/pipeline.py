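"""Pipeline orchestration: configured stages over synthetic fixtures with
deterministic outputs, a manifest of everything written, and a one-command
demonstration that exercises every analysis module against planted ground
truth.

All randomness flows from one top-level seed fanned out per stage, so a
config fully determines the output bytes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    activation_switches as act,
    contacts,
    core_io,
    free_energy as fe,
    ligand_geometry as lig,
    residue_network as net,
    synthetic_data as syn,
    water_channel as wat,
)
from .core_io import GenericNumberingMap, Role, SelectionSpec
from .errors import GpcrDynError

__all__ = ["RunConfig", "RunReport", "StageResult", "run", "demo", "DEFAULT_STAGES"]

DEFAULT_STAGES = ["io", "contacts", "activation", "ligand", "water", "network", "free_energy"]


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the module-level defaults."""

    out_dir: str = "gpcrdyn_out"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in DEFAULT_STAGES}
    )
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        cfg.seed = int(raw.get("seed", cfg.seed))
        stages = {s: False for s in DEFAULT_STAGES}
        stages.update(raw.get("stages", {s: True for s in DEFAULT_STAGES}))
        unknown = set(stages) - set(DEFAULT_STAGES)
        if unknown:
            raise GpcrDynError(f"unknown stages in config: {sorted(unknown)}")
        cfg.stages = stages
        cfg.params = raw.get("params", {})
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"out_dir": self.out_dir, "seed": self.seed, "stages": self.stages,
                 "params": self.params},
                fh,
            )


@dataclass
class StageResult:
    name: str
    status: str                      # "ok" | "failed" | "skipped"
    wall_time_s: float = 0.0
    outputs: list[str] = field(default_factory=list)
    checks: list[dict] = field(default_factory=list)
    error: str = ""


@dataclass
class RunReport:
    config_echo: dict
    stages: list[StageResult] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)   # file -> sha256
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s.status in ("ok", "skipped") for s in self.stages) and all(
            c["passed"] for s in self.stages for c in s.checks
        )

    def failed_checks(self) -> list[str]:
        return [
            f"{s.name}: {c['name']} ({c.get('detail', '')})"
            for s in self.stages
            for c in s.checks
            if not c["passed"]
        ] + [f"{s.name}: stage error: {s.error}" for s in self.stages if s.status == "failed"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config_echo,
            "stages": [
                {
                    "name": s.name, "status": s.status, "wall_time_s": round(s.wall_time_s, 3),
                    "outputs": s.outputs, "checks": s.checks, "error": s.error,
                }
                for s in self.stages
            ],
            "manifest": self.manifest,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check(checks: list, name: str, passed: bool, detail: str = "") -> None:
    checks.append({"name": name, "passed": bool(passed), "detail": detail})


# ---------------------------------------------------------------------------
# Stages (each returns list of written files and appends its checks)
# ---------------------------------------------------------------------------

def _stage_io(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    schedule = syn.ContactScheduleSpec(
        pairs=((124, 0.75), (125, 0.5), (129, 1.0), (210, 0.25), (271, 0.0)),
        n_frames=40, cutoff=4.0, seed=seed,
    )
    traj = syn.make_toy_complex(schedule, ligand_shape="U")
    pdb = out / "toy_complex.pdb"
    dcd = out / "toy_complex.dcd"
    core_io.write_structure(traj, pdb)
    core_io.write_trajectory(traj, dcd)
    top2, single = core_io.read_structure(
        pdb, {"R": Role.RECEPTOR, "L": Role.LIGAND, "W": Role.WATER}
    )
    back = core_io.read_trajectory(top2, dcd)
    _check(
        checks, "pdb_roundtrip_coordinates",
        np.allclose(single.frames[0], np.round(traj.frames[0], 3), atol=5e-4),
    )
    _check(
        checks, "dcd_roundtrip_coordinates",
        back.n_frames == traj.n_frames and np.allclose(back.frames, traj.frames, atol=1e-4),
    )
    nmap = GenericNumberingMap(
        entries={("R", 124): "3.28", ("R", 125): "3.29", ("R", 129): "3.33",
                 ("R", 210): "5.43", ("R", 271): "6.48"}
    )
    map_csv = out / "numbering_map.csv"
    nmap.to_csv(map_csv)
    return [pdb, dcd, map_csv]


def _stage_contacts(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    planted = ((124, 0.75), (125, 0.5), (129, 1.0), (210, 0.25), (271, 0.0))
    schedule = syn.ContactScheduleSpec(pairs=planted, n_frames=40, cutoff=4.0, seed=seed)
    traj = syn.make_toy_complex(schedule, ligand_shape="U")
    cm = contacts.contact_frequency(
        traj, SelectionSpec(role=Role.LIGAND), [p[0] for p in planted], cutoff=4.0
    )
    recovered = dict(zip(cm.residue_seq, cm.frequency))
    _check(
        checks, "planted_contact_occupancy_exact",
        all(recovered[seq] == occ for seq, occ in planted),
        detail=str(recovered),
    )
    csv = out / "contact_frequency.csv"
    contacts.contacts_to_csv(cm, csv, label="toy U-shaped ligand")
    return [csv]


def _stage_activation(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    files = []
    # χ2 rotamer recovery: planted constant active-state angle
    traj = syn.make_rotamer_trajectory(np.full(50, 92.0), residue_seq=210, residue_name="TRP")
    series = act.chi2_series(traj, 210)
    _check(
        checks, "chi2_planted_92deg",
        abs(series.circular_mean() - 92.0) < 1e-6 and series.circular_sd() < 1e-6,
    )
    df = pd.DataFrame({"frame": np.arange(series.values.size), "chi2_deg": series.values})
    f = out / "chi2_W210.csv"
    df.to_csv(f, index=False)
    files.append(f)

    # planted two-cluster interhelical density
    rng = np.random.default_rng(seed + 1)
    d1 = np.concatenate([rng.normal(5.0, 0.15, 300), rng.normal(9.0, 0.15, 300)])
    d2 = np.concatenate([rng.normal(13.0, 0.15, 300), rng.normal(12.0, 0.15, 300)])
    dens = act.density2d(
        contacts.DistanceSeries("TM3-TM7", d1), contacts.DistanceSeries("TM3-TM6", d2)
    )
    modes = dens.local_modes()
    near = lambda m, t: min(np.hypot(m[0] - t[0], m[1] - t[1]) for m in modes) < 0.5
    _check(
        checks, "density_modes_recovered",
        len(modes) >= 2 and near(modes, (5.0, 13.0)) and near(modes, (9.0, 12.0)),
        detail=str(modes),
    )
    grid = pd.DataFrame(
        {"d1": np.repeat(dens.grid_x, dens.grid_y.size),
         "d2": np.tile(dens.grid_y, dens.grid_x.size),
         "density": dens.density.ravel()}
    )
    f = out / "density_tm3tm7_tm3tm6.csv"
    grid.to_csv(f, index=False)
    files.append(f)

    # planted 70/30 state classification
    ref = act.StateReference(
        values={"TM3-TM7": (4.5, 9.0), "chi2_W210": (92.0, -100.0)},
        kinds={"TM3-TM7": "distance", "chi2_W210": "angle"},
    )
    metrics = syn.make_state_metric_frames(40, 0.7, ref.values, seed=seed + 2)
    labels, fractions = act.classify_state(metrics, ref)
    _check(
        checks, "state_populations_70_30",
        fractions["active_like"] == 0.7 and fractions["inactive_like"] == 0.3,
        detail=str(fractions),
    )
    f = out / "state_classification.csv"
    pd.DataFrame({"frame": np.arange(len(labels)), "state": labels}).to_csv(f, index=False)
    files.append(f)
    return files


def _stage_ligand(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    files = []
    schedule = syn.ContactScheduleSpec(pairs=((124, 1.0),), n_frames=10, seed=seed)
    traj = syn.make_toy_complex(schedule, ligand_shape="U")
    alpha = lig.alpha_series(traj)
    _check(checks, "alpha_U_shape_60deg", np.allclose(alpha.values, 60.0, atol=1e-9))

    counts = {s: lig.rotatable_bond_count(lig.lpa_graph(s)) for s in ("18:0", "18:1")}
    _check(
        checks, "rotatable_bonds_22_21",
        counts["18:0"] == 22 and counts["18:1"] == 21, detail=str(counts),
    )
    f = out / "ligand_descriptors.json"
    with open(f, "w") as fh:
        json.dump({"alpha_mean_deg": alpha.mean(), "rotatable_bonds": counts}, fh, indent=2)
    files.append(f)

    # pose clustering on a toy RMSD matrix with two planted basins
    rng = np.random.default_rng(seed + 3)
    n = 12
    basin = np.array([0] * 7 + [1] * 5)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = 1.0 if basin[i] == basin[j] else 8.0
            m[i, j] = m[j, i] = base + rng.uniform(0, 0.2)
    pc = lig.cluster_poses(m, cutoff=3.0)
    members = pc.members(pc.largest_cluster)
    _check(
        checks, "largest_cluster_and_medoid",
        members.size == 7 and pc.medoid_frame in members,
        detail=f"medoid={pc.medoid_frame}",
    )
    f = out / "pose_clusters.csv"
    pd.DataFrame(
        {"frame": np.arange(n), "cluster_id": pc.membership,
         "is_medoid": np.arange(n) == pc.medoid_frame}
    ).to_csv(f, index=False)
    files.append(f)
    return files


def _stage_water(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    spec = syn.WaterFluxSpec(
        planted_crossings=(1, 2, 0, 3, 1, 0), upper_z=10.0, lower_z=-10.0,
        n_frames=120, seed=seed,
    )
    traj = syn.make_water_walk(spec)
    flux = wat.water_flux(traj, spec.upper_z, spec.lower_z)
    _check(
        checks, "planted_flux_total",
        flux.total_events == sum(spec.planted_crossings),
        detail=f"total={flux.total_events}",
    )
    f = out / "water_flux.csv"
    pd.DataFrame(
        [
            {"water": seq, "downward": d, "upward": u}
            for seq, (d, u) in flux.per_water.items()
        ]
    ).to_csv(f, index=False)
    return [f]


def _stage_network(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    # occupancy gate: strictly-over-75% edges only
    import networkx as nx

    n_frames = 100
    t = np.arange(n_frames)
    results = {}
    for occ in (0.74, 0.75, 0.76):
        k_in = int(round(occ * n_frames))
        d = np.full(n_frames, 30.0)
        d[:k_in] = 4.0
        traj = syn.make_distance_pair_trajectory(d, seq_a=1, seq_b=2, shared_drift=0.1)
        g = net.build_graph(traj, [1, 2])
        results[occ] = g.graph.has_edge(1, 2)
    _check(
        checks, "occupancy_gate_strict",
        results == {0.74: False, 0.75: False, 0.76: True},
        detail=str(results),
    )

    # optimal path on a hand-built weighted graph vs exhaustive enumeration
    g = nx.Graph()
    edges = [(1, 2, 0.5), (2, 3, 0.5), (1, 3, 1.5), (3, 4, 0.2), (2, 4, 1.0)]
    for a, b, w in edges:
        g.add_edge(a, b, weight=w, occupancy=1.0, correlation=np.exp(-w))
    rg = net.ResidueGraph(graph=g, contact_cutoff=4.5, occupancy_gate=0.75)
    opt = net.optimal_path(rg, 1, 4)
    brute = min(
        (
            (nx.path_weight(g, p, "weight"), tuple(p))
            for p in nx.all_simple_paths(g, 1, 4)
        ),
    )
    _check(
        checks, "optimal_path_matches_enumeration",
        opt.nodes == brute[1] and abs(opt.length - brute[0]) < 1e-12,
        detail=f"{opt.nodes} len={opt.length:.3f}",
    )
    f = out / "network_paths.json"
    net.paths_to_json(net.suboptimal_paths(rg, 1, 4, tolerance=0.5), f)
    return [f]


def _stage_free_energy(out: Path, seed: int, params: dict, checks: list) -> list[Path]:
    files = []
    n_samples = int(params.get("umbrella_samples_per_window", 4000))
    spec = syn.default_umbrella_spec(seed=seed + 5, n_samples=n_samples)
    windows = syn.sample_umbrella_windows(spec)
    pmf = fe.wham(windows, bin_width=0.2, plateau=(26.0, 29.0))
    z_true, F_true = syn.double_well_pmf()
    F_interp = np.interp(pmf.z, z_true, F_true)
    desc_true = fe.pmf_descriptors(
        fe.PMFCurve(z=z_true, F=F_true), 310.0, plateau=(26.0, 29.0)
    )
    acc = F_interp <= desc_true.dG_partitioning + desc_true.RT
    rms = float(np.sqrt(np.mean((pmf.F[acc] - F_interp[acc]) ** 2)))
    desc = fe.pmf_descriptors(pmf, 310.0, plateau=(26.0, 29.0))
    _check(checks, "wham_rms_accessible_range", rms < 0.25, detail=f"rms={rms:.3f}")
    _check(
        checks, "partitioning_descriptors_recovered",
        abs(desc.dG_partitioning - desc_true.dG_partitioning) < 0.3
        and abs(desc.dG_crossing - desc_true.dG_crossing) < 0.3,
        detail=f"dG_part={desc.dG_partitioning:.2f}, dG_cross={desc.dG_crossing:.2f}",
    )
    f = out / "pmf.csv"
    pmf.to_csv(f)
    files.append(f)
    f = out / "partitioning_descriptors.json"
    fe.descriptors_to_json(desc, f)
    files.append(f)

    # metadynamics FES: closed-form Gaussian sum, prefactor gamma/(gamma-1)
    hills_spec = syn.HillsSpec(
        cv_path=((1.0, 150.0), (0.8, 120.0), (0.6, 90.0)),
        sigma=(0.05, 5.0), height=1.5, bias_factor=15.0,
    )
    records = syn.make_hills(hills_spec)
    cv1 = np.linspace(0.4, 1.2, 41)
    cv2 = np.linspace(60.0, 180.0, 49)
    fes = fe.metad_fes(records, cv1, cv2)
    G1, G2 = np.meshgrid(cv1, cv2, indexing="ij")
    V = np.zeros_like(G1)
    for r in records:
        V += r.height * np.exp(
            -((G1 - r.cv1) ** 2) / (2 * r.sigma_cv1**2)
            - ((G2 - r.cv2) ** 2) / (2 * r.sigma_cv2**2)
        )
    F_ref = -(15.0 / 14.0) * V
    F_ref -= F_ref.min()
    _check(
        checks, "metad_fes_closed_form",
        np.allclose(fes.F, F_ref, atol=1e-10),
    )
    path = fe.min_energy_path(fes, (0, 0), (len(cv1) - 1, len(cv2) - 1))
    max_on_path = max(v for _, v in path)
    _check(
        checks, "min_energy_path_bottleneck_bound",
        max_on_path >= max(fes.F[0, 0], fes.F[-1, -1]) - 1e-12,
    )
    f = out / "fes.csv"
    fes.to_csv(f)
    files.append(f)
    return files


_STAGE_FUNCS = {
    "io": _stage_io,
    "contacts": _stage_contacts,
    "activation": _stage_activation,
    "ligand": _stage_ligand,
    "water": _stage_water,
    "network": _stage_network,
    "free_energy": _stage_free_energy,
}


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Identical config + seed produce byte-identical CSV/JSON outputs.  A stage
    failure is recorded and downstream stages still run (they are independent
    over synthetic inputs); the report's ``ok`` flag reflects both stage
    errors and failed planted-recovery checks.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_echo={"out_dir": str(out), "seed": config.seed, "stages": config.stages,
                     "params": config.params},
    )
    for name in DEFAULT_STAGES:
        if not config.stages.get(name, False):
            report.stages.append(StageResult(name=name, status="skipped"))
            continue
        checks: list[dict] = []
        t0 = time.perf_counter()
        try:
            written = _STAGE_FUNCS[name](out, config.seed, config.params, checks)
            status = "ok"
            error = ""
        except GpcrDynError as exc:
            written, status, error = [], "failed", str(exc)
        wall = time.perf_counter() - t0
        result = StageResult(
            name=name, status=status, wall_time_s=wall,
            outputs=[p.name for p in written], checks=checks, error=error,
        )
        report.stages.append(result)
        for p in written:
            report.manifest[p.name] = _sha256(p)
    report.to_json(out / "run_report.json")
    return report


def demo(seed: int = 0, out_dir: str = "gpcrdyn_demo") -> RunReport:
    """Generate all synthetic fixtures, run every stage, assert every planted
    recovery.  Scaled to finish in minutes on one CPU."""
    config = RunConfig(out_dir=out_dir, seed=seed)
    return run(config)
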