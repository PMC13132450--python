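# gpcrdyn

Trajectory analysis and free-energy post-processing for lipid-GPCR activation
studies, built around the question of why two nearly identical
lysophosphatidic acids behave so differently at the LPA1 receptor: 18:1-LPA
(oleoyl, one cis C9=C10 double bond) is a full agonist while the fully
saturated 18:0-LPA (stearoyl) is a weak/partial agonist.  The package
implements the complete post-processing chain such a study needs —
protein–ligand contact fingerprints, activation-switch metrics, ligand shape
descriptors, water-channel bookkeeping, residue-network communication paths,
and umbrella-sampling / metadynamics free-energy analysis — together with a
synthetic-data module that plants exactly recoverable ground truth, so every
analysis can be validated end-to-end without any trajectory download.

It is aimed at computational structural biologists who run molecular-dynamics
campaigns on membrane receptors and want the *analysis* layer to be tested,
reusable and deterministic.

## What it computes

- **Contacts** (`gpcrdyn.contacts`): per-residue contact occupancy at an
  inclusive 4 Å heavy-atom cutoff, nearest-heavy-atom distance series,
  per-segment ligand fingerprints (glycerophosphate head / upper acyl chain /
  lower acyl chain vs residues or lipid functional groups), and named
  polar-interaction presets for the receptor–Gα interface keyed by generic
  residue labels.
- **Activation switches** (`gpcrdyn.activation_switches`): χ2 side-chain
  torsions with circular statistics (the rotamer states of the CWxP, PIF and
  NPxxY microswitches), interhelical TM3–TM6/TM3–TM7 distance series, 2D
  kernel densities, and per-frame active/inactive/intermediate classification
  against reference structures.
- **Ligand geometry** (`gpcrdyn.ligand_geometry`): the internal angle α
  (phosphate head — mid-chain C9/C10 — chain terminus; ≈60° U-shaped, ≈75°
  L-shaped, ≈180° extended), binding-site-superposed ligand RMSD,
  average-linkage pose clustering with medoid ("most-preferred pose")
  selection, and bond-graph descriptors (rotatable-bond counts from SMILES).
- **Water channel** (`gpcrdyn.water_channel`): waters near the ligand,
  bridging waters, upper↔lower flux with a hysteresis crossing rule, and
  per-frame channel continuity along a pore axis.
- **Residue networks** (`gpcrdyn.residue_network`): nodes are residues, an
  edge exists when heavy atoms stay within 4.5 Å for *more than* 75% of the
  frames, and edge weights are `w = -log|C|` with `C` the normalised
  displacement covariance; shortest paths model allosteric communication,
  plus suboptimal paths and Girvan–Newman communities.
- **Free energy** (`gpcrdyn.free_energy`): WHAM for 1D membrane-partitioning
  PMFs (`p(z_b) = Σ_i h_ib / Σ_i N_i e^{βf_i} e^{-βU_i(z_b)}` iterated to
  self-consistency) with partitioning descriptors (ΔG_partitioning,
  ΔG_crossing, z_min, RT-accessible halfwidth); well-tempered metadynamics
  FES reconstruction `F(s) = -(γ/(γ-1)) V(s)` from PLUMED-style HILLS; and
  minimum-energy (minimax bottleneck) paths on 2D free-energy surfaces.
- **Synthetic data** (`gpcrdyn.synthetic_data`): every fixture generator is a
  pure function of its spec — planted contact occupancies are exact, umbrella
  windows are inverse-CDF draws from the exact biased density of a known PMF
  (k = 1.5 kcal mol⁻¹ Å⁻², 30 windows at 1 Å, 310 K), hills files follow
  well-tempered damping (σ = 0.05 nm, bias factor 15), and water walks
  realise exact traversal counts.

## Worked example

```bash
gpcrdyn demo --seed 1 --out demo_out
```

runs every stage on synthetic fixtures and asserts each planted recovery.
Output (abridged):

```
[     ok] io (1.30 s)
[     ok] contacts (0.01 s)
[     ok] activation (0.17 s)
[     ok] ligand (0.01 s)
[     ok] water (0.00 s)
[     ok] network (0.00 s)
[     ok] free_energy (0.07 s)
all checks passed
```

`demo_out/run_report.json` records, per stage, the checks and their details,
e.g. for the free-energy stage

```
wham_rms_accessible_range        rms=0.103
partitioning_descriptors_recovered  dG_part=-9.09, dG_cross=10.87
```

meaning: WHAM re-estimated the planted membrane-partitioning PMF (well depth
−9 kcal/mol at z = 15 Å, central barrier 11 kcal/mol above the minimum) with
0.10 kcal/mol RMS error over the thermally accessible range, and the
partitioning descriptors came back within 0.1–0.15 kcal/mol of the planted
values.  The same config and seed reproduce byte-identical outputs
(`run_report.json` carries a SHA-256 manifest).

The library surface mirrors the CLI; for example

```python
from gpcrdyn.ligand_geometry import lpa_graph, rotatable_bond_count
rotatable_bond_count(lpa_graph("18:0"))   # 22
rotatable_bond_count(lpa_graph("18:1"))   # 21  (the C9=C10 bond is rigid)
```

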