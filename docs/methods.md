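# Methods

This note documents the models, conventions and numerical choices behind
`gpcrdyn`, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Coordinate and unit conventions

All internal coordinates are Å; readers convert nm-based containers (XTC) on
ingest.  Times are ps.  Energies are kcal/mol in the umbrella-sampling path
(RT = k_B·310 K = 0.616 kcal/mol) and carry explicit unit declarations in the
metadynamics path, because HILLS files in the wild mix kJ/mol and kcal/mol;
the reader refuses to guess.  Residue numbering is taken verbatim from input
files; generic Ballesteros–Weinstein ("3.50") and CGN ("G.H5.22") labels live
only in an explicit numbering map and are never inferred from sequence.  A
heavy atom is any element other than H/D.  When a periodic box accompanies a
trajectory, pair distances use the orthorhombic minimum-image convention;
whether production analyses of wrapped, receptor-centred trajectories need
the correction is system-dependent, so toy fixtures are non-periodic and the
box is optional.

## Contacts

A residue is in contact with the ligand in a frame iff the minimum
heavy-atom pair distance is ≤ 4.0 Å — the boundary counts as contact, which
makes the planted-occupancy tests sharp.  Contact occupancy is exactly
(frames in contact)/(total frames).  Whether an all-atom or heavy-atom rule
is more faithful to common practice is debatable; heavy-only is used
consistently because polar-contact distances are defined between nearest
heavy atoms, and explicit hydrogens are not required anywhere.  Salt bridges
are measured between charged-group heavy atoms (Arg/Lys side-chain N to
Asp/Glu carboxylate O); the H-bond proxy, when a boolean is needed, is a
donor–acceptor heavy-atom distance ≤ 3.5 Å.  The ligand segment split is
glycerophosphate head (P, its O substituents, glycerol C/O), upper acyl
chain (C1–C9) and lower acyl chain (C10–C18); the boundary is configurable.

## Activation switches

χ2 quartets are fixed per residue type (aromatics: CA–CB–CG–CD1; Pro:
CA–CB–CG–CD; full table in `activation_switches.CHI2_QUARTETS`).  Angle
summaries use circular mean/SD: for concentrated rotamer distributions this
is indistinguishable from the arithmetic mean, and it remains correct for
distributions straddling ±180°.  Interhelical activation distances use the
minimum heavy-atom convention, matching the contact module, since reference
values of a few Å between side chains are not Cα–Cα distances.

2D kernel densities use a Gaussian product kernel with Scott's-rule
bandwidth per dimension (recorded in the output); the grid spans the data
± 3 bandwidths, and the numerical integral over the grid is within 1% of 1.

Frame classification: a frame is active-like iff every metric lies within
tolerance of its active reference (circular distance for angles; defaults
± 1.5 Å and ± 30°, both configurable); inactive-like analogously, and
everything else intermediate.  The active test is decided independently of
the inactive test, so a frame ambiguously within both tolerance bands is
labelled active-like; this keeps the classifier monotone — tightening
tolerances can only shrink the active population — at the cost of an
arbitrary resolution of a case that well-separated references never produce.

## Ligand geometry

The internal angle α is measured at the midpoint of the C9/C10 positions,
between the phosphate P atom and the midpoint of the two terminal chain
carbons.  Acyl-chain nomenclature counts C1 as the carbonyl carbon, so "the
tail end" is anchored at the *terminal* two carbons — the geometric reading
of a chain-terminus anchor; the choice only relabels which carbons define
the tail point and does not change the U/L/extended classification.

Ligand RMSD superposes each frame onto the reference by least squares over
the binding-site selection only (rotation from an SVD-based alignment), then
measures RMSD over ligand heavy atoms without refitting — so the descriptor
captures motion of the ligand relative to the pocket, not global tumbling.
Pose clustering is hierarchical average-linkage on the pairwise RMSD matrix,
cut at a distance threshold; the largest cluster's medoid (member minimising
summed RMSD to the rest) is the representative pose.  All ties break toward
the lowest frame index so results are deterministic.

Rotatable bonds are acyclic single bonds between heavy atoms that each have
at least two heavy neighbours (ring membership = the bond is not a bridge of
the heavy-atom graph).  On the two LPA species this yields 22 (18:0) and 21
(18:1): the cis C9=C10 double bond removes exactly one rotatable bond.

## Water bookkeeping

A water is its O atom.  Flux between two z-planes uses a hysteresis counter:
each water's state is the last plane it was beyond, and an event fires only
when it reaches beyond the other plane, so oscillations inside the slab
count nothing.  Both event totals and unique-water counts are reported,
because "how many waters moved" and "how many traversals happened" answer
different questions.  The planes are free parameters of the measurement; a
helper places them at the 10th/90th axial percentiles of the binding-site
atoms.  Channel continuity is per snapshot: a frame is continuous iff every
axial bin of the pore cylinder holds at least one water (no time averaging),
which is the per-frame reading of a "continuous water channel".

## Residue networks

Edges require heavy-atom contact (≤ 4.5 Å, inclusive) in strictly more than
75% of frames.  Edge weights are `w_ij = -log|C_ij|` where `C_ij` is the
normalised covariance of the two residues' reference-point displacement
vectors (Cα for amino acids, heavy-atom centroid otherwise) — the standard
dynamic-network construction, stated here explicitly because the weight
formula matters for reproducibility.  Residues with zero displacement
variance have undefined correlations and are excluded from edges with a
warning.  Optimal paths are minimum-total-weight (Dijkstra), ties broken by
lexicographic node sequence; suboptimal paths enumerate all simple paths
within a caller-chosen tolerance of the optimum (no default tolerance is
sensible, so it is required).  Communities are Girvan–Newman divisive
clustering driven by weighted edge betweenness (path lengths in `w`), with
the partition chosen by maximum modularity evaluated with coupling strength
`|C|` as the edge weight and the undivided graph included as a candidate.
Girvan–Newman is greedy: on graphs with clear block structure it attains the
modularity optimum, but it carries no global guarantee on adversarial
topologies.

## Free energy

**WHAM.**  Windows are binned (default 0.2 Å) and the standard
self-consistent equations are iterated until the window free-energy
constants move by less than 10⁻⁷ kcal/mol (default cap 10⁵ iterations).
Adjacent windows must have overlapping sampled histograms; a gap raises an
error naming the two centers rather than silently extrapolating.  The PMF is
anchored so the mean over a declared aqueous-plateau z-range is zero, which
is what makes ΔG_partitioning a water→membrane transfer free energy.
Descriptors: z_min is the global grid minimum refined by a local parabola;
ΔG_partitioning = F(z_min); ΔG_crossing = max F between z_min and the
bilayer center, relative to F(z_min); the thermally accessible halfwidth is
the half-extent of the contiguous region with F ≤ F(z_min) + RT, with the RT
level crossing interpolated linearly.  Bins within half a grid step of the
interval ends are included when scanning for the barrier, so an extremum at
an endpoint is not lost to float round-off.

**Well-tempered metadynamics.**  HILLS records store heights already damped
by the well-tempered factor (the convention PLUMED writes), so the
reconstruction sums the recorded Gaussians into the bias V and reports
F = −(γ/(γ−1)) V shifted to a zero minimum; for γ = 15 the prefactor is
15/14.  Mixed bias factors in one file are an error.

**Minimum-energy paths.**  On a 2D grid the path criterion is minimax — the
energetic bottleneck defines the cost — with ties broken by minimal summed
F, then fewest nodes, then lexicographic node order.  (Pure lexicographic
tie-breaking after the sum would prefer meandering detours on flat surfaces,
since node energies of zero add nothing to the sum; the node-count key
restores the expected direct step.)  The search runs from the
lexicographically smaller endpoint and reverses if needed, so
`path(a, b) == reversed(path(b, a))` exactly.

## Synthetic data: what it emulates, and what passing tests show

The toy receptor is a rigid cage of one-atom residues around a five-bead
ligand (head P, mid C9/C10, tail C1/C2 anchors) — the minimal geometry that
exercises contacts, α, superposition and RMSD.  Contact occupancies are
planted *exactly* (a seeded choice of in-contact frames, not Bernoulli
draws), so contact recovery is an equality test; distributional generators
(von Mises rotamer mixtures, umbrella windows) are validated at stated
stochastic tolerances instead.  Umbrella windows are inverse-CDF draws from
the exact biased density of a tabulated PMF — by construction there is no
force-field, friction or autocorrelation structure, so a passing WHAM
recovery validates the estimator and its bookkeeping, not the convergence of
any real simulation.  The planted partitioning PMF is a monotone spline with
an aqueous plateau at 0, a well of −9 kcal/mol at z = 15 Å and a +2 kcal/mol
barrier at the bilayer center (crossing barrier 11 kcal/mol), tabulated so
its descriptors are exact by construction.  Water walks interpolate between
stations beyond the planes with bounded jitter, so traversal counts are
exact under the hysteresis rule.  None of this emulates lipid structure,
solvent correlations, or realistic protein dynamics; conclusions about real
trajectories require real trajectories.

Default problem sizes (40-frame contact fixtures, 30 umbrella windows with
10⁴ samples each in the validation suite and 4×10³ in the demo, ≤ 50-node
toy graphs) keep the full validation cycle in the minutes range on one CPU
while leaving the stochastic tolerances comfortably resolvable.

## Known limitations

- No MBAR generalisation, 2D WHAM, or bootstrap error bars on the PMF.
- PDB input only for structures (no mmCIF); DCD/XTC only for trajectories;
  no force-field topology parsing beyond ligand bond graphs.
- The residue-network node set is caller-defined; nothing prevents or
  requires including ligand or G-protein nodes.
- Girvan–Newman communities carry no global modularity guarantee.
- Water analyses ignore hydrogens and residence-time kinetics.
- The pipeline stages operate on the synthetic fixtures; applying the
  library to production trajectories is done through the module APIs.
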