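# Methods

## Problem and scope

`cmap2struct` reconstructs three-dimensional protein structures —
single chains and cyclic homomultimers such as tetrameric ion
channels — from *ternary contact maps*: symmetric L×L matrices over
{1, 0, −1} where 1 marks a residue pair within a distance threshold,
0 a known non-contact, and −1 an unknown pair that imposes no
restraint.  It also implements the assessment side: RMSD-family
structural metrics, the channel "structure diameter", contact density,
and a functional metric — the electrostatic potential profile along
the pore axis from a two-dielectric Poisson solve — together with an
experiment runner that degrades contact knowledge in controlled ways
(positive-only, randomly reduced, erroneous maps) and measures how
model quality responds.

## Contact maps

Contacts default to Cα–Cα distance ≤ 8 Å with all sequence
separations; Cβ mode (with Cα fallback for glycine) is available.  The
threshold and atom mode travel with the map in its `meta` dict because
every downstream stage depends on them.  The diagonal is a
self-contact and is excluded from all counts and perturbations.
Contact density is CD = (1/L)·Σᵢ cᵢ with cᵢ the number of off-diagonal
contacts of residue i.

Perturbations operate on the upper triangle and mirror, so symmetry is
structural rather than incidental; counts use round-half-away-from-zero
and selection is uniform without replacement from a seeded generator.
Erroneous maps support two modes because the two natural readings of
"flip a fraction of entries" differ: `flip_ones` (1→0 only, the
default) and `flip_both` (1↔0 over all known entries).

For multimers the chains are concatenated; *dummy loops* — blocks of
all-unknown rows/columns (default length 15, ≈ 60 Å of slack) — are
inserted between chain terminals so the reconstructor's
chain-continuity assumption does not glue the C-terminus of one chain
to the N-terminus of the next.  The insertion mapping is invertible
and the loops are trimmed from the trace after reconstruction,
leaving chain breaks.

## Trace reconstruction

The reconstructor is a seeded two-phase scheme. *Initialization* is a
random walk with fixed virtual-bond steps (3.8 Å) biased toward a
compact ball of radius (3/4π)^(1/3)·L^(1/3)·4 Å, the scaling of
globular packing.  *Refinement* is iterative averaged constraint
projection: each sweep computes all pairwise distances and corrects
violations — contacts beyond the threshold pull both partners
together (target 0.95·threshold), known non-contacts inside it push
apart to threshold + 0.1 Å, and bonded neighbours are reset to the
virtual bond length by a few extra Jacobi passes per sweep.  Each
point moves by the *average* of its pairwise corrections, scaled by a
move fraction of 1.0 (full projection; 0.5 also works but converges
more slowly).  When the satisfaction score — the fraction of known
pairs whose distance relation matches its label; vacuously 1.0 on an
all-unknown map — stagnates for 25 sweeps, coordinates are jittered
with Gaussian noise (σ = 1 Å) and refinement continues from the
best-ever structure, which is also what is returned.  Defaults:
500 sweeps, satisfaction target 0.98, 3 restarts per model; ensembles
use seeds seed, seed+1, …

Contact maps carry no chirality, so a refined trace and its mirror
image satisfy identical restraints.  Handedness is resolved after
refinement: the mean sign of the Cα pseudo-dihedral over 4-residue
windows (right-handed α-helical windows sit near +50°; near-trans
windows, |dihedral| > 150°, are ambiguous and excluded from the vote)
decides whether to reflect.  All model-versus-native comparisons are
additionally mirror-aware.

### What a binary map can and cannot determine

A complete 8 Å Cα map determines a *compact* fold essentially uniquely:
long-range contacts triangulate every residue, and the 60-residue
compact-coil fixture self-reconstructs to ≈ 1.2 Å with satisfaction
≥ 0.98.  An isolated secondary-structure fragment is different: a lone
30-residue helix has contacts only at |i−j| ≤ 4, and *any* gently bent
rod satisfies every contact and non-contact inequality exactly (the
non-contact bound d(i,i+5) > 8 Å tolerates curvature radii down to a
few Å), so full-satisfaction reconstructions can sit 10 Å from the
native helix.  This is an information limit of binary maps, not a
solver failure, and it is the desk-scale face of the well-known
empirical rule that reconstruction accuracy rises with contact
density and is worst for all-α architectures.  Tests therefore assert
RMSD recovery on compact fixtures and satisfaction/local-geometry
properties on the extended ones.

## All-atom completion

The backbone builder replaces structural-alphabet fragment assembly
with deterministic ideal geometry: N, C, O positions are expressed in
a local orthonormal frame spanned by (Cαᵢ₋₁, Cαᵢ, Cαᵢ₊₁) with offsets
calibrated once on an ideal α-helix built by internal coordinates
(N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å, C=O 1.23 Å, φ = −57°,
ψ = −47°, ω = 180°).  Cα coordinates are preserved bit-exactly; on an
ideal helix trace the reconstruction reproduces helix dihedrals
exactly, and termini use separately calibrated end frames.  Peptide
closure (C–N across residues placed from different frames) is
approximate on irregular traces — adequate for heavy-atom RMSD and
charge placement, not for covalent-geometry-sensitive applications.

Side chains are placed from CCD ideal-residue templates: the template
is superposed on the local N/Cα/C triad and rotated to one of a small
embedded χ-rotamer set (1–5 rotamers per type, weights summing to 1;
χ₁ ∈ {−60°, 180°, +60°} dominant).  Placement is greedy and
deterministic: the highest-weight rotamer without hard-sphere clashes
(non-bonded heavy-atom pairs closer than 0.8 × the sum of van der
Waals radii; intra-residue and short-range cross-peptide pairs
exempt), else the least-clashing.  A relief stage sweeps clashing
residues, re-picking rotamers only when the total overlap count
decreases, so the count is monotone non-increasing; the backbone is
never moved.  Proline keeps its template ring; no torsion-space
energy minimization is attempted.

## Symmetry assembly

A reconstructed multimer trace is split at the trimmed loop positions
and each chain gets its own backbone.  The asymmetric assembly is
oriented with its pore axis on z: the axis is the normal of the
best-fit plane through the chain centroids (an explicit z-aligned
reference structure can be supplied instead, in which case a Kabsch
superposition is used), the centroid moves to the origin, and the
axial *orientation* is made canonical by requiring N-terminal chain
halves to lie below C-terminal halves — without this the axis sign is
arbitrary and any z-dependent comparison (the pore profile above all)
would be randomized.  Each subunit is then projected order-times
about the axis (machine-precision Cₙ symmetry by construction),
yielding order channels, plus one more from the atom-wise average of
the Kabsch-superposed subunits: order + 1 candidate channels per
reconstruction.  Because symmetric assemblies have no canonical chain
labelling, RMSDs between assemblies minimize over cyclic chain
permutations (and the mirror).

## Pore electrostatics

With zero ionic strength and zero membrane potential the linearized
Poisson–Boltzmann equation reduces to the variable-dielectric Poisson
equation ∇·(ε(r)∇φ) = −ρ/ε₀.  It is discretized on a cubic grid
(defaults follow the channel-study setup: 129³ nodes, 1 Å spacing)
with a 7-point finite-volume stencil and harmonic-mean dielectric on
cell faces; ε = 4 inside any atom's van der Waals sphere, ε = 80
(electrolyte) elsewhere including the pore lumen.  Charges are
splatted trilinearly onto nodes; Dirichlet boundary values are summed
Coulomb potentials in the solvent dielectric; the system is solved by
Jacobi-preconditioned conjugate gradients to a relative residual of
10⁻⁶.  Accuracy: a unit point charge in uniform ε = 80 reproduces the
Coulomb closed form within ≈ 1 % for r ≥ 5 Å on a 65³ grid.

The default charge scheme is *formal*: −1 e split over Asp OD1/OD2
and Glu OE1/OE2, +1 e on Lys NZ, +0.5 e on each Arg NH1/NH2, +1 e on
each chain's N-terminal N and −1 e on its C-terminal O/OXT.  A PQR
reader is provided for per-atom charge/radius sets; absolute
potential values depend strongly on the charging scheme, so only
PQR-grade charges are expected to reproduce any particular published
profile amplitude.

Profiles sample φ by trilinear interpolation along (x₀, y₀, z) —
default the pore axis — at 1 Å steps and are parameterized by Fmax,
Fmin and zmin (first minimum on ties, flagged).  Model profiles are
compared to a template by RMSE on the common z grid and by relative
deviations |X − X_t|/|X_t| of the three parameters.

## Synthetic systems

The fixtures module generates every structure the tests and the
acceptance script use:

* ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å, poly-Ala);
* β-hairpin-like chain (two antiparallel extended strands);
* compact coil (seeded self-avoiding walk in a globular-scaling ball)
  — the fixture whose complete map fully determines the fold;
* toy C4 channel: four ideal helices in exact C4 symmetry about z
  around a pore (default radius 5 Å, 14–20 residues per chain).  The
  pore-facing marker residue (an alanine; opposite-chain markers sit
  exactly 2·pore_radius apart, the "structure diameter" gauge) and two
  outward-facing charged rings (one Asp, one Lys, at different
  heights) give the pore a smooth mV-scale potential profile carried
  by well-constrained interior residues rather than by the floppy
  termini;
* ±1 e point-charge pair for solver tests.

What the toy channel does *not* emulate: real secondary-structure
diversity, side-chain packing of a native core, sequence-dependent
contact statistics, membrane dielectric anisotropy, and crystallographic
coordinate noise.  Green tests on it demonstrate the machinery and the
qualitative knowledge-vs-quality relationships, not absolute accuracy
on any particular protein.

## Experiment runner and problem sizes

`run_experiment` derives the native map, applies each perturbation
variant over `n_random_maps` seeded replicates (deterministic variants
collapse to one), reconstructs `n_models_per_map` models per map
(each multimer model yields its 5 channels), scores every output, and
writes a tidy TSV plus a mean ± SD / median-quartile summary.  Seeds
derive hierarchically from (base, variant, map, model) through
`numpy.random.SeedSequence`, so every experiment is fully
deterministic given the base seed.

The shipped test-suite and acceptance-script conditions are desk
scale by design: the toy channel uses 14 residues per chain, dummy
loops of 6, 3 maps × 3 models per reduced fraction, and a 49³ grid at
1.5 Å spacing for per-model electrostatics (the 129³/1 Å default
remains for production use).  At these sizes the degradation sweep
reproduces the expected behavior: median RMSD is non-decreasing as
the retained fraction drops 1.0 → 0.3, positive-only maps collapse
the diameter far below native while complete maps preserve it, and
Kendall τ between model RMSD and pore-profile RMSE is positive
(≈ 0.24, p ≈ 10⁻⁶) — the structure–function correlation that makes
the electrostatic profile usable as a model-quality indicator.

## Known limitations

* Binary-map underdetermination of extended architectures (above).
* Ideal-geometry backbones and the minimal rotamer set shift absolute
  full-atom RMSDs by a few tenths of Å relative to dedicated backbone
  and side-chain programs; comparisons between knowledge conditions
  are unaffected.
* The formal charge scheme ignores partial charges and protonation;
  absolute Fmax/Fmin values are scheme-dependent.
* Only cyclic (Cₙ) symmetry is supported; the symmetry axis estimate
  needs ≥ 3 chains or a reference.
* PDB input only (no mmCIF); hydrogens are dropped on read.
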