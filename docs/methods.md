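# Methods

`lipsite` analyzes molecular-dynamics trajectories of membrane receptors
whose ligands bind *extrahelical* (lipid-facing) allosteric sites. Every
stage is a post-processing step over coordinates and per-atom parameters
(charges, 12-6 Lennard-Jones terms); no dynamics are integrated here.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test systems do and do not establish.

## Units and conventions

Lengths in Å, energies in kcal/mol, charges in elementary-charge units,
temperatures in K. Boxes are orthorhombic; any distance-based analysis
applies the minimum-image convention whenever a frame carries a box, and
plain distances otherwise. Structures travel as PDB (multi-model PDB is
read as a trajectory), trajectories as DCD, scalar grids as OpenDX, and
all result tables as TSV. Because PDB cannot carry charges or LJ
parameters, a TSV *topology sidecar* keyed by `atom_id` supplies them;
this avoids committing to any force-field file dialect while keeping
every number bit-checkable. Atom elements missing from a PDB are
inferred from atom names, with ambiguous names (`CA`) resolved by
residue class and logged.

## Stability metrics

RMSD is computed per frame after an unweighted Kabsch (SVD)
superposition of a fit selection onto a reference frame; the measured
selection may differ from the fit selection (receptor Cα for the fit,
ligand heavy atoms for ligand RMSD). The reference is the first analyzed
frame by default and is configurable. RMSF is the fluctuation of each
atom about its time-averaged position after superposing all frames on
the fit selection — the common trajectory-viewer convention. A ligand
fragment's RMSF is the unweighted mean over its heavy atoms
(configurable to the maximum); source material for such numbers rarely
states the aggregation, so it is explicit here. Degenerate (collinear)
fit selections are rejected because the rotation about the degenerate
axis is not determined by the data. The superposition is validated
against an independent quaternion (Horn) solver in the tests.

## Hydrogen-bond and water occupancy

A hydrogen bond D–H···A is counted when the donor–acceptor heavy-atom
distance is ≤ `d_cut` (default 3.2 Å) **and** the D–H···A angle is
≥ `angle_cut` (default 150°). The distance criterion is the one under
which the occupancy statistics this package targets are defined; the
angle gate is required to keep grazing contacts out, and since the
original analyses do not state their angle setting, it is an exposed
parameter that every run logs rather than a hidden constant. Donors are
N/O with at least one bonded hydrogen, acceptors are N/O; halogens do
not participate here (halogen-bond classification lives in the
charge-transfer stage). Occupancy is the exact fraction of frames in
which *any* qualifying triple exists between the two selections.
Water-in-site occupancy counts frames in which at least one water is
hydrogen-bonded (in either donor/acceptor direction) to at least one
site atom (`mode=any`, the default) or to every listed site atom
(`mode=all`); which water plays partner is irrelevant. The `any`
default reflects that multi-atom site statements are usually
ambiguous between the two readings.

## Nonbonded energies

Pair energies use the Amber conventions: 12-6 LJ in Rmin–epsilon form,
E = ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶], Lorentz–Berthelot combining
(Rmin_ij as the sum of Rmin/2 values, ε_ij geometric mean), and Coulomb
E = k·q_i·q_j/r with k = 332.0636 kcal·Å·mol⁻¹·e⁻² and dielectric 1.
Interactions are hard-truncated at 10 Å — the stated production cutoff —
with no switching function, no long-range correction and no 1-4 scaling
(all pairs handled are intermolecular). Hard truncation means group
energies change discontinuously when a pair crosses the cutoff; this is
accepted and documented rather than papered over, since the original
decomposition tool's switching setup is unstated. Group energies are
bit-exactly symmetric (the implementation canonicalizes summation
order).

Per-residue decomposition selects residues with any heavy atom within a
5 Å shell of any ligand atom, decided on the first analyzed frame
(configurable to the union over frames — the results can differ for
mobile ligands), then reports mean ± sd over frames per residue. Rows
are additive: they sum to the ligand-versus-shell total to 1e-8
kcal/mol, which the tests enforce against an explicit O(N²) pair-loop
oracle. The lipid contact census counts a lipid tail (its bonded carbon
chain) as engaged when its mean vdW energy with the target is at or
below −1 kcal/mol, and a head group by the same rule on the
electrostatic energy; the thresholds are reporting conveniences, always
logged, because the source statements are qualitative counts.

## Lipid occupancy and grid free energy

The lipid-carbon occupancy grid counts, per cell and per frame, the
selected atoms falling in the cell (half-open binning, so boundary atoms
land in exactly one cell and counts are conserved; a binary
presence/absence mode exists and coincides with counts for sub-Å cells).
The free-energy map applies the SILCS-style conversion

    GFE = min( −R·T·ln(occ / occ_bulk), GFE_max )

with R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, T = 310 K, and GFE_max = 3
kcal/mol; the cap absorbs the +∞ of zero-occupancy cells inside the
protein medium. The bulk reference is the mean occupancy of
membrane-slab cells whose centers are at least 10 Å from every protein
atom, with the protein taken from a static snapshot (first frame;
configurable to an all-frame minimum distance). Around a real receptor
the 10 Å criterion implicitly excludes the analysis site from the bulk;
in synthetic geometries a site region can extend beyond that distance,
so the reference optionally excludes an explicit site box. Replicas are
averaged as the arithmetic mean of GFE grids (capped values averaged
as-is); pooling occupancies before conversion is also available because
the two differ wherever cells hit the cap — the GFE mean is the default.
Maps are written as OpenDX with 1 Å default spacing and are convention-
ally rendered at the −1.2 kcal/mol isovalue, which corresponds to an
occupancy ratio of exp(1.2/RT) ≈ 7.0 at 310 K.

Two caveats are inherited by construction: grid cells are treated as
independent, and a single initial lipid configuration underlies any one
trajectory.

Numerics worth knowing: the per-cell log makes the *mean* regional GFE
a biased estimator at small per-cell counts (E[ln X] ≈ ln λ − 1/(2λ) for
Poisson-like counts). The acceptance analyses therefore use 2–3 Å cells
on 2000-frame runs, where λ is in the hundreds and the bias is an order
of magnitude below the statistical error; when comparing a regional
mean against a programmed enrichment, the region must be aligned to
whole grid cells (cells fully inside the region) or boundary cells
dilute the estimate.

## Cavity volume and surface area

The cavity detector is a probe-excluded voxel flood fill, deliberately
simpler than alpha-sphere pocket scoring: a grid (0.8 Å default spacing)
spans the site seed's bounding box plus a margin; a cell is blocked when
its center lies within (vdW radius + probe) of any context atom; free
cells are labeled by 6-connectivity; the cavity is the component
containing the seed centroid, and it counts toward the volume only if
it is *enclosed* — unreachable from the grid boundary through probe-free
space. An open groove therefore reports zero enclosed volume, and
adding lipid atoms (those within 6 Å of the site atoms, in the
`receptor_plus_lipids` context) can wall it off and create volume —
reproducing the direction of lipid-dependent pocket volumes. Because
this replaces an alpha-sphere/druggability method, volume-loss
percentages from it are qualitative analogues, never claimed equivalent.
A seed centroid buried in solid atoms yields an empty cavity with a
logged warning (a solid block legitimately has no cavity). Voxel
volumes on flat-walled fixtures oscillate by up to ~8% between 0.8 and
0.4 Å spacings (quantization against planar boundaries); on curved
boundaries they converge within 5%.

SASA is Shrake–Rupley with deterministic golden-spiral test points (960
per atom by default), a 1.4 Å probe, and Bondi van der Waals radii
shipped as an in-code table. Polar area sums N, O and hydrogens bonded
to them; sulfur counts nonpolar by default. Polar and nonpolar fractions
sum to one by construction. The implementation is cross-checked against
mdtraj's Shrake–Rupley in the tests.

## Fragment decomposition and charge-transfer post-processing

The quantum-chemistry stage consumes *tabulated* outputs only: fragment
interaction-energy decompositions (electrostatics, exchange, induction,
dispersion, total per residue side chain or backbone amide) and
natural-population-analysis charge-transfer values Q_CT (au). Records
whose total deviates from the component sum by more than 0.02 kcal/mol
are warned with the delta but kept — published tables are rounded.
Fragment efficiency is total energy per heavy atom (heavy-atom counts
exclude capping groups added for fragment preparation; overridable per
record). Grouped electrostatic ratios use absolute values — every
quantity of interest is attractive, so signed and absolute sums agree on
real tables — and are reported both unrounded and rounded to integer
percent. Q_CT classification compares a contact against a per-bond-class
reference: 0.05 au for a classical N/O–H···N/O hydrogen bond at optimal
geometry and ten times lower for a nonclassical C–H donor; no reference
is shipped for the O–Br halogen bond because none is published, so that
class must be user-supplied. The strength labels (optimal ≥ 0.8 of
reference, weak ≥ 0.2, very weak below) are reporting conveniences
chosen to reproduce the qualitative labels on the printed values, not
claims.

## Synthetic systems and what they establish

The generator builds a membrane–protein–ligand toy: seven bead rods
(N, H, CA, O per residue) on a circle with one widened gap forming an
extrahelical groove, a two-leaflet slab of pseudo-lipids (head particles
plus tail carbons), a rigid two-fragment ligand docked ~4.5 Å outside
the bundle in the groove, and three-site waters in the solvent layers.
Toy nonbonded parameters sit in plausible ranges (ε ∈ [0.05, 0.2]
kcal/mol, Rmin/2 ∈ [1.2, 2.0] Å, |q| ≤ 1 e). One seeded random stream
drives a run and the seed is recorded in the manifest; the same spec and
seed reproduce the system bit-for-bit.

Trajectories are *programmed*, not simulated: hydrogen-bond events are
deterministic frame assignments (exactly round(occupancy × frames)
bound frames at a collinear bound-distance geometry), so occupancy
recovery is exact rather than stochastic and the recovery tests can
assert equality; lipid tail carbons are resampled i.i.d. per frame with
a prescribed in-region/bulk density ratio ρ, so the regional mean GFE
has the analytic expectation −RT ln ρ; everything else receives
isotropic Gaussian noise (per-atom RMSF expectation σ√3). A separate
deterministic fixture — a five-walled box open on one face that a plane
of lipid carbons seals — isolates the cavity-enclosure contrast.

These systems validate the *measurement machinery*: binning, geometry,
energy sums, statistics, file round-trips, determinism. They do not
establish anything about real membranes: there are no forces, no lipid
phase behaviour, no correlated dynamics, no solvent structure, and the
programmed events are noise-free by design. Passing tests mean the
pipeline measures what it claims to measure, not that a μs-scale
receptor simulation would reproduce any published number.

## Pipeline and reproducibility

The CLI is a thin layer over the library: one YAML config declares the
input source (generated or PDB/DCD + topology TSV), the stages, and all
parameters; subcommands run single stages and `all` runs everything,
writing TSV/DX/JSON plus a manifest with resolved parameters, input
checksums, software version and per-stage timings (success or failure).
Floats in tables and reports are written at 6 significant digits, so a
fixed config and seed reproduce every analysis output byte-for-byte;
the manifest is the one exception, since it records wall-clock timings.
The committed golden report is compared numerically (rtol 1e-4) rather
than byte-wise so that last-digit differences between BLAS builds do
not masquerade as regressions; byte-identity is asserted between
repeated runs in the same environment. Exit codes: 0 success, 2 config
error, 3 input error, 4 stage failure.

Problem sizes in the test and acceptance runs — a ~1300-atom toy system,
2000-frame occupancy runs, 5000-frame noise-recovery runs, 100 random
systems for the energy oracle — were chosen so each statistical check
has comfortable margin (3 standard errors with bias an order of
magnitude smaller) while the full suite stays fast.

## Known limitations

- Hard cutoff electrostatics/LJ only; no Ewald, switching, or
  polarizability. Decomposition energies are therefore analysis-grade,
  not simulation-grade.
- The cavity method is a voxel flood fill, not an alpha-sphere
  druggability model; its volumes are for paired comparisons.
- Shell membership (first frame by default) can change per-residue
  tables for highly mobile ligands; the union mode exists for that case.
- Only orthorhombic boxes; DCD and (multi-model) PDB are the only
  trajectory formats.
- The synthetic generator makes no claim of physical realism (no
  integrator, no lipid phases, no cholesterol).
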