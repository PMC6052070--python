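# Methods

`saposim` models why a sea-cucumber (holothuroid) saponin permeabilizes
cholesterol-containing membranes but spares membranes built on the
holothuroid's own Δ7 sterol (5α-cholest-7-en-3β-ol).  The pipeline combines
four coarse computational stages — implicit-membrane insertion, interfacial
pair docking, a lattice monolayer Monte Carlo, and domain statistics — with
the arithmetic used to analyse the corresponding wet-lab assays (calcein
leakage, isothermal titration calorimetry).  This note records the models, the
parameters that matter, and the design decisions taken where the method
descriptions leave the details open.

## Molecules and parameterization

Molecules are ordered lists of parameterized atoms (or coarse beads): position
(Å), partial charge (e), van der Waals radius (Å), accessible surface S(i)
(Å²) and transfer energy E_tr(i) (kJ/mol).  Transfer energies are derived from
a per-element scale `etr_per_area` (kJ·mol⁻¹·Å⁻²) via E_tr(i) =
etr_per_area · S(i); carbon carries −0.105, oxygen +0.100 (the packaged table
`data/element_params.csv` is editable and per-atom overrides are accepted in
the CSV atom-table dialect).  Negative scales mark apolar atoms.  Accessible
surfaces are computed by a deterministic Shrake–Rupley construction (300
golden-spiral points per atom, probe radius 1.4 Å); an isolated atom recovers
the analytic 4π(r+1.4)² sphere.

Conformers are enumerated on a systematic torsion grid (offsets 0, step, …
applied per rotatable torsion to the input geometry), scored with an empirical
intramolecular energy — 6-12 van der Waals (well depth 0.4 kJ/mol, minimum at
σ = r_i+r_j), Coulomb with the distance-dependent dielectric ε(r) = 3r, a
threefold torsional barrier (V₀ = 0.5 kJ/mol), and a hydrophobic contact
reward — and sorted ascending.  Grid points where nonbonded atoms (graph
distance ≥ 3) come closer than 0.7·(r_i+r_j) are discarded as clashes; an
enumeration cap (default 5·10⁴) guards against combinatorial blow-up.  The
intramolecular hydrophobic weight (0.05) is deliberately much gentler than the
docking weight: inside one small molecule sterics dominate, and a
docking-strength contact term would collapse short chains into gauche knots.

Interface orientation aligns the axis from the hydrophobic (S·|etr|-weighted,
apolar atoms) centroid to the hydrophilic centroid with +z, hydrophobic side
down, and shifts the molecule so its overall amphiphilic balance point (the
S·|etr|-weighted mean over all atoms) sits at z = 0.  Molecules without
amphiphilic contrast get the identity transform and a warning.  The
interfacial area is the union of the atom disks whose centers lie within
±5 Å of the interface plane, projected with their vdW radii and rasterized at
0.05 Å; it is invariant (to raster tolerance) under rotation about z and
in-plane translation.

## Implicit-membrane insertion

The bilayer is the empirical hydration function

    C(z) = 1 − 1/(1 + exp(α(|z| − z₀))),   α = 1.99,

rising from ≈0 at the core (z = 0) to ≈1 in water.  The total thickness is
36 Å.  z₀, the polar-head/alkyl-chain interface, is not printed alongside the
method description; we use 13.5 Å, consistent with the original
parameterization of a 36 Å bilayer, and it is a constructor argument.

Two restraints score a pose: the hydrophobic restraint
E_pho = −Σ S(i)·etrᵢ·C(zᵢ) (apolar atoms pay to be hydrated, polar atoms are
rewarded) and the lipid perturbation restraint
E_lip = a_lip·Σ S(i)·(1 − C(zᵢ)) with a_lip = 0.018 kJ·mol⁻¹·Å⁻².  The
functional forms and a_lip are reconstructed from the method lineage rather
than printed in the source; the qualitative contracts (apolar matter prefers
the core, polar matter the water, amphiphiles the interface, symmetric
profiles, positive core energy for amphiphiles) are insensitive to the exact
constant, which is configurable.  a_lip is smaller than carbon's |etr| so that
purely apolar matter still prefers the core over water.

The insertion scan translates the center of mass from −36 to +36 Å in 1 Å
steps (18 Å of bulk water margin each side) and minimizes over an exhaustive
ZYZ Euler grid at each depth.  Because the restraints depend on atom depths
only through |z|, and the angular grid over full turns is closed under the
in-plane flip (β, α) → (180°−β, α+180°) that negates every atom's z offset,
the resulting profile is symmetric to machine precision — the numerical
realization of the mirror symmetry of the implicit bilayer.  Default angular
step: 30° (exhaustive) for tests and drivers; refining the grid can only
lower the profile.

## Interfacial docking and the interaction matrix

Both molecules are interface-oriented and stay so during the search: the pose
space is azimuthal position around the central molecule, radial distance
(2–12 Å in 0.5 Å steps), ligand spin about its own z, and a small vertical
offset (±2 Å) — a full SO(3) search would break the interface constraint the
method prescribes.  The coarse grid holds ~1.5·10⁴ poses (tests, drivers); the
production preset (72×72 angles, 40 radial, 49 vertical) exceeds 10⁷.

Pose energy = vdW (6-12 over heavy-atom pairs) + Coulomb (ε(r) = 3r) + the
hydrophobic contact term

    E_pho(i,j) = −w·(S_i|etr_i| + S_j|etr_j|)·min((σ/r)⁶, 1)   for apolar pairs
                 with r < σ + 1.4 Å,  σ = r_i + r_j,

with w = 0.40.  Two deliberate choices here.  First, the (σ/r)⁶ taper: a flat
contact step rewards glancing contacts as much as flush packing, which erases
the packing difference between an elongated sterol lying parallel to the
saponin's aglycone and a bent sterol that can only graze it; the taper makes
tight parallel packing win.  Second, the weight makes the hydrophobic
component dominate the breakdown, matching the observation that
saponin–lipid interactions at the interface are chiefly apolar.  Poses with
any atom pair closer than 0.7σ are rejected (energy sentinel +inf).

Energies are reported per heavy atom of the pair (divisor = heavy atoms of
both partners) so self- and cross-pairs of differently sized molecules are
comparable; a per-pair matrix entry is the average of the two best-pose
per-heavy-atom totals with the roles swapped, which symmetrizes grid
anisotropy exactly.  Greedy assemblies place ligands one at a time, each
taking the best pose that neither clashes with nor ignores the energetic field
of the previously placed ligands.

## Lattice monolayer Monte Carlo

A monolayer is a side×side grid (200 default, 100 in the replicate studies
below) with one molecule per cell, 4-neighbor coupling through the interaction
matrix, and periodic boundaries (clipped available for figure-matching).
Moves are global Kawasaki exchanges — any two cells of different type swap —
so the composition is conserved exactly; acceptance is Metropolis with a
dimensionless temperature in matrix-energy units (only ΔE/T matters; no
physical k_B is introduced for per-heavy-atom energies).  ΔE uses the eight
edges incident to the two cells; the edge joining adjacent swap partners is
invariant under the swap, so the local update is exact, and the incremental
energy matches a from-scratch recomputation to floating-point equality over
10⁶ moves.  Minimization is simulated annealing: a 12-stage geometric ladder
from T = 1.5 to 0.05 followed by a zero-temperature quench over the trailing
20% of proposals.  At fixed temperature the chain samples the exact Boltzmann
distribution (verified against a full enumeration of all C(9,4) states of a
3×3 two-type lattice).

Compositions: 67% phospholipid / 23% sterol / 10% saponin (the Methods-stage
ratio) is the default; the 63/27/10 ratio quoted with the results is shipped
as a named preset.  Counts use largest-remainder rounding so they sum exactly
to side².

## Domain statistics

Sterol domains are connected components of sterol-occupied cells;
8-connectivity and clipped boundaries by default, matching a particle analysis
run on the rendered image (one pixel per molecule), with 4-connectivity and
periodic boundaries available.  Whether saponin cells count toward sterol
domains is an explicit parameter (`target_types`); the default is sterol only.
Per replicate: relative mean size = mean domain area / total sterol area
(composition-independent), compared across systems by a Welch two-sample
t-test on the natural-log values — the log because replicate variances differ
strongly between systems, Welch for the same reason.  The test statistic and
Welch–Satterthwaite degrees of freedom are computed closed-form and verified
against an independent implementation to 1e-12.

## In vitro arithmetic

Calcein leakage: %L = 100·(F_t − F_contr)/(F_tot − F_contr) with methanol and
Triton X-100 controls; affine-invariant in the three readings; out-of-range
values are returned as-is and flagged.

ITC: lipid vesicles (syringe, mM; 10 µL injections) titrated into saponin
(cell, µM) at 26 °C.  After subtracting the two blank titrations element-wise,
heats are fitted with a lipid-partition model: bound saponin fraction
f = K[L]/(1+K[L]) with [L] the dilution-corrected total lipid, and injection
heat q_i = ΔH·n_sap·(f_i − f_{i−1}).  The instrument software's model is not
named in the source; a partition model is the appropriate default for
lipid-into-saponin titrations, a one-site variant is selectable, and constants
are comparable only model-to-model.  K is fitted on a log scale
(Levenberg–Marquardt); standard errors come from the Gauss–Newton covariance
with the delta method for K.  ΔG = −RT·ln(K·c°) uses the 1 M standard state
(K in mM⁻¹ × 1000) — the only convention that makes the logarithm
dimensionless, stated here because the source does not; TΔS = ΔH − ΔG.  The
package reports TΔS (kJ/mol) rather than ΔS.

## Synthetic data: what it does and does not emulate

The fixture molecules are idealized bead models, not sterols: an elongated
12-bead apolar rod with a polar head (cholesterol-like), the same bead
multiset bent 90° at mid-length into an "L" (Δ7-like — the two share a
"chemical formula"), a cone with a wide half-arc polar base over a 10-bead
apolar tail (saponin-like; the half-arc leaves one flank of the aglycone
accessible, as a single sugar chain would), and a two-tailed zwitterionic
phospholipid.  Their geometries were designed so that the documented ordering
contracts — footprint(Δ7) > footprint(cholesterol), E(sap,PL) < E(sap,chol) <
E(sap,Δ7) < 0, interfacial saponin optimum — are properties of the shapes, not
accidents of force-field constants; passing tests therefore demonstrate that
the pipeline propagates shape differences into the published orderings, not
that it reproduces any real molecule's energies.

The interaction-matrix scenarios encode the docking-stage orderings directly
(one physical matrix over DMPC/CHOL/DELTA7/SAPONIN; the two systems differ in
which sterol the composition selects), with strong cholesterol self-coupling
(−3.0 per heavy atom vs −1.0 DMPC–sterol, hence demixing) and weak Δ7
self-coupling (−1.3, hence scattered small clusters).  ITC traces come from
the same partition model the fitter assumes plus seeded Gaussian noise — the
round trip tests estimator correctness, not model adequacy.  Recovery studies
use K = 1.5 mM⁻¹, ΔH = −30 kJ/mol: with 5 mM lipid titrated into a 200 µL
cell, K[L] then sweeps the informative part of the isotherm (very large K
saturates the cell at the first injection and is identifiable only as a lower
bound — the package reports such fits honestly with large standard errors).
Leakage traces saturate exponentially (τ = 120 s) over 900 s.

## Problem sizes and numerics

The replicate monolayer study uses five 100×100 lattices per system with
4·10⁵ annealed proposals each, which reaches the energy plateau for these
matrices; the full 200×200 grid is a flag away and scales linearly in cells
and proposals.  Docking drivers and tests use the ~10⁴-pose coarse grid.
Raster tolerances: interfacial areas are accurate to ~0.5% at the 0.05 Å
pixel; SASA to ~1% at 300 sphere points.  Ties in docking are broken by grid
index, making results deterministic and oracle-comparable pose for pose.  All
randomness flows through per-call `numpy` generators seeded explicitly; no
global random state is touched.

## Limitations

No explicit lipids, curvature, leaflet asymmetry or translocation kinetics in
the insertion model; rigid-body docking of single conformers with no solvent
beyond the hydrophobic term and no affinity calibration; the lattice carries
no molecular orientation or off-lattice packing, and move counts have no
kinetic meaning; domain analysis measures area only.  The in vitro module
fits per-injection heats (no raw thermogram integration) and computes endpoint
leakage percentages (no kinetic modeling of the release curves).
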