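# Methods

`protpka` computes protonation and redox equilibria of coupled titratable
sites in a protein from a continuum-electrostatics model, and attributes the
resulting pKa shifts to individual residues and cofactors. This note records
the model, its numerical realization, the conventions that were genuinely
open choices, and what the synthetic test systems do and do not demonstrate.

## Electrostatic model

The protein is a low-dielectric body (relative permittivity eps_p = 4 by
default) embedded in solvent (eps_w = 80) with a 1:1 salt atmosphere at
ionic strength I (default 100 mM) and temperature T (default 300 K). The
electrostatic potential obeys the linearized Poisson–Boltzmann (LPB)
equation

    div( eps(r) grad phi(r) ) − eps_w kappa²(r) phi(r) = −4 pi l_B rho(r)

written in reduced units: phi in kT/e, charge in elementary charges, length
in Å, with l_B = e²/(4 pi eps0 kT) the vacuum Bjerrum length (≈ 557 Å at
300 K). kappa² = 8 pi (l_B/eps_w) n with n the total ion number density; at
100 mM and 300 K the Debye length is 9.74 Å.

### Discretization

Cubic, node-centered grids with odd point counts. Dielectric values live on
the six links of each node: the fraction of each link inside the van der
Waals union surface is estimated from a linear level-set (the signed
distance min_i(|x−c_i| − R_i) at the two end nodes) and the link dielectric
is the harmonic mean weighted by that fraction. This smoothing gives O(h²)
placement of the dielectric boundary, which is what makes the Born-sphere
test below pass at the sub-percent level. The molecular region is the vdW
*union*: overlapping atoms leave no interstitial solvent, and cavities left
by removed crystal waters are genuinely filled with eps_w (no patching).

Ions are excluded from a Stern layer of 2.0 Å beyond the vdW surface
(configurable; the screening term eps_w·kappa²·h² is applied only at
ion-accessible nodes). Point charges are spread to the eight surrounding
nodes trilinearly. Dirichlet boundary values on the box faces come from the
Debye–Hückel sum l_B q_i exp(−kappa r)/(eps_w r).

### Solver

Successive over-relaxation with red–black ordering; omega = 2/(1 +
sin(pi/n)); relative-residual stopping criterion (default 1e-6) checked
every 20 sweeps; maximum 10^4 iterations, with the residual history attached
to any non-convergence error. The inner sweep has two implementations: a
vectorized numpy reference and a fused compiled kernel (numba) used when
available; both perform the identical red–black update. Because same-color
nodes never neighbor each other the update is order-independent within a
color, so the two paths agree to rounding.

### Grid focusing

The default cascade solves at 2.5, 1.0 and 0.3 Å. All levels are centered on
the focus site; the coarsest spans the whole structure plus a 20 Å margin,
the finest spans the site plus 10 Å, intermediate extents interpolate
geometrically, and every level's point count is capped (default 81) and
recorded. Finer levels take both their Dirichlet boundary and their initial
guess from trilinear interpolation of the level above. Potentials are
evaluated on the finest level containing the query point, falling back to
coarser levels (with a warning) for distant partners.

### Validation oracles

* Born sphere: the transfer energy of a unit charge in a 2 Å sphere between
  eps = 4 and eps = 80 surroundings, (q²l_B/2r)(1/4 − 1/80) ≈ 33.07 kT,
  is reproduced by the 3-level focused solver to 0.23%.
* Screened Coulomb at 100 mM: ≤ ~3% at r ≥ 3 grid spacings on a 1 Å grid.
* Superposition holds to 1e-10 (relative) when converged to 1e-12.
* At I = 0 the screening term is identically zero, so the LPB operator *is*
  the Poisson operator.

## Charge model

A compact polar-hydrogen charge set (CHARMM22-informed; version
`compact-1.0`, shipped as a flat table) with PARSE-style element-keyed radii
(H 1.0, C 1.7, N 1.5, O 1.4, S 1.85 Å). Apolar hydrogens are subsumed into
heavy-atom radii. The choice of radius set is a genuine unknown of this kind
of calculation and bounds absolute accuracy; it is configurable and the
charge-set version is recorded in every run manifest.

Protonation-state bookkeeping uses smeared protons:

* carboxylate protonation adds +0.5 e to each of the two oxygens;
* ammonium/guanidinium deprotonation removes 1/n e from each of the n
  protons, which stay in place;
* the photo-oxidized cofactor pair carries a +1 hole split between the two
  macrocycles at a fixed ratio (default 2:1, the nearer ring taking the
  larger share), spread uniformly over each ring's atoms;
* phenol/thiol deprotonation zeroes the hydroxyl/thiol proton charge (a
  "ghost" proton that keeps its position for state-difference bookkeeping
  but is invisible to H-bond analysis and steric scoring).

Reference pKa values: Arg 12.0, Asp 4.0, Cys 9.5, Glu 4.4, Lys 10.4,
Tyr 9.6; His is two proton-binding subsites with references 7.0 (N-epsilon)
and 6.6 (N-delta). Redox sites use a reference midpoint in mV and the Nernst
constant ln10·kT/e (59.6 mV per pK unit at 300 K).

### Histidine

His is modeled as coupled N-delta and N-epsilon subsites whose neutral
reference microstate is the N-delta tautomer. The doubly-deprotonated
imidazolate is suppressed by a +30 pK penalty. Two deliberate conventions:
(i) the *intramolecular* subsite coupling is excluded from the interaction
matrix because the measured microscopic reference values already contain the
tautomer energetics; (ii) a subsite's pKa is titrated with its sibling
clamped protonated, i.e. it is the microscopic pK of the His⁺ deprotonation
at that nitrogen — the convention under which the reference values are
defined, and the only one that lets an isolated imidazole return them
exactly.

## Statistical mechanics

Each site i has a binding indicator x_i (1 = proton bound; for redox sites
1 = electron bound/reduced). A microstate has energy

    E(x)/kT = ln10 [ Σ_i x_i (driv_i − pK_intr,i − bias_i)
                     + ½ Σ_{i≠j} W_ij t_i t_j ] + penalties,

where driv is pH (or E_h/59.6 mV for redox sites), t_i indicates the charged
(non-reference) form and W_ij is the site–site coupling in pK units,
computed as the interaction of the two sites' charging vectors through the
focused potentials and symmetrized by averaging the two reciprocity
estimates (asymmetry before averaging is reported; it stays below 0.05 pK on
the finest grids). With this sign bookkeeping two acids repel (W > 0) and an
acid–base pair attracts (W < 0) automatically.

The intrinsic pK is pK_ref + [ΔG_release(protein) − ΔG_release(model)]/ln10,
with ΔG_release = ½Δq·Φ(Δq) − q_bound·Φ(Δq) − q_bg·Φ(Δq) evaluated from a
single solve per context for the binding charge difference Δq. The model
context is the site's residue alone in solvent *on identically placed fine
grids*, which cancels the grid self-energy exactly; a model compound run in
pure water therefore returns its reference value to machine precision, and
the bias titration recovers it to the bias-search resolution (0.01 pK).

Sampling: exact enumeration up to 2^20 microstates (the oracle and the
default for ≤ 14 free sites), otherwise Metropolis Monte Carlo with
single-site moves plus joint moves for strongly coupled pairs (|W| > 2 pK)
and His subsite pairs; default schedule 100 burn-in + 10^4 sweeps, seed
mandatory, acceptance rate and schedule reported. Fixed seeds give
bit-identical means.

pKa values come from bias titration: bisection on a per-site bias until both
forms are equally populated (|mean − ½| at a bias grid of 0.01 pK), all
other sites re-equilibrating at every bias, each bias evaluation drawing a
deterministically derived MC seed. The reported value is **pKa = pH −
bias**, with a positive bias favoring the bound form; the sign pair was
fixed by requiring the single-site closed form (half-titration of a pKa-9.6
site at pH 7 needs a bias of −2.6) to come out right.

## Decomposition

In the linear-response model the background contribution to a target's pKa
decomposes exactly over groups: each contributes −(1/ln10) Σ_a qbar_a
phi_Δq(r_a) pK units, with qbar the group's equilibrium-averaged charges
(fractional occupancies from the sampled pattern; a frozen most-probable
pattern is available as an option) and positive values stabilizing the
protonated target. Residue rows split into side chain and backbone
(N, H, CA, HA, C, O); cofactors and waters are reported as totals. With the
pattern frozen, reference + desolvation/model term + Σ contributions equals
the directly titrated pKa (asserted to 0.3 pK on toys; the residual is
bias-search and interpolation noise).

## Hydrogen placement

Crystal structures at ~3 Å do not resolve protons, and force-field
minimization is outside this package's scope. Polar hydrogens are built at
ideal internal coordinates; rotatable groups (Ser/Thr/Tyr hydroxyls, Cys
thiol, Lys ammonium, water) are then oriented by a deterministic 15° grid
search scoring bare Coulomb interactions plus a distance-weighted H-bond
well toward N/O/S acceptors, with a 1.15 Å steric cutoff (transparent to
ghost protons). Heavy atoms are never moved. This is an idealized-geometry
approximation: it reproduces donor-direction physics (a hydroxyl next to a
phenolate donates into it) but can shift absolute pKa values by up to a few
units relative to a minimized-hydrogen treatment, which is part of why
absolute values carry a ±2 pK band while state-to-state differences are
tighter.

H-bond edges: donor→acceptor when d(H···A) ≤ 2.5 Å and the D–H···A angle is
≥ 120°; heavy-atom distances are attached to every edge for comparison with
crystallographic O···O / O···N separations. Hydrogens carrying less than
0.05 e are not donors (smeared-proton convention).

## Synthetic fixtures

`make_model_compound` builds capped single residues; `make_toy_multisite`
places single-atom acid/base/redox sites at controlled separations with
seeded perpendicular jitter (which can only increase pairwise distances) and
bundles closed-form screened-Coulomb coupling expectations that are
recomputed from the stored geometry on every use (fixture-rot guard).

`make_mini_rc` is a ~1100-atom bundle emulating the buried-phenol motif: a
tyrosine whose side chain has three altloc conformers with hydroxyl-O at
exactly 4.4 / 3.3 / 2.7 Å from a threonine hydroxyl (a dark / light /
relaxed-deprotonated geometry ladder), a histidine, an aspartate ~6 Å from
the phenol, one retained crystal water on the reachable H-bond cone of the
dark hydroxyl, two 12-carbon cofactor rings at ~7 and ~13 Å that accept the
2:1 hole, and a lattice ball of uncharged carbons (2.2 Å spacing, tight
enough that the vdW union has no solvent channels) providing the
low-dielectric interior. Layout clearances are asserted at build time; the
same seed regenerates a bit-identical PDB.

What the bundle demonstrates: the photo-hole strictly lowers the phenol pKa
(the full battery prints 11.6 → 6.7 between the neutral-dark and
hole-relaxed states at seed 1); the relaxed geometry with the hydroxyl
partner donating into the phenolate lowers it further; and the H-bond
direction around the phenol flips on deprotonation. What it does not
demonstrate: real-protein magnitudes or orderings that depend on the actual
fold — e.g. in the bundle the *light* conformer's pKa is slightly above the
dark one's, because at 3.3 Å the protonated phenol gains a strong donated
H-bond to the threonine oxygen that outweighs the acceptor-side relaxation,
and the retained water stabilizes the protonated form in the dark state
rather than the anion. Passing these tests shows the machinery and sign
conventions are right, not that any particular protein's values are.

## Problem sizes and tolerances used in the shipped analyses

Focusing levels 2.5/1.0/0.3 Å with an 81-point cap for the bundle and Born
validation; 1.5/0.5 Å with a 53-point cap for model compounds and toy
systems, where context cancellation or closed-form comparisons make finer
grids unnecessary. Monte Carlo: 4000–20000 sweeps in tests and analyses.
Solver tolerance 1e-6 (1e-12 for the superposition check). These sizes are
the package's default desk-scale choices; all are configurable.

## Known limitations

* No conformational sampling coupled to titration; conformers are explicit
  named states.
* Nonlinear PB, membrane slab dielectrics and multigrid beyond focusing are
  out of scope.
* The charge set is compact rather than a full force-field set; cofactor
  charges beyond the uniform-ring hole model must be supplied as tables.
* Absolute pKa accuracy is bounded by the hydrogen-placement approximation
  and the radius set, both documented above; state-to-state differences
  cancel much of this.
* Titrating a real membrane-protein structure additionally requires its
  cofactor charge tables and minimized alternate-geometry coordinates as
  inputs; residues without library entries must be explicitly waived (they
  then contribute no charge, only their dielectric volume).
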