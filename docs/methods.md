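# Methods

## The problem

The absolute binding free energy of a protein–protein dimer is hard to
compute directly: the physical binding path of two fully flexible monomers
converges far too slowly.  The strategy implemented here replaces the real
binding process with a fictitious thermodynamic cycle built from three
steered processes on a restrained copy of the system:

* **A** — in the unbound state, ramp every restraint force constant from its
  stiff value down toward zero ("release"), giving ΔF_A;
* **B** — with all restraints stiff, pull the monomer–monomer
  center-of-mass (COM) distance along a fixed x axis from the unbound
  separation to contact, giving the binding profile and ΔF_B;
* **C** — release the restraints in the bound state, giving ΔF_C.

Closing the cycle,

    ΔF = −ΔF_A + ΔF_B + ΔF_C + ΔF_V + ΔF_R,

where ΔF_V converts the volume the restrained unbound monomer can explore
into the standard-state volume V₀ = 1661 Å³ and ΔF_R accounts for the
orientational freedom suppressed by the bound-state restraints.  Each stage
free energy comes from repeated nonequilibrium steered simulations via the
Jarzynski equality, exp(−βΔF) = ⟨exp(−βW)⟩.

This package implements the full machinery — restrained steered Langevin
dynamics, work bookkeeping, the Jarzynski estimator with bootstrap errors,
the cycle assembly with both corrections — and validates it on toy dimers
whose binding free energy has an *exact* quadrature oracle.  Protein-scale
simulation (explicit solvent, all-atom force fields) is out of scope.

## Units and constants

kcal mol⁻¹, Å, ps, amu, K throughout; k_B = 0.0019872 kcal mol⁻¹ K⁻¹;
1 kcal mol⁻¹ = 418.4 amu Å² ps⁻².  All default temperatures are 298 K
(k_BT ≈ 0.5922 kcal mol⁻¹).

## The restraint vocabulary

A `RestraintSet` holds the eleven-restraint scheme used for restrained
dimer binding:

1. one **CV spring** ½k(ξ−λ)² on the collective variable ξ = |X_com(I) −
   X_com(II)| (mass-weighted monomer COMs, x components only);
2. two **shape restraints**, one per monomer: ½k·Σᵢ‖(rᵢ−c) − (rᵢʳᵉᶠ−cʳᵉᶠ)‖²
   with c the monomer centroid.  Translation is removed but there is *no*
   rotational superposition: rigid rotation is already pinned by the point
   restraints, so a fitted RMSD restraint would be redundant and its
   gradient far more expensive.  This is a deliberate simplification;
3. two **planar restraints** ½k(Δy²+Δz²) on each monomer COM, keeping the
   binding axis on x;
4. six **single-bead point restraints** in the line-fix / z-fix / y-fix
   pattern (two beads pinned in y and z, two in z only, two in y only),
   suppressing rigid rotation of each monomer while leaving x translation
   free;
5. optionally a **flat-bottom umbrella** on the radial COM distance with
   knots r₁ ≤ r₂ ≤ r₃ ≤ r₄: zero on [r₂,r₃], parabolic on the shoulders,
   linear beyond r₁/r₄ with the slope frozen at the outer knots (the common
   MD-restraint dialect; only the knots are prescribed, so the tail shape
   is a package choice).

The default force constant is 50 kcal mol⁻¹ Å⁻².  One `Schedule` per run
drives either the CV-spring center ("center", pulls) or a global scale on
every force constant ("force-constant", releases), linearly: λ(t)=λ₀+vt.
Scheduling the set rather than one restraint reflects that a release ramps
all restraints simultaneously.

## Dynamics and work

The integrator is the BAOAB splitting of Langevin dynamics; with zero
friction and temperature it reduces to velocity Verlet (energy conserved to
O(dt²), verified).  The default dt = 0.002 ps resolves the stiffest default
mode (ω ≈ 42 ps⁻¹ for k = 50 on 12 amu) with ω·dt ≈ 0.08.

Work follows the discrete-protocol convention: each step the scheduled
parameter jumps at frozen coordinates, accumulating
dW = V(r; λ_{t+dt}) − V(r; λ_t), then the system propagates at the new
parameter.  This discrete work enters the Jarzynski average exactly for the
simulated Markov chain; its dt→0 limit is −k(ξ−λ)·v·dt for center steering
and ½(ξ−λ)²·dk per ramped restraint for force-constant steering.  Work is
recorded on a uniform grid of the driven quantity (default bins 0.1 Å or
0.5 kcal mol⁻¹ Å⁻²).

Each trajectory draws noise from `default_rng([master_seed, index])`, so
trajectory i is bit-for-bit reproducible regardless of ensemble size.

## Estimation

The Jarzynski estimate is −(1/β)·log-mean-exp(−βW) with max-shift; naive
exponentials overflow near βW ≈ 700, so the shifted form is mandatory.
Errors are bootstrap standard deviations over trajectories (default 1000
resamples), reported as 1 SD; whether published ± values of this kind are
SD or SEM is generally unstated, so the convention is documented here and
used consistently.  Profile errors are pointwise (no cross-λ covariance),
sharing one resample-index matrix across grid points so bands are smooth.
The bound-state free energy ΔF_B is read at the *profile minimum*, not at
the schedule endpoint — pulling deliberately overshoots the well so the
minimum is interior (ties break toward the schedule end).

Cycle uncertainty is independent-Gaussian quadrature of the three simulated
stage errors only; the corrections are treated as exact.  (On the published
insulin components, √(0.89²+0.95²+0.53²) = 1.41 reproduces the printed ±,
which is what motivates this convention.)

## Corrections

With spans measured from restrained trajectories (max−min of the COM
distance components in the unbound state; max |y|, |z| deviations in the
bound state; r_b the mean radial COM distance):

    ΔF_V = k_BT · ln( V₀ / (Δr_x,u · Δr_y,u · Δr_z,u) ),   V₀ = 1661 Å³
    ΔF_R = −k_BT · ln( 4 r_b² / (Δr_y,b · Δr_z,b) )

ΔF_V is positive whenever the restrained unbound volume is smaller than the
standard-state volume (it always is, for stiff restraints); ΔF_R compares
the transverse patch the restrained bound monomer occupies (an ellipse with
semi-axes Δr_y,b, Δr_z,b at radius r_b) with the full orientational sphere
4πr_b², and is negative for tight restraints.  Because steering runs along
a fixed Cartesian axis, no Jacobian correction applies to the profile.

Span-based volume estimates are range statistics: they carry an O(1)
multiplicative convention (the range of a sampled Gaussian is a run-length-
dependent multiple of σ).  The corrections are therefore validated against
Gaussian-range statistics and sign/derivative identities, not against the
exact oracle — see "What the toys do and do not show".

## The toy dimers and their oracles

`make_toy_dimer` builds two rigid-ish bead clusters (default 3 beads per
monomer, 12 amu each, harmonic intra-monomer bonds) carrying the full
eleven-restraint set, starting at an unbound COM distance of 9 Å.  The
attractive interface is an LJ-form well U(ξ) = 4ε[(σ/ξ)¹² − (σ/ξ)⁶] acting
on the COM x-distance ξ itself (default ε = 3 kcal mol⁻¹, σ = 3 Å, minimum
at 2^{1/6}σ ≈ 3.37 Å).  Making the interface a function of the steering
coordinate alone is the key design choice: every transverse and internal
degree of freedom then contributes *identically* to the bound and unbound
end states and cancels exactly in the cycle sum, so the toy's binding free
energy reduces to one-dimensional quadrature and the oracle is exact, not
approximate.  A conventional bead-pair LJ interface ("pair") is also
implemented for force tests.

Releases end at k_end = 0.5 kcal mol⁻¹ Å⁻², not 0: a fully released free
particle has no normalizable state, so "flexible" is represented by a weak
residual spring present identically in both released end states (and in
the oracle).  `exact_free_energy_1d` integrates e^{−βU} over bound/unbound
windows by Simpson's rule with a Richardson-style error estimate from grid
halving (non-convergence raises); `toy_cycle_oracle` applies the same
quadrature to the two released end-state potentials.

Closed forms used as independent references: harmonic force-constant change
ΔF = (n/2)k_BT ln(k_to/k_from); Gaussian work ensembles ΔF = μ − βσ²/2;
equipartition var(x) = k_BT/k; free-energy perturbation for instantaneous
k-jumps.

## Protocol sizes and convergence

The converged ("slow") tier uses: pull speed 0.05 Å ps⁻¹ (9 → 3.2 Å,
116 ps), release ramps 50 → 0.5 over 250 ps, 40 trajectories per process,
friction 1 ps⁻¹, 5 ps equilibration per trajectory.  These sizes were
chosen so that the linear ramp stays adiabatic relative to the slowest
relaxation time at the soft end of the ramp (≈1 ps at k = 0.5) with an
order-of-magnitude margin; the whole three-process cycle then runs in a few
minutes on one core.  Speed tiers at 10× and 100× deliberately violate
adiabaticity, and the cycle-closure gap shrinks monotonically from ~1.9 to
~1.4 to ~0.14 kcal mol⁻¹ across 100×/10×/1× (see
`analysis/04_speed_convergence.py`).

## What the toys do and do not show

Passing the closure test demonstrates that the steering, work bookkeeping,
estimator and cycle algebra are mutually consistent and converge to the
exact answer as driving slows.  It does not demonstrate that a protein
system's force field, sampling, or restraint choices are adequate — the
toys have no solvent, no conformational substates, and relaxation times in
picoseconds rather than nanoseconds.  Two further caveats:

* the corrections: for the axial-interface toy the *unrestrained* bound
  dimer has no finite orientational volume (the interface does not confine
  transverse motion), so ΔF_V/ΔF_R have no exact toy reference.  They are
  computed from measured spans, validated for sign, scaling and
  range-statistics magnitude, and reported alongside the closure — but the
  pass/fail closure identity is the corrections-free one, where both sides
  describe exactly the same pair of end states.  r_b is measured from the
  weakly restrained bound run for the same reason.
* structure fixtures plant idealized ring/donor geometries with exact
  values; they exercise detector thresholds and bookkeeping, not the
  statistics of real conformational ensembles.

## Structural analyzers

SASA is Shrake–Rupley sphere sampling (default probe 1.4 Å, 960 points per
atom) with Bondi van-der-Waals radii (H 1.20, C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, F 1.47, Cl 1.75, Br 1.85, I 1.98, Zn 1.39 Å); an element
outside the table is an explicit error.  The engine is Bio.PDB's
implementation supplied with this radii table; isolated-sphere and
two-sphere spherical-cap closed forms serve as independent checks (≤2% at
960 points).

π–π detection uses ring centers (mean of the six ring-carbon coordinates of
Phe/Tyr) and ring normals from the smallest singular vector of the centered
ring coordinates (robust to slight non-planarity).  Thresholds are strict
inequalities exactly as printed: distance < 7.2 Å, parallel < 30°, T-shaped
> 50°, the 30–50° band rejected; boundary values do not fire.  Hydrogen
bonds: O–N < 3.0 Å and donor–H–acceptor angle > 135°, donors being
nitrogens with a hydrogen within 1.25 Å; when a structure carries no
hydrogens an ideal H is placed at 1.01 Å opposite the bisector of the
nitrogen's heavy neighbors (each placement logged; donors with no usable
geometry are skipped with a warning count).  Residue numbering follows the
PDB file as-is; chain groups default to splitting the sorted chain list in
half and can be given explicitly.

Alanine truncation keeps the backbone (N, CA, C, O, OXT and backbone
hydrogens) plus Cβ, renames the residue to ALA, and leaves every other
residue untouched; an existing alanine is a rename-only no-op (stripping
"sidechain" atoms would delete its own Cβ hydrogens and break idempotence),
and glycine raises because it has no Cβ.  The nonpolar solvation term is
G_np = 0.0072 × SASA.

## Known limitations

* No explicit solvent, periodic boundaries, constraints (SHAKE-like), or
  protein force fields — toy systems only.
* Cumulant/fluctuation-theorem estimator variants beyond plain Jarzynski
  are not implemented.
* Polar (Poisson–Boltzmann/GB) solvation, entropy decompositions and
  secondary-structure assignment are out of scope; only the nonpolar SASA
  term and the mutant builder from that workflow are provided.
* The flat-bottom umbrella participates in the restraint vocabulary and the
  fixed-distance analysis runs, but the default cycle protocol defines its
  end states with the residual weak spring instead.
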