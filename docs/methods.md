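# Methods

This note records the models implemented in `barmech`, the numerical
choices behind the solvers, the default parameters and why they were
chosen, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Electric double layer

### Model

The electrolyte is a lattice of `n_s` sites per unit volume shared by
monovalent anions and cations (bulk density `n_0` each) and water dipoles
(bulk density `n_0w = n_s − 2 n_0`, dipole moment `p_0`). The mean-field
free-charge density and relative permittivity follow from the lattice
statistics:

    rho_free(phi, E) = −2 e0 n_s n_0 sinh(e0 phi beta) / H(phi, E)
    eps_r(phi, E)    = 1 + n_s n_0w p_0 F(p0 E beta) / (eps0 E H(phi, E))
    H(phi, E)        = 2 n_0 cosh(e0 phi beta) + n_0w sinh(u)/u,  u = p0 E beta

`H` is the local partition-like normalization: counterion crowding
(`cosh`) and dipole alignment (`sinh(u)/u`) both deplete the remaining
species. Two saturation effects follow, and both are exercised by tests:
the counterion density is bounded by `e0 n_s` (steric/Bikerman limit) and
`eps_r` decreases monotonically with `E` at fixed `phi` (dielectric
saturation).

`n_s` is always derived as `n_0w + 2 n_0` and never user-set; exposing it
independently invites inconsistent lattice bookkeeping.

### Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| salt concentration | 0.15 | mol/l | physiological monovalent salt |
| water concentration | 55 | mol/l | pure-water molarity |
| water dipole moment `p_0` | 4.79 | debye | standard value in this model family; treated as an effective parameter (it may represent a small water cluster); clustering itself is not modelled |
| temperature | 298 | K | room temperature; with the defaults above it reproduces a bulk permittivity of 78.4, matching the conventional 78.5 within 0.2 % |
| surface charge `sigma` | 0.2 | As/m² | typical of the concave binding face of a BAR domain |
| ordered-layer thickness `a` | 0.32 | nm | one water-diameter-scale layer of strongly oriented water |

Validity: `|sigma| <= 1 As/m²` is enforced; beyond that the lattice
model's assumptions (point dipoles, mean field) degrade and the solvers
refuse to run.

User-facing units are mol/l, debye, As/m² and nm; everything internal is
SI, with pure, round-trip-tested converters in `barmech.constants`.

### Numerical evaluation of the constitutive functions

* `L(u) = coth(u) − 1/u` cancels catastrophically for small `u`; below
  `u = 0.02` a three-term odd series (`u/3 − u³/45 + 2u⁵/945`) is used.
  At the crossover both branches are accurate to better than 1e-12
  relative (the tests compare against a 50-digit mpmath oracle over
  `u ∈ [1e-8, 50]` at 1e-10 relative tolerance).
* `F(u) = L(u) sinh(u)/u` uses the matching series `u/3 + u³/30 + u⁵/840`
  below the same switch and log-domain evaluation above `u = 350`, where
  `sinh` would overflow; ratios such as `F/H` are formed by dividing
  numerator and denominator by `sinh(u)/u` so the permittivity and charge
  density remain finite at arbitrarily large fields.
* The `E → 0` limit of `eps_r` is taken analytically
  (`1 + n_0w p_0² beta / (3 eps0)` at `phi = 0`); a test checks the
  pointwise expression at `E = 1 V/m` agrees to six significant figures,
  so the implementation is continuous at the limit.

### Planar solver

Finite volumes on a geometrically graded 1-D grid (first cell 0.005 nm at
the charged surface, ~400 nodes over 15 Debye lengths by default). The
surface carries the Neumann condition `eps0 eps_r(0) phi'(0) = −sigma`;
the far boundary is Dirichlet `phi = 0`, a documented approximation of
the bulk condition whose insensitivity is tested by doubling the domain.

Two nested iterations:

* **outer (permittivity) iteration** — start from constant bulk `eps_r`,
  re-solve, recompute `eps_r(x)` from the newest `(phi, E)`, under-relax
  with factor 0.5, stop when the relative sup-norm update falls below
  1e-6. The field magnitude entering `H` is frozen at the previous outer
  iterate, which keeps the inner problem local in `phi`.
* **inner (Newton) iteration** — damped Newton with backtracking line
  search on the finite-volume residual, tridiagonal Jacobian, residual
  tolerance 1e-10 (relative to the imposed surface-charge flux scale).
  `d rho/d phi < 0` everywhere, so the Jacobian is strictly diagonally
  dominant and the damped iteration is robust from the zero initial
  guess.

The reported surface field is taken from the Neumann condition itself
(`sigma / (eps0 eps_r(0))`, self-consistently with the converged
permittivity) rather than from a one-sided difference, which would lag
the steep near-surface decay at first order in the cell size.

Checks built into the test suite: total electroneutrality of every
converged profile to 0.1 %; grid-refinement stability of the surface
potential to 0.1 % under node doubling; exact reduction to the closed
Gouy–Chapman solution (< 1 %) when the permittivity is frozen at the bulk
value and the steric denominator is replaced by `n_s`.

`surface_layer_permittivity` reports both the contact value `eps_r(0)`
and the arithmetic mean over `[0, a]`, because "the" ordered-layer value
of a continuously varying profile is convention-dependent; the contact
value is the one that matches the conventional step height (≈ 55 at
`sigma = 0.2 As/m²`), while the layer average is substantially higher
(≈ 70) since the profile recovers quickly.

### Arc (2-D) solver

The BAR binding face is a uniformly charged circular arc of radius `R`
and fixed arc length `L_0` in a 2-D cross-section (the rod axis is
translationally invariant; the arch geometry, not the full 3-D protein,
is the model). The permittivity is a step function: `eps_ord` within
distance `a` of the concave face, bulk `eps_b` elsewhere. The probe
("point 1") sits on the symmetry axis at distance `d` from the concave
midpoint; `d` is a free geometric parameter fixed at 0.5 nm by default,
and all monotonicity properties are asserted at fixed `d` (whether the
probe should instead sit at a fixed absolute position as `R` varies is
unknowable from the arch drawing alone; fixed surface distance is the
choice made here and used consistently).

Discretization decisions, each of which proved load-bearing:

* **Charge as a deposited line source.** The surface charge enters as
  `sigma · ds` deposited bilinearly onto the control volumes crossed by
  the arc — the weak (integrated) form of the flux-jump condition across
  a charged interface.
* **Ion-free protein body.** A band of thickness 1 nm (fixed physical
  thickness, independent of the mesh) and permittivity 2 sits behind the
  convex face, and ions are excluded from everything behind the charged
  line. Without it, electrolyte on both sides of the line would swallow
  roughly half the flux (and a saturated counterion film would form
  behind the line), and the flat-arc limit could never match the planar
  solver. With it, a nearly straight arc reproduces the planar profile
  with the same step permittivity to within ~4 %.
* **Mesh alignment.** Axes are tensor-product grids, uniform at
  `h = a/8` near the arc (validated hard limit `a/4`), geometrically
  coarsened (ratio 1.2, cap 0.4 nm) to the outer boundary ≥ 10 Debye
  lengths away. Fine nodes sit on exact multiples of `h`, so meshes for
  different radii share the node layout near the probe; otherwise
  half-cell jitter of the deposited charge (~5 % in the probe field)
  swamps the few-percent physical `R`-dependence.
* **Accuracy.** The immersed-line discretization is first-order: halving
  the cell size from the default moves the probe field by < 2 %
  (measured in the tests); the remaining bias is a sub-cell shift of the
  effective surface position common to all radii in a scan.

Two charge-density modes: `full` (complete Langevin–Bikerman density,
solved by the same frozen-field Newton scheme as the planar solver) and
`linearized` (`sinh → identity`, `H → n_s`; a single Debye–Hückel-like
linear solve). The field at the probe **rises strictly with `R`** in the
full mode at the reference conditions — the model's curvature-sensing
signature: flatter faces keep more charged surface within a Debye length
of the probe. The linearized mode genuinely reverses this trend (a
concave surface wraps slightly around the probe, and in a linear screened
theory that raises the field as `R` shrinks); saturation and steric
crowding in the full model overcome that geometric effect. The
monotonicity property therefore belongs to the full mode only, which is
the default; the linearized mode is retained as the fast, small-potential
expansion.

## Bending energetics

### Flexible rods

`curvature_seen`, `protein_energy`, `protein_energy_orient` and
`optimal_orientation` implement the orientation-dependent rod energy; the
oriented form is computed *as* the composition of the curvature map and
the quadratic energy, and a test asserts the explicit
`(K_p L_0/2)(H − C_p + D cos 2ω)²` formula agrees to round-off on
randomized inputs. `optimal_orientation` is analytic: interior minimum
`cos 2ω* = (C_p − H)/D` with zero energy when `C_p` is within
`[H − D, H + D]`, boundary minima `ω* = 0` or `π/2` otherwise, ties
resolved toward the smaller non-negative angle, `ω* = 0` by convention
for isotropic patches (`D = 0`). A dense two-stage grid search over `ω`
serves as the independent oracle.

### Rigid rods

`rigid_tube_c1` inverts `C_p = C_1 cos²ω` using the half-angle form
`cos²ω = (1 + cos 2ω)/2`, which is exact in floating point at the special
orientations 0, π/4 (`C_1 = 2 C_p`) and π/3 (`C_1 = 4 C_p`). At
`ω = π/2` the rod lies along the tube axis and no longer constrains the
curvature; this is signalled, not silently clamped.

### Membrane energy and the deviatoric coupling area

The bilayer energy is evaluated in closed form on cylinders and spheres.
The printed deviatoric term `ln 2 cosh(D_eff D)` has a dimensionally
inhomogeneous argument (`D_eff·D` carries 1/m²); published variants of
this orientational-ordering theory carry a molecule-scale coupling
constant there, so the implementation makes it explicit:
`ln 2 cosh(ℓ² D_eff D)` with `ℓ² = 1 nm²` by default. All qualitative
properties asserted in the tests (monotonicities, limits, scenario
orderings) are invariant to the value of `ℓ²`.

No elastic moduli are printed in the source theory; the default fixtures
(`k_c = 20 kT`, `K_p = 10–10⁴ kT·nm`, `L_0 = 15–20 nm`,
`m_0 = 1.6·10¹⁸ m⁻²` ≈ one lipid per 0.6 nm² counting both leaflets) are
package fixtures at textbook magnitudes, not source values, and are
marked as such wherever they appear.

### Tube equilibria and parameter regimes

`equilibrium_tube_radius` minimizes the per-area energy
`W_b(cylinder)/A + coverage · min_ω E_p` over `R` (log-grid scan plus
bounded refinement). Two distinct regimes matter, and the tests choose
them deliberately:

* **Membrane-dominated:** a strong lipid deviator
  (`m_0 kT ℓ⁴ D_eff² / 2 > k_c`) gives the bare membrane a finite
  preferred tube radius; with `D_eff = 6 nm⁻¹` this sits at a few nm and
  is verified against a dense grid scan.
* **Protein-capped:** with a weak deviator the membrane alone prefers
  the flat limit (signalled as "no interior minimum" when `coverage = 0`
  and the deviatoric term is absent), and stiff, densely adsorbed rods
  cap the tube near `1/C_p`. The equilibrium radius is then monotone
  non-increasing in `C_p` — the mechanism by which inclusions with
  smaller intrinsic curvature produce wider tubes. The residual
  flattening `C_p − 1/R*` scales as `k_c/(R* · coverage · K_p L_0)`, so
  the "cap" is exact only asymptotically; tests assert it at the 1 %
  level under `K_p = 10⁴ kT·nm`, `coverage = 10¹⁷ m⁻²`.
  With a strong deviator this ladder degenerates (the membrane term pins
  `R*` below every `1/C_p`), which is why the monotonicity tests use
  `D_eff = 0`.

### Packing scenarios

`packing_scenarios` compares three stylized arrangements at each rod
density: dispersed (tube at `1/C_p`, optimal `ω`, no contacts), ring
(`ω = 0`, one contact per rod), spiral (`ω = π/4`, tube curvature
`2 C_p`, two contacts per rod). Per-rod energy = rod strain + membrane
energy of the rod's area share (`1/density`) + contacts × interaction
energy. At zero contact energy the dispersed and ring configurations are
exactly degenerate (both strain-free on the `1/C_p` tube); ties resolve
in the order dispersed → ring → spiral, standing in for the
configurational-entropy preference that is not modelled explicitly (no
mixing-entropy formula is part of the implemented theory — see
limitations). Strong end-to-end attraction at high density flips the
minimum to the spiral, whose membrane penalty per rod vanishes as the
area share shrinks.

## Scenario layer

Configurations are single YAML mappings (electrolyte block + one task
block) validated with field-path-named errors. `builtin_scenarios()`
provides `planar_reference` and `arc_scan` — the reference study
conditions above; every default not fixed by those conditions
(temperature, arc length `L_0 = 15 nm` chosen as a typical BAR-domain
length, probe distance `d = 0.5 nm`) is listed under `assumed` and
flagged in the run manifest. Runs are deterministic: the same config
yields byte-identical CSV output, and the manifest records every resolved
parameter plus convergence statistics.

## Problem sizes

Default solves are sized for interactive use on one CPU: the planar
profile (400 graded nodes, 27 outer iterations at `sigma = 0.2 As/m²`)
takes well under a second; one full-mode arc solve at the reference
conditions uses 2–6·10⁴ mesh nodes and a few seconds; the six-point
radius ladder completes in under a minute.

## Limitations

* Monovalent symmetric electrolytes only; no Stern layer, dispersion
  forces, or ion-specific corrections.
* The arc model is a 2-D cross-section with a uniformly charged concave
  face; the convex face is uncharged and the protein body is a uniform
  low-dielectric band, not an atomistic charge distribution.
* Single isolated surface: no overlapping double layers, no dynamics.
* The bending module treats cylinders and spheres in closed form; general
  shapes would need a surface-integration backend.
* No configurational (mixing) entropy of adsorbed proteins; the packing
  comparison is energy-only with a scalar per-contact interaction.
* Protein parameters (`C_p`, `K_p`, `L_0`) for specific proteins
  (pacsin2, β2-GPI) are not established values; users must supply their
  own.
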