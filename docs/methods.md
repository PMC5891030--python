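# Methods

`fluctfem` simulates mesoscale biomolecules as continuum viscoelastic
bodies ("blobs") discretised into linear tetrahedral finite elements and
driven by thermal noise. This note records the model, the numerical
choices, and what the shipped validation suite does and does not show.

## Model

Each body obeys the Cauchy momentum balance with a Kelvin–Voigt
constitutive split: the stress is the sum of an elastic part (a function
of strain), a Newtonian viscous part (linear in strain rate), and a
fluctuating part whose statistics enforce the fluctuation–dissipation
theorem (FDT). Discretising with linear tetrahedra (material velocity
interpolated linearly between the four vertices) yields

    M dv/dt = -Λ v + E(x) + N + O

for the 3N nodal velocity components: `M` the mass matrix, `Λ` the
viscosity matrix, `E` the (nonlinear, conservative) elastic force, `N`
the thermal force, `O` external/inter-body forces.

**Elastic energy.** A compressible neo-Hookean split,

    W(F) = (G/2) (J^{-2/3} tr(FᵀF) - 3) + (K/2) (J - 1)²,

with `F` the per-element deformation gradient and `J = det F`. The form
is hyperelastic in shear with an isotropic volumetric penalty; its
linearisation is exactly isotropic elasticity with shear modulus `G` and
bulk modulus `K`, which is all the validation suite probes (all tests
operate at small strain). Forces are the exact analytic gradient
(first Piola–Kirchhoff stress contracted with the reference shape
gradients), so the conservativity test `E = -∇U` holds to roundoff.

**Viscosity.** The internal viscous stress is Newtonian,
`σᵛ = 2 μ_s dev(d) + μ_b tr(d) I`; with constant-gradient elements it
assembles into a sparse matrix with the same operator structure as the
small-strain stiffness (moduli replaced by viscosities). Solvent
friction is a local Stokes drag `6 π r μˢ` per node (diagonal addition
to `Λ`); there is no inter-body hydrodynamic coupling. For the sphere
fixtures the node radius is `r = R/N`, which makes the whole object's
drag exactly `6 π R μˢ`.

*Reference vs current geometry*: the integrator assembles `Λ` once at
the reference configuration and keeps its factorisation for the whole
run; the thermal forces are drawn against the same operator, so the FDT
holds exactly for the operator actually used in the solve. Thermal
strains in the validation regime are ~4%, making the difference from a
current-geometry `Λ` second order. `viscosity_matrix(positions=...)`
evaluates the deformed-geometry operator when needed.

**Thermal force.** Per step, each element receives an independent random
symmetric stress: a Gaussian symmetric matrix projected onto its
deviator and coupled to `μ_s`, plus an independent scalar isotropic part
coupled to `μ_b`, scaled by `sqrt(2 k_B T / (V_e dt))`. Mapping it to
the nodes through the same operator as the viscous stress gives nodal
noise with covariance `(2 k_B T/dt) Λ_int`, strictly local, with zero
net force and torque per element. Solvent noise is an independent kick
per node against the diagonal drag. The construction is verified against
the assembled `Λ` by Monte-Carlo covariance in the test suite.

**Integration.** Two schemes:

* *Brownian (overdamped)*: solve `Λ v = E + N + O`, then `x += dt v`
  (Euler–Maruyama; noise drawn once per step). `Λ` is factorised once
  (dense inverse below 1500 dof, sparse LU above).
* *Langevin (inertial)*: semi-implicit Euler — `v += dt M⁻¹(-Λv + E + N
  + O)` then `x += dt v(t+dt)` — chosen over fully explicit position
  update for stability.

Pinned nodes are removed from the solves by constraint elimination.
Every body owns an independent, serialisable PCG64 stream derived from
the master seed; checkpoints store positions, velocities, step index and
the generator state in hex-float JSON, so restarts are bit-exact. A
numba-compiled kernel advances single-body runs in blocks; it consumes
the *same* generator calls in the same order as the numpy path and is
cross-checked against it in the tests.

**Mass matrix.** Consistent (default) or lumped (`ρVₑ/4` per vertex).
The inertial validation protocols use the lumped form: at the protocol
step `dt = 10 fs` the generalised spectrum of `(Λ, M)` with the
consistent matrix exceeds the explicit stability bound
(`max eig(M⁻¹Λ) dt ≈ 4 > 2` on the fine sphere), while the lumped form
is comfortably stable.

## Inter-body forces

* *Steric repulsion*: overlapping surface tetrahedra of different bodies
  gain energy `k_steric · V_overlap`. The overlap volume is exact
  (successive half-space clipping, validated against a qhull
  half-space-intersection oracle to 5e-13 and a Monte-Carlo oracle); the
  force is the central-difference gradient of that volume under rigid
  relative displacement (step `1e-3` of the shortest edge), applied at
  the overlap centroid and spread to the 4+4 nodes barycentrically.
  `k_steric` defaults to `1e6 J/m³` — with that value a face-on contact
  of the default material resists piconewton-scale loads with
  sub-picometre interpenetration; it is a config parameter.
* *Surface Lennard-Jones*: a force-per-area² kernel
  `f(r) = 12 ε/r_eq [(r_eq/r)¹³ - (r_eq/r)⁷]` integrated over face pairs
  with 1-point (optionally 3-point) triangle quadrature; per-type-pair
  parameters, symmetric in the pair. When steric mode is also active the
  attractive branch below `r_eq` is replaced by the cubic
  `72 ε r²(r_eq - r)/r_eq⁴`, which matches the LJ force and slope at
  `r_eq` and has zero value and slope at `r = 0`, handing the hard core
  to the steric term.
* *Candidate search*: faces are binned by centroid into cubic voxels
  (default size: LJ cutoff, or half the longest surface edge for
  steric-only runs), pairs taken from the 27-cell neighbourhood,
  filtered to active types (`t ≠ -1`), opposed normals (`n₁·n₂ < 0`)
  and, by default, different bodies. The voxel assignment refreshes
  every `n_refresh` steps (default 10). Equality with brute-force
  enumeration is a property test.
* *Springs*: Hookean node–node links `F = -k(|d| - l₀) d̂`.
* *Beads*: pseudo-particles bound at setup to the element with the
  nearest centroid, positioned barycentrically, interacting through
  tabulated `(r, F[, E])` pair potentials (missing pair ⇒ null
  interaction; beyond-table distances clamp to the last entry). Forces
  are spread to the host-element nodes with the bead's weights.

## Linear elastic model, mapping, analysis

The stiffness matrix is assembled analytically from the linearised
constitutive model (same kernel as `Λ_int` with moduli in place of
viscosities) and cross-checked against finite differences of the
nonlinear force. Normal modes come from dense `eigh` below 1500 dof and
shift-invert `eigsh` above. The two relaxation spectra are defined as
the generalised eigenproblems `K v = (1/τ) Λ v` (viscoelastic; the slow
end bounds the simulation length needed) and `Λ v = (1/τ) M v`
(inertial; the fast end bounds the stable step).

The atomic mapper assigns each atom the containing element (barycentric
weights ≥ -1e-9, ties to the lowest element index) or, outside the mesh,
the nearest-centroid element with extrapolated weights; replaying a
trajectory is a per-frame linear interpolation, so it commutes with
affine motion exactly. RMSD uses an optional Kabsch fit; PCA is an SVD
of the (optionally rigid-fitted) centred frames; two eigensystems are
compared by the inner-product matrix and the subspace overlap
`(1/n) ΣΣ (vᵢ·wⱼ)²`.

## Fixture meshes

* *Cube*: n³ bricks split into six tetrahedra each (Kuhn decomposition,
  shared diagonals ⇒ conforming); fills the volume exactly.
* *Sphere*: radial stacks of geodesic (icosphere) shells down to a
  central vertex; prisms between shells split into three tetrahedra with
  a global vertex-order diagonal rule (conforming). This gives
  near-uniform element quality — a mapped-lattice ball was tried first
  and rejected because cells squashed near the cube corners produced
  sliver elements with viscous relaxation rates ~100× the bulk value.
  The shells are inflated uniformly so the discrete volume equals
  `(4/3)πR³` (the faceted surface is inscribed, and the body should
  carry the analytic mass and drag), mirroring volume-preserving surface
  coarsening practice.
* *Cylinder*: a square cross-section lattice mapped to the disc and
  extruded; the section is inflated radially so its discrete area equals
  `πR²`.

Minimum-edge warnings are emitted below 0.5 nm, where a continuum
element description stops being meaningful; no hard floor is enforced.

## Validation suite: conditions and limits

Study conditions (fixed): sphere `R = 5 nm`, `ρ = 1500 kg/m³`,
`E = 1 GPa`, `ν = 0.35`, internal and solvent viscosities `1e-3 Pa·s`,
`T = 300 K`, `dt = 10 fs` for equipartition (10⁵ steps/ns) and `0.1 ps`
for diffusion; cylinder `160 × 10 nm`, `E = 600 GPa`.

* Two sphere resolutions are used deliberately: *fine* (edge ~2 nm,
  N = 185) for the overdamped protocols, where run-to-run sampling
  scatter limits accuracy, and *coarse* (edge ~2.5 nm, N = 85) for the
  inertial protocols, where kinetic-energy accuracy requires the fixed
  10 fs step to resolve the fastest viscous relaxation
  (`max eig(M⁻¹Λ) dt ≈ 0.06` on the coarse mesh). Both choices follow
  from the operator spectra, not from tuning on outcomes.
* The beam tests specify only `E`; we take `ν = 0` so the fully clamped
  end exerts no Poisson constraint (with `ν = 0.35` the clamp stiffens
  the measured stretch modulus by ~0.6%, far above the reference
  accuracy of that test — verified by comparing against axial-only
  pinning, which is exact). Static equilibria are found by Newton
  iteration on the full nonlinear elastic force (reference stiffness as
  Jacobian), equivalent to a noise-free relaxation.
* The bend test uses 5 elements across the radius; linear tetrahedra
  are systematically stiff in bending and the error decreases under
  refinement (10.5% at 4 across, 2.4% at 6 across), so the quoted
  accuracy is a statement about this resolution.
* *Known limitation (long equipartition averages)*: at `dt = 10 fs` the
  overdamped scheme carries a systematic strain-energy excess of
  ~+0.2% (measured over 20 ns with ~1300 independent frames, sampling
  error 0.17%). Per mode the Euler–Maruyama stationary variance is
  inflated by `dt/(2τ)` with `τ ∈ [μ_b/K, μ_s/G] = [0.9, 2.7] ps` — a
  property of the *material*, not the mesh — partly offset by the
  anharmonicity of the finite-fluctuation elastic energy (per-element
  strain fluctuations are ~12% at these element sizes). Long averages
  converge to this bias level rather than to zero. Higher-order
  stochastic integrators would remove the floor but are out of scope.
* *Statistics of the last-60-frame estimator*: one recorded frame's
  strain energy has relative standard deviation `sqrt(2/(3N-6))` (5.9%
  at N = 185) and decorrelates within ~5 ps, so an average over the last
  60 recorded frames carries ~0.7% scatter however long the run is; the
  long-run protocols therefore record every 15 ps and average all
  post-equilibration frames.
* Collision/cube-pull scenarios: spheres approach at 2 m/s (soundspeed
  ~800 m/s, penetration ~0.3 nm « element size) with `dt = 0.25 ps` and
  no solvent drag so the rebound is visible; cubes (4 nm, edge-2
  lattice) are pulled by four corner springs of `5e-5 N/m` against drag
  with 0.1 nm node radius at `dt = 1 ps`, weak enough that steric
  contact (`k_steric = 1e6 J/m³`) halts interpenetration at the
  sub-picometre level.
* The PCA stiffness-scaling check runs 20 ns per modulus at `dt =
  0.1 ps` on the coarse sphere and compares the mean of the top five
  eigenvalue ratios; at this length the estimate lands within a few
  percent of the modulus ratio 3.

What passing these tests shows: correct FDT statistics, elastic
linearisation, drag calibration, steric/spring/LJ force consistency and
mapping fidelity *for homogeneous convex fixtures at small strain*. What
they do not show: accuracy for irregular experimental meshes, large
deformations, heterogeneous materials, or time-scales where the
reference-geometry `Λ` approximation matters.

## Problem sizes and determinism

Default validation sizes: spheres N = 85/185 nodes (320/720 elements),
cylinder ~9.8k nodes (48k elements), cubes 27 nodes each. The pytest
suite runs the 1 ns protocols at full length and the long equipartition
check at 6 ns (its deviation is bias-dominated and does not change with
further averaging); the acceptance script runs the full 20 ns protocol.
All stochastic results are reproducible bit-for-bit from (config, seed),
including across checkpoint/restart and across the numpy/numba paths up
to floating-point associativity.
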