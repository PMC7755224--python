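# Methods

`mtled` simulates needle insertion into soft, nearly incompressible continua
(silicone-gel samples, brain-like phantoms) with a meshless total Lagrangian
explicit dynamics solver and a two-parameter *kinematic* needle–tissue
interaction model. This note records the model, the numerical choices, and
what the synthetic studies do and do not establish.

## Governing model

The solid is discretized by an unstructured cloud of nodes carrying the
displacement unknowns, plus a background tetrahedralization used solely for
numerical quadrature (one stress evaluation point per cell, at the centroid).
All quantities are referred to the reference configuration (total Lagrangian),
so shape-function derivatives are precomputed once.

The semi-discrete equations of motion

    M ü + F_int(u) = F_ext,
    F_int = ∫ F S : ∇₀φ dV₀   (one-point quadrature per background cell)

are advanced by damped central differences

    u(t+Δt) = [Δt² M⁻¹ (F_ext − F_int) + 2u(t) − (1 − cΔt/2) u(t−Δt)] / (1 + cΔt/2).

### Constitutive law

One-term Ogden hyperelasticity in principal stretches λᵢ, with J = λ₁λ₂λ₃:

    W = (2μ/a²) (J^(−a/3)(λ₁^a + λ₂^a + λ₃^a) − 3) + (1/D)(J − 1)²

with shear modulus μ (Pa), exponent a (dimensionless) and volumetric
compliance D (1/Pa). a = 2 recovers the neo-Hookean model. The volumetric
penalty implies a bulk modulus K = 2/D; this convention reproduces ν = 0.49
for every gel parameter set shipped with the package (e.g. μ = 722 Pa,
D = 5.57738×10⁻⁵ Pa⁻¹), and is unit-tested. The second Piola–Kirchhoff
stress is assembled spectrally: Sᵢ = λᵢ⁻¹ ∂W/∂λᵢ on the eigenprojectors of
C = FᵀF (analytic trigonometric eigenvalues; explicit repeated-eigenvalue
branches). Near-incompressibility is handled by the penalty term alone.

### Kinematic needle model

Contact, friction and cutting are not modeled. Instead the insertion is posed
as a Dirichlet problem with two image-identifiable parameters:

* **Indentation.** Surface nodes within the needle footprint move with the
  tip while the maximum principal Green strain, max eig ½(FᵀF − I), is
  monitored at quadrature points near the entry. When it exceeds the
  puncture strain ε_p (default 10⁻⁵, i.e. an intentionally short indentation
  stage for membrane-free gels), penetration begins. A tie (strain = ε_p)
  does not puncture.
* **Penetration.** Nodes inside a sleeve around the traversed shaft
  (perpendicular distance ≤ capture radius, axial position between entry and
  tip) are *captured* and thereafter prescribed the axial displacement
  C_D·(depth − activation depth), C_D being the deformation coefficient
  (default 0.4, identified from images as the ratio U₂/U₁ of maximum surface
  deflection along the shaft to insertion depth).

Two continuity details matter in practice and are deliberate design choices:
the activation depth of a captured node is set so that the kinematic rule
matches the node's axial displacement at the instant of capture, and the
lateral displacement it acquired while free is frozen into the prescription
(the drive increment itself is purely axial, consistent with a symmetric
tip). Without these, capture injects a displacement jump that can invert
cells next to the shaft. Driven nodes are never released; retraction is out
of scope.

Defaults: capture radius = needle radius + median nodal spacing (a one-node
sleeve); strain monitor radius = max(2 × needle radius, 1.5 × spacing).

## Approximation: modified moving least squares

Shape functions use a linear monomial basis augmented with the six quadratic
monomials whose coefficients are ridge-penalized (default penalty 10⁻⁷),
preserving partition of unity and linear completeness exactly while keeping
the moment matrix invertible on nearly degenerate clouds. Weight function:
quartic spline 1 − 6q² + 8q³ − 3q⁴. The moment system is Jacobi-equilibrated
and iteratively refined so partition of unity holds to 10⁻¹² and gradient
sums to 10⁻¹⁰/mm.

Support domains take the nodes within `dilation` × (distance to the
`min_neighbors`-th neighbor); defaults 16 and 1.1. Supports whose shape
functions are not at machine-level consistency, or oscillate (|φ| > 1.2, or
‖∇φ‖·radius > 4), are automatically enlarged in up to three rounds. This
adaptivity is what makes arbitrary jittered clouds safe.

Two weight variants exist. The *interpolating* variant divides the weight by
(q² + 10⁻¹⁰), giving a near-delta property at nodes; it is used wherever
nodal values must bind the field: cross-grid transfer, marker (bead)
evaluation, and the solver tables, so that prescribed nodal displacements
(fixed base, driven sleeve) constrain the actual displacement field.

### Quadrature: conforming smoothed gradients

Evaluating MLS point gradients at cell centroids and summing with cell
volumes violates the divergence identity Σ_c V_c ∇φᵢ(x_c) = ∮ φᵢ n dΓ at
stiffness scale; on a coarse jittered brick this made the discrete solid
~25 % too soft in a confined-compression patch test (verified against a
direct sparse solve, so it is a discretization property, not a solver
artifact). The per-cell gradient stored in the solver table is therefore the
*cell-averaged* (smoothed) gradient, computed as a one-point-per-face surface
integral of the shape values over the tetrahedron's faces. Interior faces are
shared with opposite orientation by their two cells, so the divergence
identity holds exactly and the linear patch test passes to discretization
accuracy: on a 512-node jittered brick under confined compression to
λ_z = 0.9, the settled field matches the homogeneous closed form to 0.13 %
RMS and the face reaction to 0.25 %. The max-norm error carries an O(1 %)
boundary layer because interior shape functions do not vanish on the
Dirichlet surface — a known property of meshless essential boundary
conditions; integrated quantities converge. Stress is still evaluated once
per background cell.

## Quasi-static solution by dynamic relaxation

The loading of interest is slow, so the solver seeks the settled static
field. Mass is then a free (fictitious) parameter; only its distribution
affects convergence:

* **Mass.** A Gershgorin bound on the tangent-stiffness row sums gives a
  diagonal mass for which the central-difference scheme is stable at pseudo
  time step Δt = 1 with a configurable stiffening margin (default 3×).
  A power-iteration estimate of the true spectral bound 2/ω_max is re-checked
  every 1,000 steps (the tangent stiffens at large strain — the Ogden
  exponent a = −1.3 hardens strongly in compression) and Δt is reduced if
  the margin is exhausted, rescaling the displacement history so the
  discrete velocity is preserved. The *physical* critical-step estimate
  Δt = safety·h_min/c with c = √((K + 4μ/3)/ρ) remains exposed as
  `critical_time_step` with its scaling contracts.
* **Damping.** Mass-proportional, at the critical value 2ω₁ of the dominant
  residual mode, with ω₁ estimated on the fly from the Rayleigh quotient of
  the displacement increment against the internal-force increment
  (secant stiffness), re-tuned every 25 steps.
* **Schedule.** Each requested depth is approached by a smoothstep ramp
  (default 1,500 steps per stage) and then relaxed at constant depth until
  the kinetic-to-strain-energy ratio falls below 10⁻⁹, which corresponds to
  a residual oscillation amplitude of ~3×10⁻⁵ of the displacement scale.
  Failure to settle raises an error carrying the energy trace.

Reaction force on the needle is recovered as the projection on the insertion
axis of Σ (M ü + F_int − F_ext) over the driven nodes, accelerations by
central differences; at a settled state the inertial term is negligible, so
the fictitious mass does not bias it.

Mass lumping for physical-mass uses (`lumped_mass`) is per-cell diagonal
scaling (HRZ): each cell's mass ρV is split over its supporting nodes in
proportion to φᵢ², which conserves every cell's mass exactly and remains
positive where MLS shape values are negative (plain row-sum lumping produces
negative rim-node masses on healthy grids).

## Synthetic geometries

The generators recreate the study geometries from their defining dimensions:
a homogeneous ∅30 × 17 mm gel cylinder and a three-layer ∅65 × 34 mm
cylinder (layer heights 18/9/7 mm from the base, a different Ogden parameter
set per layer), with 46 synthetic markers placed on two interface planes
standing in for embedded steel beads. Nodes are placed on concentric rings
per z-level (interfaces snapped to levels so layers conform), with seeded
xy-jitter of strictly interior nodes; background cells come from Delaunay
tetrahedralization. Coordinates: origin at the base centre, z up, insertion
along −z — one convention throughout. The clouds are deterministic in the
seed, match a node-count target within 15 %, and their summed cell volumes
approach the analytic volume as the target grows (the residual is lateral-
surface faceting).

What the synthetic studies do **not** emulate: real CT image formation, bead
localization error and its contrast dependence, needle deflection (excluded
by design), membrane spring-back at puncture, and rate/viscoelastic effects.
Passing the synthetic checks therefore establishes internal consistency of
the solver and the kinematic model — grid convergence, material-independence
of displacements, mechanical consistency of forces — not agreement with any
particular physical experiment.

## Verification studies and problem sizes

The shipped verification suite (and `scripts/acceptance.py`) runs
deliberately scaled-down versions of the full protocols so everything fits
on one CPU in minutes. The bounds asserted are the published full-size
reference values; a scaled study can therefore fall short of its bound for
resolution reasons alone, and the suite reports that honestly rather than
adjusting either the bound or the study:

* **Material independence** (~3,000-node small cylinder, 15 mm insertion,
  μ = 72 vs 7,220 Pa with D inversely scaled): asserted ≤ 4.17×10⁻⁴ and met
  with a large margin. The discretized equilibrium is *exactly* invariant
  under (μ, D) → (sμ, D/s) — captured-node prescriptions are purely
  geometric once their fades elapse — so the measured NRMSE (~10⁻⁴) is
  residual settling noise of two differently-conditioned relaxations.
* **Grid convergence**: the reference protocol compares 7,480- and
  30,294-node solutions (bound 1.40×10⁻², available via
  `mtled convergence`; the refined solve costs tens of CPU-minutes). The
  in-suite version runs the same protocol at ~3,000 vs ~8,000 nodes against
  the same full-size bound; because the cross-grid NRMSE shrinks with the
  coarse grid's spacing, the scaled value sits above the full-size bound at
  this scale. The suite additionally asserts the qualitative claim that the
  NRMSE against the densest grid decreases monotonically under refinement.
  Convergence studies freeze the needle's capture/monitor radii at the
  coarsest grid's resolved values so that every density solves the same
  physical problem.
* **Model-form insensitivity** (~5,000-node layered cylinder: per-layer
  Ogden vs homogeneous neo-Hookean μ = 1,000 Pa): asserted against the
  full-size reference ≤ 8.1×10⁻³. The driven sleeve is one nodal spacing
  thick, hence fatter at coarse resolution, and the material-sensitive
  large-strain layer around it carries correspondingly more volume, so this
  quantity too decreases with refinement; the value the suite computes at
  the prescribed scale is of order 10⁻² and is reported as computed.
* **Marker interpolation**: affine fields are reproduced at the 46 marker
  positions to L∞ ≤ 10⁻⁹ mm.
* **Closed-loop kinematics**: the settled surface deflection ratio U₂/U₁
  next to the shaft recovers C_D = 0.4 within [0.3, 0.5].

NRMSE is per displacement component: RMS of the node-by-node difference on
the denser grid, normalized by that component's range in the denser field.

## Known limitations

* Essential boundary conditions are imposed on nodal parameters; with
  interpolating weights the field is bound at the nodes but not between
  them, leaving a small boundary-layer error (see patch test above).
* The kinematic drive has no force feedback: reaction forces are meaningful
  only when material parameters are (they are for the verification gels),
  and the Ogden fit loses accuracy at very large strains near the tip.
* No retraction, cutting, needle bending, or rupture mechanics.
* Dynamic relaxation yields statics only; transient dynamics with physical
  mass are possible through the `step`/`lumped_mass`/`critical_time_step`
  primitives but are not the packaged workflow.
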