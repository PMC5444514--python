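# Methods

`fm2d` simulates a closed, inextensible, bending-elastic fluid membrane (a
two-dimensional vesicle cross-section) immersed in incompressible two-phase
Navier–Stokes flow, with an unfitted finite element method: the bulk
triangulation and the membrane polygon are discretised independently, and
the membrane cuts freely through bulk elements.

## Model

The domain Ω ⊂ R² is split by the moving closed curve Γ(t) into an inner
phase Ω₋ and an outer phase Ω₊ with densities ρ± ≥ 0 and viscosities
μ± > 0. In each phase,

    ρ (∂ₜu + (u·∇)u) = ∇·σ + f,   ∇·u = 0,   σ = 2μ D(u) − p I,

with D(u) the rate-of-deformation tensor, a Dirichlet condition u = g on
∂₁Ω and a stress-free condition σn = 0 on ∂₂Ω. The membrane itself is a
two-dimensional fluid: velocity is continuous across Γ, the membrane moves
with the flow, and the surface momentum balance

    ρ_Γ ∂ₜ•u = ∇ₛ·σ_Γ + [σ n]⁺₋ + α f_Γ ν,   ∇ₛ·u = 0   on Γ

carries a Boussinesq–Scriven surface stress σ_Γ (surface pressure p_Γ plus
interfacial shear viscosity μ_Γ; for plane curves the μ_Γ term vanishes
identically in the continuous problem but not discretely, and it is kept),
surface inextensibility enforced by p_Γ, and the bending force
f_Γ = −Δₛκ − κ|∇ₛν|² + κ³/2, the first variation of the Willmore energy
E = ½∫_Γ κ². Enclosed area (2D volume) and total membrane length are
conserved; circles with zero bulk velocity are stationary.

## Discretisation

**Bulk.** Taylor–Hood P2–P1 elements on a conforming triangulation obtained
from a structured macro grid of right isosceles triangles by newest-vertex
bisection, refined to size h_f = 2·min(H)/N_f in a band of one element
diameter (plus half an h_f of margin) around Γ and left at
h_c = 2·min(H)/N_c elsewhere. Elements are classified as interior /
exterior / interfacial by exact segment clipping; the discrete density and
viscosity are ρ±, μ± in the bulk phases and the arithmetic mean on cut
elements. The discretisation shorthand `n adapt_{k,l}` sets N_f = 2^k,
N_c = 2^l, τ = 10⁻³/n and, by default, K_Γ = 2^k + 1 membrane vertices.

**Membrane.** A closed polygon with P1 (vertex) and P0 (segment) surface
fields and the lumped inner product ⟨·,·⟩ʰ (vertex weights w_k = half the
adjacent segment lengths). The curvature vector is Dziuk's: ⟨κ, η⟩ʰ +
⟨∇ₛ id, ∇ₛ η⟩ = 0, which is diagonal after lumping; on an equidistributed
polygon inscribed in a circle of radius R it reproduces |κ| = 1/R exactly.
The sign convention makes κ negative where the inner phase is convex.

**Coupling.** Every interface integral involves the interface interpolant
π_ℓ (ℓ = 1 at vertices, ℓ = 2 also at segment midpoints) of the bulk
velocity, so only point evaluations of the P2 basis on Γ are needed and all
integrands are polynomials on whole segments (integrated exactly).
Three incompressibility constraints act on the velocity: bulk divergence
against P1 pressures; surface inextensibility ⟨χ_k, ∇ₛ·(π_ℓ u)⟩ = 0 against
the P1 surface pressure; and the single scalar constraint ⟨u, ω⟩ʰ = 0
against a multiplier P_sing, where ω is the length-weighted vertex normal.
Because ⟨z, w ν⟩ʰ = ⟨z, w ω⟩ʰ for P1 fields, this "virtual element"
constraint is exactly the vanishing of the discrete normal flux through the
polygon, which is the first variation of the enclosed area — so the area
drift per step is O(τ²) (the residual quadratic term of vertex motion),
not O(τ).

**Bending force.** The force equation is the exact first variation of the
lumped discrete bending energy Eʰ = ½⟨κ,κ⟩ʰ under the curvature constraint:
for plane polygons

    ⟨F, χ⟩ʰ = ⟨∇ₛκ, ∇ₛχ⟩ − ⟨∇ₛ·κ, ∇ₛ·χ⟩ + ½⟨|κ|², ∇ₛ·χ⟩ʰ,

assembled as the stiffness A_Γ (taken implicitly at κ^{m+1}), the
divergence–divergence block B_Γ (for plane curves symmetric, so the
combination Z_Γ = B_Γ − B_Γ* − R_Γ collapses to −B_Γ) applied to κ^m, and a
|κ^m|²-weighted stiffness applied to the current vertex positions. A test
differentiates the energy numerically and checks the assembled force
against it.

**Time stepping.** One linear solve per step for (U^{m+1}, P^{m+1},
P_sing^{m+1}, P_Γ^{m+1}, κ^{m+1}, δX^{m+1}, F^{m+1}): implicit Euler for the
viscous and bending terms, convection antisymmetrised and linearised at
U^m (with the ½ρ₊⟨U^m·n, u·ξ⟩ stress-free boundary term), lumped surface
inertia with the previous membrane velocity as history. The membrane then
moves by pure vertex motion, q_k ← q_k + τ U^{m+1}(q_k); the curvature,
surface pressure and membrane velocity are pushed forward label-for-label,
and a marker field Ψ (initially 1) is transported conservatively,
Ψ_k ← Ψ_k w_k^old / w_k^new, so Ψ measures local length change.

## Linear algebra

The saddle system is solved monolithically with a sparse LU after symmetric
elimination of Dirichlet rows/columns. A Schur variant eliminates
(κ, δX, F) analytically — possible because the lumped surface mass is
diagonal — adding ατ M_{Γ,Ω}M⁻¹A M⁻¹A M⁻¹M_{Γ,Ω}ᵀ (symmetric positive
semidefinite) to the momentum block; both paths agree to 1e−8 and the
direct path is the default. Two amortisations keep desk-scale runs fast,
without changing the scheme: the adapted mesh is kept while no membrane
vertex has moved more than a fifth of the band margin (the refined band
remains valid), and between refactorisations the previous LU serves as a
preconditioner for Richardson iteration to 1e−12 relative residual, with
automatic refactorisation when the iteration stalls. When ∂₂Ω = ∅ the
pressure is normalised by a zero-mean Lagrange multiplier rather than by
pinning a node.

Uniqueness of the discrete solution needs two genuinely geometric
conditions worth knowing about. First, an even membrane vertex count admits
an alternating ±1 checkerboard mode in the P1 surface pressure for ℓ = 1
(the inextensibility rows annihilate it on an even cycle); the convention
K_Γ = 2^k + 1 is odd and the constructor warns otherwise. Second, on an
exactly circular polygon the discrete curvature is exactly constant, and
(P, P_sing, P_Γ) are then unique only up to a one-parameter family, exactly
as for the continuous problem on a sphere; velocities and vertex motion
remain unique, so stationary-circle runs are unaffected.

## Parameters

| symbol | meaning | default |
|---|---|---|
| ρ± | bulk densities | 1 (0 = quasi-static) |
| μ± | bulk viscosities | 1 |
| ρ_Γ | membrane density | 1 |
| μ_Γ | interfacial shear viscosity | 1 |
| α | bending rigidity | 1 |
| τ | time step | 10⁻³/n from the shorthand |
| ℓ | interface interpolation order | 1 |

Scenario presets reproduce the standard experiments: `shear_a`/`shear_b`
(Ω = (−2,2)², g = (z₂, 0) on top/bottom, stress-free sides, initial
ellipse of axes 1 × 2.5 so a_r = 0.745, α = 0.05, μ₋ = 1 or 10),
`constriction` (three-rectangle channel, Poiseuille inflow g = (1−z₂², 0),
ρ± = 0, α = 0.1, ρ_Γ ∈ {0, 15}, initial 0.2 × 1.5 tube, a_r = 0.351,
placed upright in the inlet), `letter_C` (open-annulus C in (−1,1)², all
parameters unity, ρ_Γ ∈ {0, 1}) and `relax_circle`. The letter-C generator
exposes inner/outer radius and opening angle (defaults 0.3 / 0.6 / π/2,
giving a_r ≈ 0.33) since only its reduced area, not its construction, is
standard. The "tube of total dimension 0.2 × 1.5" is realised as a stadium
(rectangle with semicircular caps); this choice reproduces the printed
reduced area 0.351 to three decimals, where a sharp-cornered rectangle
does not.

## What the tests do and do not show

The suite verifies: machine-precision geometric identities (weighted
normals summing to zero, the ν/ω pairing identity, clipping length
conservation, transport conservation); the dense-oracle equality of all
membrane matrices on small polygons and the finite-difference energy
variation; third-order velocity convergence on a manufactured Stokes
solution; exact stationarity of circles; monotone energy decay on
driven-free relaxations; and, on scaled-down runs (adapt_{6,3}, K_Γ = 129,
T = 1 for shear; adapt_{4,2}, K_Γ = 33 for the constriction marker and
adapt_{5,2}, K_Γ = 33 for the shear regimes), conservation of length and
phase areas to ≤ 0.2 %, near-unit element ratio, the ℓ = 1 vs ℓ = 2 local
inextensibility contrast, and the tank-treading vs tumbling distinction by
viscosity contrast. Problem sizes were chosen once as desk-scale settings;
the full-resolution runs of the literature (2 adapt_{9,4}, K_Γ = 513) use
identical code paths but are not exercised by the suite. The scaled runs
probe shorter times and coarser meshes than the full experiments, so
quantitative figures (drifts, r_a) are upper bounds of a coarser
computation, not reproductions of full-resolution values; qualitative
regime distinctions are robust at these sizes.

## Limitations

Two space dimensions only (the reduced volume v_r is provided as a formula
for reference); no topology change, no remeshing or vertex redistribution
(the inextensibility constraint is what keeps the polygon equidistributed —
that is a property under test, not engineered around); rectilinear domains
only; no preconditioned Krylov solvers (desk-scale problems factor
directly); the decoupled-update variant and piecewise-constant surface
pressures are documented alternatives, not implemented.
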