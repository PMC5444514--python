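# fm2d — fluidic membranes in two-phase flow, unfitted FEM in 2D

`fm2d` simulates closed lipid-bilayer membranes (vesicles, the 2D
cross-section of red-blood-cell-like objects) immersed in incompressible
two-phase Navier–Stokes flow. The membrane is itself a fluid: it resists
bending through the Willmore energy E(Γ) = ½∫_Γ κ² (bending rigidity α),
carries Boussinesq–Scriven surface viscosity, and is locally inextensible,
∇ₛ·u = 0 on Γ, enforced by a surface pressure. The package is for
numerical analysts and biophysics modellers who want a stable, conservative
scheme for this coupled free-boundary problem at desk scale.

The method is *unfitted*: a Taylor–Hood P2–P1 bulk mesh, adaptively refined
near the interface by newest-vertex bisection, is discretised independently
of the membrane, which is tracked as a polygon cutting freely through bulk
elements. One linear saddle system per time step couples the bulk momentum
and divergence equations, the surface inextensibility constraint, a scalar
"vertex normal" constraint ⟨u, ω⟩ʰ = 0 that conserves the enclosed area,
Dziuk's curvature relation ⟨κ, η⟩ʰ + ⟨∇ₛid, ∇ₛη⟩ = 0, and the exact first
variation of the discrete bending energy as the force. The scheme's
signature properties — membrane length and phase areas conserved to a small
fraction of a percent, the polygon staying equidistributed without any
remeshing, circles being exactly stationary — are what the test suite
checks. See `docs/methods.md` for the full write-up.

## Worked example

A vesicle of reduced area a_r = 4π·area/length² = 0.745 in shear flow
(`examples/03_shear_tank_treading.py`, scaled down to K_Γ = 17 vertices,
a few minutes):

```
t      angle(deg)  length      area
0.50     81.60   5.676491   1.902858
1.00     60.11   5.677346   1.903022
1.50     40.60   5.678225   1.903435
2.00     29.21   5.678957   1.903947
2.50     23.91   5.679703   1.904412
3.00     21.89   5.680507   1.904826
3.50     21.40   5.681349   1.905210
4.00     21.52   5.682204   1.905581

mean membrane speed: tangential 0.3585, normal 0.0208
drifts: length 0.1058 %, area 0.1434 %, max r_a 1.00177
```

The initially upright vesicle tilts to a steady inclination of about 21°
while the membrane keeps circulating (tangential speed 17× the normal
speed): tank treading. Even at this very coarse resolution, length and
enclosed area drift by ~0.1 % and the element ratio r_a = max/min segment
length stays below 1.002 — the inextensibility constraint keeps the
polygon equidistributed with no remeshing (at adapt_{6,3}, K_Γ = 129 the
drifts fall to ~0.01 % and r_a to 1.00014). With viscosity contrast
μ₋/μ₊ = 10 (`shear_b`) the same vesicle tumbles instead: the inclination
never settles but rotates through horizontal.

Other examples: `01_shapes_and_reduced_area.py` (the initial-shape
generators and their shape numbers), `02_circle_relaxation.py` (discrete
stationarity of circles), `04_constriction_marker.py` (a tube entering a
constriction; a transported marker shows local length preservation for
interface-interpolation order ℓ = 1 and its loss for ℓ = 2).

There is also a thin CLI:

```sh
fm2d run --preset shear_a --disc "adapt_{6,3}" --k-gamma 129 --T 1.0 --out results/
fm2d diag results/
```

YAML configs mirror the flags (`fm2d run --config run.yaml`). Outputs are
plain text: a full-precision diagnostics CSV (columns t, length, area,
energy, kinetic, a_r, r_a, psi_min, psi_max, constraint residuals, p_sing)
and legacy-ASCII VTK snapshots of the bulk grid and the membrane polyline.

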